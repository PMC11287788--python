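"""Distribution comparison machinery for grouped event data.

Implements, from their definitions:

* the rank-based k-sample Anderson-Darling (AD) criterion with midrank tie
  handling, its finite-sample variance, the standardized statistic, and an
  asymptotic p-value by interpolation of the published critical-value
  surface (a permutation p-value is available for small samples),
* Holm's step-down multiple-comparison adjustment,
* a design-aware percentile bootstrap: units (cells by default, since
  events within a cell are dependent; configurable to mice or raw events)
  are resampled with replacement within treatment group, the sampled units'
  events pooled, and group means plus pairwise differences recorded per
  iteration; 95% intervals are the 2.5th/97.5th percentiles of the
  bootstrap distribution (linear-interpolation quantiles).

A statsmodels-flavoured front door, :class:`GroupDistributionComparison`,
bundles the omnibus test, the four canonical post hoc pairs with Holm
adjustment, and the bootstrap effect sizes into a results object with a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ADResult",
    "BootstrapSpec",
    "BootstrapResult",
    "ad_ksample",
    "ad_criterion",
    "holm_adjust",
    "pairwise_ad_posthoc",
    "hierarchical_bootstrap",
    "GroupDistributionComparison",
    "GroupComparisonResults",
    "CANONICAL_PAIRS",
]

CANONICAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("STD-CON", "STD-ALPS"),
    ("LBN-CON", "LBN-ALPS"),
    ("STD-CON", "LBN-CON"),
    ("STD-ALPS", "LBN-ALPS"),
)

# Critical values of the standardized k-sample AD statistic: tm(m) =
# b0 + b1/sqrt(m) + b2/m at the tail probabilities in _AD_SIG (m = k - 1).
_AD_B0 = np.array([0.675, 1.281, 1.645, 1.960, 2.326, 2.573, 3.085])
_AD_B1 = np.array([-0.245, 0.250, 0.678, 1.149, 1.822, 2.364, 3.615])
_AD_B2 = np.array([-0.105, -0.305, -0.362, -0.391, -0.396, -0.345, -0.154])
_AD_SIG = np.array([0.25, 0.10, 0.05, 0.025, 0.01, 0.005, 0.001])


class ADResult(NamedTuple):
    """k-sample AD test: raw criterion, standardized statistic, p-value."""

    criterion: float
    standardized: float
    pvalue: float


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = []
    for g in groups:
        a = np.asarray(g, dtype=float).ravel()
        if a.size == 0:
            raise ValueError("every group must be non-empty")
        out.append(a)
    return out


def ad_criterion(groups: Sequence[np.ndarray], midrank: bool = True) -> float:
    """The k-sample Anderson-Darling criterion A.

    ``midrank=True`` gives the tied-data (midrank) version; ``False`` the
    continuous-population version, defined only for untied pooled data.
    """
    gs = _check_groups(groups)
    n = np.array([g.size for g in gs], dtype=float)
    pooled = np.concatenate(gs)
    N = pooled.size
    z, l = np.unique(pooled, return_counts=True)

    if midrank:
        bj = np.cumsum(l) - l / 2.0
        a = 0.0
        for gi, ni in zip(gs, n):
            f = np.zeros(z.size)
            idx, cnt = np.unique(np.searchsorted(z, gi), return_counts=True)
            f[idx] = cnt
            m = np.cumsum(f) - f / 2.0
            num = (N * m - ni * bj) ** 2
            den = bj * (N - bj) - N * l / 4.0
            a += (l / N * num / den).sum() / ni
        return float(a * (N - 1) / N)

    if np.any(l > 1):
        raise ValueError("continuous-version criterion requires untied pooled data")
    zs = np.sort(pooled)[:-1]
    j = np.arange(1, N)  # ranks 1..N-1
    a = 0.0
    for gi, ni in zip(gs, n):
        m = np.searchsorted(np.sort(gi), zs, side="right")
        a += (((N * m - j * ni) ** 2) / (j * (N - j))).sum() / ni
    return float(a / N)


def _ad_sigma(n_sizes: Sequence[int]) -> float:
    """Null standard deviation of the criterion (finite-sample formula)."""
    N = int(sum(n_sizes))
    k = len(n_sizes)
    H = float(np.sum(1.0 / np.asarray(n_sizes, dtype=float)))
    i = np.arange(1, N, dtype=float)
    h = float(np.sum(1.0 / i))
    g = 0.0
    for ii in range(1, N - 1):
        g += float(np.sum(1.0 / ((N - ii) * np.arange(ii + 1, N, dtype=float))))
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    var = (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))
    return float(np.sqrt(var))


def _asymptotic_pvalue(standardized: float, k: int) -> float:
    m = k - 1
    tm = _AD_B0 + _AD_B1 / np.sqrt(m) + _AD_B2 / m
    coef = np.polyfit(tm, np.log(_AD_SIG), 2)
    # beyond the tabulated tail, continue log(p) linearly with the fit's
    # slope at the table edge: the quadratic itself turns around and would
    # otherwise give nonsense for extreme statistics
    t_hi = float(tm.max())
    if standardized > t_hi:
        slope = 2 * coef[0] * t_hi + coef[1]
        logp = np.polyval(coef, t_hi) + slope * (standardized - t_hi)
    else:
        logp = np.polyval(coef, standardized)
    p = float(np.exp(logp))
    return float(min(max(p, 0.0), 1.0))


def ad_ksample(
    groups: Sequence[np.ndarray],
    midrank: bool = True,
    method: str = "asymptotic",
    n_permutations: int = 9999,
    seed: int | None = None,
) -> ADResult:
    """k-sample Anderson-Darling test.

    ``method='asymptotic'`` standardizes the criterion by its null mean
    (k - 1) and variance and interpolates the published critical-value
    table; ``method='permutation'`` recomputes the criterion over random
    relabellings of the pooled values (recommended for very small groups).
    """
    gs = _check_groups(groups)
    sizes = [g.size for g in gs]
    k = len(gs)
    crit = ad_criterion(gs, midrank=midrank)
    sigma = _ad_sigma(sizes)
    tstat = (crit - (k - 1)) / sigma

    if method == "asymptotic":
        p = _asymptotic_pvalue(tstat, k)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate(gs)
        edges = np.cumsum(sizes)[:-1]
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            parts = np.split(perm, edges)
            if ad_criterion(parts, midrank=midrank) >= crit:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError("method must be 'asymptotic' or 'permutation'")
    return ADResult(criterion=crit, standardized=tstat, pvalue=float(p))


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def pairwise_ad_posthoc(
    groups: Mapping[str, np.ndarray],
    pairs: Sequence[tuple[str, str]] = CANONICAL_PAIRS,
    midrank: bool = True,
    method: str = "asymptotic",
    seed: int | None = None,
) -> pd.DataFrame:
    """Post hoc two-sample AD tests for the specified pairs, Holm-adjusted.

    The default pairs are the four comparisons of the two-by-two design:
    adult stress within each rearing condition, and rearing condition within
    each adult treatment.
    """
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise KeyError(f"missing group label: {a if a not in groups else b}")
    rows = []
    for i, (a, b) in enumerate(pairs):
        res = ad_ksample([groups[a], groups[b]], midrank=midrank, method=method,
                         seed=None if seed is None else seed + i)
        rows.append((f"{a} vs {b}", res.criterion, res.standardized, res.pvalue))
    df = pd.DataFrame(rows, columns=["pair", "ad_criterion", "ad_standardized", "p_raw"])
    df["p_holm"] = holm_adjust(df["p_raw"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Hierarchical percentile bootstrap


@dataclass(frozen=True)
class BootstrapSpec:
    """Resampling protocol: 5,000 iterations and 2.5/97.5 percentiles by
    default; ``resample_unit`` picks the exchangeable unit ('cell', 'mouse'
    or 'event')."""

    n_iterations: int = 5000
    lower_percentile: float = 2.5
    upper_percentile: float = 97.5
    resample_unit: str = "cell"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.lower_percentile < self.upper_percentile < 100:
            raise ValueError("need 0 < lower < upper < 100")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.resample_unit not in ("cell", "mouse", "event"):
            raise ValueError("resample_unit must be 'cell', 'mouse' or 'event'")


@dataclass
class BootstrapResult:
    """Bootstrap group means/differences with percentile intervals."""

    group_stats: pd.DataFrame  # group, mean, ci_low, ci_high, n_units, n_events
    pair_stats: pd.DataFrame  # pair, mean_diff, ci_low, ci_high
    spec: BootstrapSpec


_UNIT_COLUMNS = {"cell": "cell_id", "mouse": "mouse_id", "event": None}


def _unit_arrays(sub: pd.DataFrame, value_col: str, unit_col: str | None):
    """Split one group's values by resampling unit.

    Returns (list of per-unit value arrays, equal-size matrix or None).
    """
    vals = sub[value_col].to_numpy(dtype=float)
    if unit_col is None:
        units = [np.array([v]) for v in vals]
        return units, vals.reshape(-1, 1)
    codes, _ = pd.factorize(sub[unit_col])
    units = [vals[codes == c] for c in range(codes.max() + 1)]
    sizes = {u.size for u in units}
    if len(sizes) == 1:
        return units, np.vstack(units)
    return units, None


def hierarchical_bootstrap(
    grouped: pd.DataFrame,
    spec: BootstrapSpec | None = None,
    statistic: Callable[[np.ndarray], float] = np.mean,
    pairs: Sequence[tuple[str, str]] = CANONICAL_PAIRS,
    value_col: str = "value",
    group_col: str = "group",
) -> BootstrapResult:
    """Design-aware percentile bootstrap of group statistics.

    Per iteration, units are drawn with replacement within each group, their
    events pooled, and the statistic (default mean) evaluated; pairwise
    differences are taken between the per-iteration group statistics.  Point
    estimates are averages over iterations; intervals are percentile
    intervals of the bootstrap distribution.  Intervals are not adjusted for
    multiplicity (only p-values are, upstream).
    """
    spec = spec or BootstrapSpec()
    spec.validate()
    unit_col = _UNIT_COLUMNS[spec.resample_unit]
    if unit_col is not None and unit_col not in grouped.columns:
        raise ValueError(f"column {unit_col!r} required for unit {spec.resample_unit!r}")

    labels = list(dict.fromkeys(grouped[group_col]))
    present_pairs = [(a, b) for a, b in pairs if a in labels and b in labels]
    rng = np.random.default_rng(spec.seed)

    stat_is_mean = statistic is np.mean
    boot = {}
    meta = {}
    for g in labels:
        sub = grouped[grouped[group_col] == g]
        units, matrix = _unit_arrays(sub, value_col, unit_col)
        n_units = len(units)
        if n_units == 0:
            raise ValueError(f"group {g!r} has no resampleable units")
        idx = rng.integers(0, n_units, size=(spec.n_iterations, n_units))
        if matrix is not None and stat_is_mean:
            # equal unit sizes: pooled mean = mean over the sampled rows
            boot[g] = matrix[idx].mean(axis=(1, 2))
        else:
            vals = np.empty(spec.n_iterations)
            for it in range(spec.n_iterations):
                pooled = np.concatenate([units[j] for j in idx[it]])
                vals[it] = statistic(pooled)
            boot[g] = vals
        meta[g] = (n_units, int(sub.shape[0]))

    q = (spec.lower_percentile, spec.upper_percentile)
    group_rows = []
    for g in labels:
        lo, hi = np.percentile(boot[g], q)
        group_rows.append((g, float(np.mean(boot[g])), float(lo), float(hi), *meta[g]))
    pair_rows = []
    for a, b in present_pairs:
        diff = boot[b] - boot[a]
        lo, hi = np.percentile(diff, q)
        pair_rows.append((f"{b} - {a}", float(np.mean(diff)), float(lo), float(hi)))

    return BootstrapResult(
        group_stats=pd.DataFrame(
            group_rows, columns=["group", "mean", "ci_low", "ci_high", "n_units", "n_events"]
        ),
        pair_stats=pd.DataFrame(pair_rows, columns=["pair", "mean_diff", "ci_low", "ci_high"]),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Model / Results front door


class GroupDistributionComparison:
    """Compare a pooled event metric across the four treatment groups.

    Built from a tidy per-event table (columns: value, group, and the
    nesting ids cell_id/mouse_id/dam_id as available), mirroring the
    model/results split of statsmodels: construct, then :meth:`fit`.

    Parameters
    ----------
    data : DataFrame
        One row per event.
    value_col, group_col : str
        Column names for the measured value and the treatment label.
    """

    def __init__(self, data: pd.DataFrame, value_col: str = "value", group_col: str = "group"):
        if data.empty:
            raise ValueError("empty data")
        self.data = data.reset_index(drop=True)
        self.value_col = value_col
        self.group_col = group_col
        self.group_labels = list(dict.fromkeys(self.data[group_col]))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "GroupDistributionComparison":
        return cls(data, **kw)

    def _group_values(self) -> dict[str, np.ndarray]:
        return {
            g: self.data.loc[self.data[self.group_col] == g, self.value_col].to_numpy(float)
            for g in self.group_labels
        }

    def fit(
        self,
        bootstrap: BootstrapSpec | None = None,
        pairs: Sequence[tuple[str, str]] | None = None,
        ad_method: str = "asymptotic",
        seed: int | None = None,
    ) -> "GroupComparisonResults":
        groups = self._group_values()
        if pairs is None:
            pairs = [p for p in CANONICAL_PAIRS if p[0] in groups and p[1] in groups]
        omnibus = ad_ksample(list(groups.values()), method=ad_method, seed=seed)
        posthoc = pairwise_ad_posthoc(groups, pairs=pairs, method=ad_method, seed=seed)
        spec = bootstrap or BootstrapSpec(seed=0 if seed is None else seed)
        boot = hierarchical_bootstrap(
            self.data, spec, pairs=pairs, value_col=self.value_col, group_col=self.group_col
        )
        return GroupComparisonResults(self, omnibus, posthoc, boot)


class GroupComparisonResults:
    """Results of :class:`GroupDistributionComparison.fit`."""

    def __init__(self, model, omnibus: ADResult, posthoc: pd.DataFrame, bootstrap: BootstrapResult):
        self.model = model
        self.omnibus = omnibus
        self.posthoc = posthoc
        self.bootstrap = bootstrap

    @property
    def omnibus_pvalue(self) -> float:
        return self.omnibus.pvalue

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-pair table: AD statistic, raw/Holm p, bootstrap effect."""
        df = self.posthoc.copy()
        pair_map = {}
        for _, row in self.bootstrap.pair_stats.iterrows():
            b, a = [s.strip() for s in row["pair"].split(" - ")]
            pair_map[f"{a} vs {b}"] = (row["mean_diff"], row["ci_low"], row["ci_high"])
        df[["mean_diff", "ci_low", "ci_high"]] = [
            pair_map.get(p, (np.nan, np.nan, np.nan)) for p in df["pair"]
        ]
        return df

    def summary(self) -> str:
        lines = ["Group distribution comparison (k-sample Anderson-Darling)"]
        lines.append("=" * 62)
        lines.append(
            f"Omnibus: criterion={self.omnibus.criterion:.4f}  "
            f"standardized={self.omnibus.standardized:.4f}  p={self.omnibus.pvalue:.4g}"
        )
        lines.append("")
        lines.append("Group means (percentile bootstrap):")
        for _, r in self.bootstrap.group_stats.iterrows():
            lines.append(
                f"  {r['group']:<10} mean={r['mean']:.4f}  "
                f"95% CI [{r['ci_low']:.4f}, {r['ci_high']:.4f}]  "
                f"(units={r['n_units']}, events={r['n_events']})"
            )
        lines.append("")
        lines.append("Pairwise comparisons (Holm-adjusted p; unadjusted CIs):")
        for _, r in self.to_frame().iterrows():
            lines.append(
                f"  {r['pair']:<24} AD={r['ad_criterion']:.4f}  "
                f"p={r['p_raw']:.4g}  p_holm={r['p_holm']:.4g}  "
                f"diff={r['mean_diff']:.4f} [{r['ci_low']:.4f}, {r['ci_high']:.4f}]"
            )
        spec = self.bootstrap.spec
        lines.append("")
        lines.append(
            f"Bootstrap: {spec.n_iterations} iterations, unit={spec.resample_unit}, "
            f"percentiles [{spec.lower_percentile}, {spec.upper_percentile}], seed={spec.seed}"
        )
        return "\n".join(lines)

    def plot_ecdf(self, ax=None):
        """Cumulative probability distribution per group (diagnostic plot)."""
        import matplotlib.pyplot as plt

        from .event_metrics import cumulative_distribution

        if ax is None:
            _, ax = plt.subplots()
        for g, vals in self.model._group_values().items():
            x, p = cumulative_distribution(vals)
            ax.step(x, p, where="post", label=g)
        ax.set_xlabel(self.model.value_col)
        ax.set_ylabel("cumulative probability")
        ax.legend()
        return ax
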