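"""k-sample AD test, Holm adjustment and the hierarchical bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stressaxis.resampling_stats import (
    BootstrapSpec,
    GroupDistributionComparison,
    ad_criterion,
    ad_ksample,
    hierarchical_bootstrap,
    holm_adjust,
    pairwise_ad_posthoc,
)

GROUPS4 = ("STD-CON", "STD-ALPS", "LBN-CON", "LBN-ALPS")


def bruteforce_ad_midrank(groups):
    """Direct, unvectorized evaluation of the midrank AD criterion."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    N = pooled.size
    zs = sorted(set(pooled.tolist()))
    total = 0.0
    for g in groups:
        g = np.asarray(g, float)
        ni = g.size
        inner = 0.0
        for z in zs:
            lj = sum(1 for v in pooled if v == z)
            bj = sum(1 for v in pooled if v < z) + lj / 2.0
            fij = sum(1 for v in g if v == z)
            mij = sum(1 for v in g if v < z) + fij / 2.0
            denom = bj * (N - bj) - N * lj / 4.0
            inner += (lj / N) * (N * mij - ni * bj) ** 2 / denom
        total += inner / ni
    return (N - 1) / N * total


class TestAdKsample:
    def test_matches_bruteforce_double_sum(self, rng):
        a = rng.normal(0, 1, 5).round(1)
        b = rng.normal(1, 1, 5).round(1)
        assert ad_criterion([a, b]) == pytest.approx(bruteforce_ad_midrank([a, b]), rel=1e-12)
        c = rng.normal(0, 2, 4).round(1)
        assert ad_criterion([a, b, c]) == pytest.approx(
            bruteforce_ad_midrank([a, b, c]), rel=1e-12
        )

    def test_rank_invariance_under_monotone_transform(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)
        r1 = ad_ksample([a, b])
        r2 = ad_ksample([np.exp(a), np.exp(b)])  # strictly increasing transform
        assert r1.criterion == pytest.approx(r2.criterion, rel=1e-12)
        assert r1.pvalue == pytest.approx(r2.pvalue, rel=1e-12)

    def test_agrees_with_reference_implementation(self, rng):
        from scipy.stats import anderson_ksamp

        groups = [rng.normal(0, 1, 20), rng.normal(0.3, 1, 25),
                  rng.normal(0, 1.4, 15), rng.normal(0.5, 0.8, 30)]
        mine = ad_ksample(groups)
        try:
            ref = anderson_ksamp(groups, variant="midrank")
        except TypeError:  # older scipy
            ref = anderson_ksamp(groups, midrank=True)
        assert mine.standardized == pytest.approx(ref.statistic, rel=1e-9)
        assert mine.pvalue == pytest.approx(ref.pvalue, rel=1e-6)

    def test_asymptotic_close_to_permutation(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
        asym = ad_ksample([a, b]).pvalue
        perm = ad_ksample([a, b], method="permutation", n_permutations=10_000, seed=0).pvalue
        assert abs(asym - perm) < 0.02

    def test_separated_samples_significant_by_permutation(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)
        res = ad_ksample([a, b], method="permutation", n_permutations=10_000, seed=1)
        assert res.pvalue < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ad_ksample([np.array([1.0]), np.array([])])

    def test_null_pvalues_calibrated(self, rng):
        # type-I error at alpha=0.05 over null datasets stays near nominal
        rej = sum(
            ad_ksample([rng.normal(0, 1, 25) for _ in range(4)]).pvalue < 0.05
            for _ in range(400)
        )
        assert 0.02 < rej / 400 < 0.08


class TestHolm:
    def test_hand_computed_example(self):
        assert np.allclose(holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    def test_four_pair_example_with_monotonicity(self):
        got = holm_adjust([0.001, 0.20, 0.50, 0.70])
        assert np.allclose(got, [0.004, 0.60, 1.00, 1.00])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]).tolist() == [0.2]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_bounded_by_input_and_bonferroni(self, ps):
        adj = holm_adjust(ps)
        bonf = np.minimum(np.asarray(ps) * len(ps), 1.0)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= bonf + 1e-12)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        ps = rng.uniform(0, 1, 8)
        _, ref, _, _ = multipletests(ps, method="holm")
        assert np.allclose(holm_adjust(ps), ref)


class TestPairwisePosthoc:
    def _groups(self, rng, shift=0.0):
        vals = {g: rng.normal(0, 1, 30) for g in GROUPS4}
        vals["STD-ALPS"] = vals["STD-ALPS"] + shift
        return vals

    def test_identical_groups_all_adjusted_to_one(self):
        x = np.arange(30.0)
        res = pairwise_ad_posthoc({g: x.copy() for g in GROUPS4})
        assert (res["p_holm"] >= 0.99).all()
        assert list(res["pair"]) == [
            "STD-CON vs STD-ALPS", "LBN-CON vs LBN-ALPS",
            "STD-CON vs LBN-CON", "STD-ALPS vs LBN-ALPS",
        ]

    def test_smallest_p_multiplied_by_four(self, rng):
        vals = self._groups(rng, shift=4.0)
        res = pairwise_ad_posthoc(vals)
        i = res["p_raw"].idxmin()
        assert res.loc[i, "p_holm"] == pytest.approx(min(4 * res.loc[i, "p_raw"], 1.0))

    def test_missing_label_rejected(self, rng):
        vals = self._groups(rng)
        del vals["LBN-CON"]
        with pytest.raises(KeyError):
            pairwise_ad_posthoc(vals)


class TestHierarchicalBootstrap:
    @staticmethod
    def _frame(rng, n_cells=10, events_per_cell=5, groups=("A", "B"), shift=0.0):
        rows = []
        for gi, g in enumerate(groups):
            for c in range(n_cells):
                vals = rng.normal(gi * shift, 1, events_per_cell)
                for v in vals:
                    rows.append((v, f"{g}-c{c}", f"{g}-m{c // 2}", f"{g}-d0", g))
        return pd.DataFrame(rows, columns=["value", "cell_id", "mouse_id", "dam_id", "group"])

    def test_constant_group_has_zero_width_ci(self):
        df = pd.DataFrame({
            "value": [3.0] * 12, "cell_id": [f"c{i}" for i in range(12)],
            "group": ["A"] * 12,
        })
        res = hierarchical_bootstrap(df, BootstrapSpec(n_iterations=200, seed=0), pairs=[])
        row = res.group_stats.iloc[0]
        assert row["ci_low"] == row["ci_high"] == row["mean"] == 3.0

    def test_defaults_match_stated_protocol(self):
        spec = BootstrapSpec()
        assert spec.n_iterations == 5000
        assert (spec.lower_percentile, spec.upper_percentile) == (2.5, 97.5)

    def test_event_unit_reduces_to_ordinary_bootstrap(self, rng):
        # one event per cell: resampling cells == resampling events
        df = self._frame(rng, n_cells=25, events_per_cell=1)
        a = hierarchical_bootstrap(df, BootstrapSpec(n_iterations=500, seed=3,
                                                     resample_unit="cell"), pairs=[("A", "B")])
        b = hierarchical_bootstrap(df, BootstrapSpec(n_iterations=500, seed=3,
                                                     resample_unit="event"), pairs=[("A", "B")])
        pd.testing.assert_frame_equal(a.group_stats, b.group_stats)
        pd.testing.assert_frame_equal(a.pair_stats, b.pair_stats)

    def test_ci_width_shrinks_with_sample_size(self, rng):
        widths = []
        for n in (10, 40, 160):
            df = self._frame(rng, n_cells=n, events_per_cell=1)
            res = hierarchical_bootstrap(df, BootstrapSpec(n_iterations=500, seed=1),
                                         pairs=[("A", "B")])
            row = res.pair_stats.iloc[0]
            widths.append(row["ci_high"] - row["ci_low"])
        assert widths[0] > widths[1] > widths[2]

    def test_reproducible_given_seed(self, rng):
        df = self._frame(rng)
        r1 = hierarchical_bootstrap(df, BootstrapSpec(n_iterations=100, seed=9), pairs=[("A", "B")])
        r2 = hierarchical_bootstrap(df, BootstrapSpec(n_iterations=100, seed=9), pairs=[("A", "B")])
        pd.testing.assert_frame_equal(r1.pair_stats, r2.pair_stats)

    def test_difference_ci_coverage(self, rng):
        # scaled-down coverage check; the full-size one lives in acceptance
        delta, cover, nd = 0.5, 0, 150
        for _ in range(nd):
            a = rng.normal(0, 1, 30)
            b = rng.normal(delta, 1, 30)
            df = pd.DataFrame({"value": np.concatenate([a, b]),
                               "group": ["A"] * 30 + ["B"] * 30,
                               "cell_id": [f"c{j}" for j in range(60)]})
            res = hierarchical_bootstrap(
                df, BootstrapSpec(n_iterations=500, seed=int(rng.integers(2**31))),
                pairs=[("A", "B")])
            lo, hi = res.pair_stats.loc[0, ["ci_low", "ci_high"]]
            cover += lo <= delta <= hi
        assert 0.90 <= cover / nd <= 0.99

    def test_unequal_cluster_sizes_use_pooled_events(self, rng):
        rows = []
        for c, vals in enumerate(([1.0], [2.0, 4.0], [3.0, 5.0, 7.0])):
            for v in vals:
                rows.append((v, f"c{c}", "A"))
        df = pd.DataFrame(rows, columns=["value", "cell_id", "group"])
        res = hierarchical_bootstrap(df, BootstrapSpec(n_iterations=4000, seed=0), pairs=[])
        # enumeration oracle: all 27 equally likely cell draws, pooled means
        import itertools

        units = [(1.0, 1), (6.0, 2), (15.0, 3)]
        pooled = [
            sum(u[0] for u in draw) / sum(u[1] for u in draw)
            for draw in itertools.product(units, repeat=3)
        ]
        assert res.group_stats.loc[0, "mean"] == pytest.approx(np.mean(pooled), abs=0.1)


class TestModelResultsFrontDoor:
    def test_fit_summary_and_frame(self, rng):
        rows = []
        for g in GROUPS4:
            shift = 1.0 if g.endswith("ALPS") else 0.0
            for c in range(12):
                for v in rng.normal(shift, 1, 4):
                    rows.append((v, f"{g}-c{c}", f"{g}-m{c//2}", f"{g}-d0", g))
        df = pd.DataFrame(rows, columns=["value", "cell_id", "mouse_id", "dam_id", "group"])
        res = GroupDistributionComparison(df).fit(
            bootstrap=BootstrapSpec(n_iterations=300, seed=0))
        assert res.omnibus_pvalue < 0.01
        tab = res.to_frame()
        assert set(tab.columns) >= {"pair", "p_raw", "p_holm", "mean_diff", "ci_low", "ci_high"}
        assert (tab["p_holm"] >= tab["p_raw"] - 1e-12).all()
        # stress pairs separated, control pairs not
        by_pair = tab.set_index("pair")
        assert by_pair.loc["STD-CON vs STD-ALPS", "p_holm"] < 0.05
        assert by_pair.loc["STD-CON vs LBN-CON", "p_holm"] > 0.05
        txt = res.summary()
        assert "Omnibus" in txt and "Holm" in txt

    def test_ci_brackets_point_estimate(self, rng):
        df = pd.DataFrame({"value": rng.normal(0, 1, 60),
                           "cell_id": [f"c{i//3}" for i in range(60)],
                           "group": ["A"] * 30 + ["B"] * 30})
        res = GroupDistributionComparison(df).fit(bootstrap=BootstrapSpec(n_iterations=400, seed=2))
        g = res.bootstrap.group_stats
        assert ((g["ci_low"] <= g["mean"]) & (g["mean"] <= g["ci_high"])).all()
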