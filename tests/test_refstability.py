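"""Reference-gene prescreen, the four stability methods, rank aggregation."""

import numpy as np
import pandas as pd
import pytest

from mirnaome.refstability import (
    aggregate_geomean_ranks,
    bestkeeper_stats,
    cq_to_quantities,
    delta_ct_stability,
    genorm_m,
    normfinder_stability,
    prescreen_candidates,
    rsd,
    stability_report,
)
from mirnaome.synthetic_data import simulate_cq


class TestRsd:
    def test_constant_vector_is_zero(self):
        assert rsd([5, 5, 5]) == 0.0

    def test_hand_computed_example(self):
        assert rsd([90, 110]) == pytest.approx(0.141421, abs=1e-5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 100, 20)
        assert rsd(3.7 * x) == pytest.approx(rsd(x), rel=1e-12)

    def test_nonpositive_mean_raises(self):
        with pytest.raises(ValueError):
            rsd([-1, 1])


class TestPrescreen:
    def _matrix(self, mean, rsd_target):
        base = np.array([1 - rsd_target, 1 + rsd_target])  # sd = rsd*mean*sqrt(2)/?
        # construct exact mean and RSD: values mean*(1 +/- d) with
        # sd(n-1) = mean*d*sqrt(2); choose d = rsd/sqrt(2)
        d = rsd_target / np.sqrt(2)
        return pd.DataFrame({"s1": [mean * (1 - d)], "s2": [mean * (1 + d)]}, index=["m"])

    @pytest.mark.parametrize("mean,r,kept", [
        (2_500, 0.0, True),       # abundance window is inclusive
        (130_000, 0.0, True),
        (2_000, 0.10, False),
        (140_000, 0.10, False),
        (10_000, 0.299, True),    # RSD ceiling
        (10_000, 0.301, False),
    ])
    def test_window_and_rsd_boundaries(self, mean, r, kept):
        out = prescreen_candidates(self._matrix(mean, r))
        assert (len(out) == 1) is kept


class TestGeNorm:
    def _q(self, arr, names=None):
        names = names or [f"c{i}" for i in range(np.asarray(arr).shape[1])]
        return pd.DataFrame(arr, columns=names)

    def test_proportional_candidates_have_zero_pair_variation(self):
        base = np.array([1.0, 2.0, 4.0, 8.0])
        q = self._q(np.column_stack([base, 3 * base, base ** 1.5]))
        m = genorm_m(q)
        # c0 and c1 are proportional: their pairwise V is 0, so both M values
        # equal the SD against c2 only... both are strictly below c2's M
        assert m["c0"] == pytest.approx(m["c1"], rel=1e-9)
        assert m["c2"] > m["c0"]

    def test_all_identical_gives_zero_m(self):
        q = self._q(np.tile([[1.0], [2.0], [4.0]], (1, 3)))
        assert np.allclose(genorm_m(q), 0.0)

    def test_noisy_candidate_has_largest_m(self):
        rng = np.random.default_rng(1)
        base = 2.0 ** rng.normal(0, 0.1, 30)
        cols = {f"c{i}": base * 2.0 ** rng.normal(0, 0.05, 30) for i in range(3)}
        cols["noisy"] = base * 2.0 ** rng.normal(0, 1.0, 30)
        m = genorm_m(pd.DataFrame(cols))
        assert m.idxmax() == "noisy"

    def test_fewer_than_three_candidates_raises(self):
        with pytest.raises(ValueError):
            genorm_m(pd.DataFrame({"a": [1, 2], "b": [1, 2]}))

    def test_global_sample_shift_invariance(self):
        """Adding a per-sample constant (in log space) to all candidates
        leaves geNorm M and delta-Ct scores unchanged."""
        rng = np.random.default_rng(2)
        cq = []
        shift = {f"s{i}": rng.uniform(-2, 2) for i in range(10)}
        for s in shift:
            for a in "abcd":
                cq.append({"sample": s, "assay": a,
                           "Cq": 20 + rng.normal(0, 0.3)})
        cq = pd.DataFrame(cq)
        cq_shifted = cq.copy()
        cq_shifted["Cq"] = cq_shifted["Cq"] + cq_shifted["sample"].map(shift)
        for table_fn in (genorm_m,):
            a = table_fn(cq_to_quantities(cq))
            b = table_fn(cq_to_quantities(cq_shifted))
            assert np.allclose(a, b, atol=1e-9)
        assert np.allclose(delta_ct_stability(cq), delta_ct_stability(cq_shifted))


class TestNormFinder:
    def test_all_constant_gives_zero(self):
        q = pd.DataFrame(np.ones((6, 3)), columns=list("abc"),
                         index=[f"s{i}" for i in range(6)])
        assert np.allclose(normfinder_stability(q), 0.0)

    def test_group_shifted_candidate_is_least_stable(self):
        rng = np.random.default_rng(3)
        idx = [f"s{i}" for i in range(12)]
        groups = {s: ("g1" if i < 6 else "g2") for i, s in enumerate(idx)}
        data = {a: 2.0 ** rng.normal(0, 0.05, 12) for a in "abc"}
        shifted = np.concatenate([np.zeros(6), np.full(6, 2.0)])
        data["shifted"] = 2.0 ** (rng.normal(0, 0.05, 12) + shifted)
        q = pd.DataFrame(data, index=idx)
        rho = normfinder_stability(q, groups)
        assert rho.idxmax() == "shifted"

    def test_rho_increases_with_noise(self):
        rng = np.random.default_rng(4)
        medians = []
        for sd in (0.05, 0.3, 1.0):
            rhos = []
            for _ in range(40):
                data = {a: 2.0 ** rng.normal(0, 0.05, 10) for a in "abc"}
                data["x"] = 2.0 ** rng.normal(0, sd, 10)
                rhos.append(normfinder_stability(pd.DataFrame(data))["x"])
            medians.append(np.median(rhos))
        assert medians[0] < medians[1] < medians[2]

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            normfinder_stability(pd.DataFrame({"a": [1.0], "b": [1.0]}))


class TestBestKeeper:
    def _cq(self, cols):
        rows = []
        for i in range(len(next(iter(cols.values())))):
            for a, v in cols.items():
                rows.append({"sample": f"s{i}", "assay": a, "Cq": v[i]})
        return pd.DataFrame(rows)

    def test_constant_candidate_ranks_best(self):
        cq = self._cq({"flat": [20, 20, 20, 20], "wob": [19, 21, 20, 22],
                       "mid": [20, 20.5, 19.5, 20.2]})
        bk = bestkeeper_stats(cq)
        assert bk["sd"].idxmin() == "flat"
        assert bk.loc["flat", "sd"] == 0.0

    def test_mirrored_deviations_rank_equally(self):
        cq = self._cq({"up": [20, 21, 22, 23], "down": [26, 25, 24, 23]})
        bk = bestkeeper_stats(cq)
        assert bk.loc["up", "sd"] == pytest.approx(bk.loc["down", "sd"])

    def test_constant_index_gives_missing_r(self):
        cq = self._cq({"up": [20, 21], "down": [22, 21]})
        bk = bestkeeper_stats(cq)
        assert np.isnan(bk["r"]).all()   # index flat -> r undefined


class TestDeltaCt:
    def _cq(self, cols):
        rows = []
        n = len(next(iter(cols.values())))
        for i in range(n):
            for a, v in cols.items():
                rows.append({"sample": f"s{i}", "assay": a, "Cq": v[i]})
        return pd.DataFrame(rows)

    def test_constant_offset_pair_has_zero_sd(self):
        cq = self._cq({"a": [20, 21, 22], "b": [23, 24, 25]})
        out = delta_ct_stability(cq)
        assert np.allclose(out, 0.0)

    def test_noisy_candidate_scores_worst(self):
        rng = np.random.default_rng(5)
        base = rng.normal(20, 0.5, 20)
        cq = self._cq({"a": base + 1, "b": base + 2,
                       "noisy": base + rng.normal(0, 2, 20)})
        assert delta_ct_stability(cq).idxmax() == "noisy"

    def test_symmetric_under_relabeling(self):
        cq = self._cq({"a": [20, 21, 23], "b": [22, 21, 20], "c": [19, 25, 21]})
        out1 = delta_ct_stability(cq)
        cq2 = cq.replace({"assay": {"a": "c", "c": "a"}})
        out2 = delta_ct_stability(cq2)
        assert out1["a"] == pytest.approx(out2["c"])


class TestAggregation:
    @pytest.mark.parametrize("ranks,expected", [
        ((2, 2, 2, 2), 2.0),
        ((1, 1, 1, 3), 1.3161),
        ((1, 2, 3, 4), 2.2134),
    ])
    def test_geometric_mean_arithmetic(self, ranks, expected):
        df = pd.DataFrame([ranks, (4, 4, 4, 4)], index=["x", "y"],
                          columns=["g", "n", "b", "d"])
        agg = aggregate_geomean_ranks(df)
        assert agg.loc["x", "geomean_rank"] == pytest.approx(expected, abs=1e-4)

    def test_missing_method_raises(self):
        df = pd.DataFrame({"g": [1, 2], "n": [np.nan, 1]}, index=["x", "y"])
        with pytest.raises(ValueError):
            aggregate_geomean_ranks(df)

    def test_report_order_invariant_to_candidate_order(self):
        cq = simulate_cq(["a", "b", "c", "u"], ["g1", "g2"], seed=6,
                         noise_sd={"a": 0.1, "b": 0.1, "c": 0.1, "u": 1.2})
        rep1 = stability_report(cq)
        cq2 = cq.sort_values("assay", ascending=False).reset_index(drop=True)
        rep2 = stability_report(cq2)
        assert rep1["geomean_rank"].sort_index().equals(rep2["geomean_rank"].sort_index())


def test_designed_unstable_candidate_ranks_last_everywhere():
    """20 simulated Cq tables: the inflated-SD + group-effect candidate is
    ranked last by all four methods and by the aggregate."""
    groups = [f"g{i}" for i in range(5)]
    for seed in range(20):
        cq = simulate_cq(
            ["r1", "r2", "r3", "unstable"], groups, seed=seed,
            noise_sd={"r1": 0.1, "r2": 0.1, "r3": 0.1, "unstable": 1.5},
            group_effect={"unstable": {g: (2.0 if i % 2 else -2.0)
                                       for i, g in enumerate(groups)}})
        sample_groups = dict(zip(cq["sample"], cq["group"]))
        rep = stability_report(cq, groups=sample_groups)
        for col in ("genorm", "normfinder", "bestkeeper", "delta_ct"):
            assert rep[col].idxmax() == "unstable", (seed, col)
        assert rep["geomean_rank"].idxmax() == "unstable"


def test_zero_noise_gives_zero_statistics():
    """With zero assay noise and no sample effect every statistic is zero."""
    cq = simulate_cq(["a", "b", "c"], ["g1", "g2"], seed=7,
                     noise_sd={"a": 0.0, "b": 0.0, "c": 0.0}, sample_effect_sd=0.0)
    rep = stability_report(cq)
    assert np.allclose(rep[["genorm_M", "normfinder_rho", "bestkeeper_sd",
                            "delta_ct_sd"]], 0.0)
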