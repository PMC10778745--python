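"""NB Wald test, BH adjustment, contrasts, and the reporting filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirnaome.diffexp import (
    Contrast,
    bh_adjust,
    custom_contrast,
    de_table,
    define_contrasts,
    estimate_dispersion,
    run_de,
    wald_lfc_test,
)

GROUPS = ["eyed_egg", "larvae_2dph", "larvae_15dph", "larvae_26dph",
          "fingerling_3g", "fingerling_35g", "liver", "head_kidney", "spleen", "gills"]


def _sheet():
    rows = [{"sample": f"{g}_r{i}", "group": g} for g in GROUPS for i in (1, 2)]
    return pd.DataFrame(rows)


def _nb_counts(rng, mu, alpha, n):
    """NB draws parameterized by mean and dispersion (var = mu + alpha mu^2)."""
    mu = np.broadcast_to(np.asarray(mu, float)[:, None], (len(mu), n))
    if alpha <= 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


class TestContrasts:
    def test_study_design_yields_five_contrasts(self):
        contrasts = define_contrasts(_sheet())
        names = [c.name for c in contrasts]
        assert names == ["early_vs_larvae", "fingerling_3g_vs_35g",
                         "head_kidney_vs_rest", "spleen_vs_rest", "gills_vs_rest"]
        early = contrasts[0]
        assert len(early.samples_a) == 4 and len(early.samples_b) == 4
        organ = contrasts[2]
        assert len(organ.samples_a) == 2 and len(organ.samples_b) == 6

    def test_liver_refused_as_focal_organ(self):
        with pytest.raises(ValueError, match="liver"):
            define_contrasts(_sheet(), focal_organs=("liver",))

    def test_missing_group_is_named(self):
        sheet = _sheet()
        sheet = sheet[sheet["group"] != "spleen"]
        with pytest.raises(ValueError, match="spleen"):
            define_contrasts(sheet)

    def test_custom_contrast_accepted_verbatim(self):
        con = custom_contrast("x", ["a1", "a2"], ["b1", "b2"])
        assert (con.samples_a, con.samples_b) == (["a1", "a2"], ["b1", "b2"])

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            Contrast("bad", ["s1", "s2"], ["s2", "s3"])


class TestDispersion:
    def test_poisson_counts_hit_the_floor(self):
        """variance ~= mean -> alpha near the floor (median < 0.01)."""
        rng = np.random.default_rng(0)
        mu = rng.uniform(50, 500, 1000)
        counts = pd.DataFrame(_nb_counts(rng, mu, 0.0, 8),
                              columns=[f"s{i}" for i in range(8)])
        con = Contrast("c", [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        alpha = estimate_dispersion(counts, con)
        assert alpha.median() < 0.01

    def test_underdispersed_counts_floor_exactly(self):
        counts = pd.DataFrame({"a": [100, 100], "b": [100, 100],
                               "c": [100, 100], "d": [100, 100]}, index=["g1", "g2"]).T
        con = Contrast("c", ["a", "b"], ["c", "d"])
        alpha = estimate_dispersion(counts.T, con)
        assert (alpha == 1e-8).all()

    def test_nb_dispersion_recovery(self):
        """alpha = 0.2 at n = 20 per group: median estimate in [0.1, 0.3]."""
        rng = np.random.default_rng(1)
        mu = rng.uniform(100, 1000, 1000)
        counts = pd.DataFrame(_nb_counts(rng, mu, 0.2, 40),
                              columns=[f"s{i}" for i in range(40)])
        con = Contrast("c", [f"s{i}" for i in range(20)], [f"s{i}" for i in range(20, 40)])
        alpha = estimate_dispersion(counts, con)
        assert 0.1 <= alpha.median() <= 0.3


class TestWald:
    def test_identical_means_give_null_statistics(self):
        counts = pd.DataFrame({"a1": [100], "a2": [100], "b1": [100], "b2": [100]})
        con = Contrast("c", ["a1", "a2"], ["b1", "b2"])
        res = wald_lfc_test(counts, con, alpha=0.1)
        assert res["log2fc"].iloc[0] == 0.0
        assert res["wald"].iloc[0] == 0.0
        assert res["pvalue"].iloc[0] == 1.0

    def test_planted_fourfold_change_recovered(self):
        rng = np.random.default_rng(2)
        n_genes = 500
        mu_a = np.full(n_genes, 400.0)
        a = _nb_counts(rng, mu_a, 0.01, 4)
        b = _nb_counts(rng, mu_a * 4, 0.01, 4)
        counts = pd.DataFrame(np.hstack([a, b]),
                              columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        con = Contrast("c", [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)])
        res = wald_lfc_test(counts, con, alpha=0.01)
        assert res["log2fc"].mean() == pytest.approx(2.0, abs=0.1)

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(0, 500, (200, 8)),
                              columns=[f"s{i}" for i in range(8)])
        fwd = Contrast("f", [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        rev = Contrast("r", [f"s{i}" for i in range(4, 8)], [f"s{i}" for i in range(4)])
        a = wald_lfc_test(counts, fwd, alpha=0.1)
        b = wald_lfc_test(counts, rev, alpha=0.1)
        ok = ~a["untestable"]
        assert np.allclose(a.loc[ok, "log2fc"], -b.loc[ok, "log2fc"])
        assert np.allclose(a.loc[ok, "pvalue"], b.loc[ok, "pvalue"])

    def test_null_pvalues_approximately_uniform(self):
        """No-effect NB simulation at the true dispersion: KS p > 0.01."""
        rng = np.random.default_rng(4)
        mu = rng.uniform(200, 1000, 2000)
        counts = pd.DataFrame(_nb_counts(rng, mu, 0.1, 8),
                              columns=[f"s{i}" for i in range(8)])
        con = Contrast("c", [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        res = wald_lfc_test(counts, con, alpha=0.1)
        ks = stats.kstest(res["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_all_zero_rows_flagged_untestable(self):
        counts = pd.DataFrame({"a1": [0], "a2": [0], "b1": [0], "b2": [0]})
        con = Contrast("c", ["a1", "a2"], ["b1", "b2"])
        res = wald_lfc_test(counts, con, alpha=0.1)
        assert bool(res["untestable"].iloc[0])
        assert np.isnan(res["pvalue"].iloc[0])


def brute_force_bh(p):
    """Literal step-up definition: padj_(i) = min_{j>=i} min(1, m p_(j)/j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    for rank_idx, i in enumerate(order):
        candidates = [min(1.0, m * p[order[j]] / (j + 1)) for j in range(rank_idx, m)]
        out[i] = min(candidates)
    return out


class TestBH:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = np.round(rng.random(m), 4)
            assert np.allclose(bh_adjust(p), brute_force_bh(list(p))), p

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30))
    def test_property_matches_brute_force(self, p):
        assert np.allclose(bh_adjust(p), brute_force_bh(p))


class TestFilters:
    def _run(self, mean_a, mean_b, dominance=None, n=4):
        rng = np.random.default_rng(6)
        cols_a = [f"a{i}" for i in range(n)]
        cols_b = [f"b{i}" for i in range(n)]
        data = {c: [mean_a] for c in cols_a} | {c: [mean_b] for c in cols_b}
        counts = pd.DataFrame(data, index=["g"], dtype=float)
        con = Contrast("c", cols_a, cols_b)
        return run_de(counts, con, dominance or {}, alpha=1e-8)

    def test_low_count_boundary(self):
        assert bool(self._run(29.0, 29.0)["low_count"].iloc[0])
        assert not bool(self._run(30.0, 29.0)["low_count"].iloc[0])

    def test_small_effect_excluded_despite_significance(self):
        res = self._run(1000.0, 1000.0 * 2 ** 0.99)
        assert not bool(res["significant"].iloc[0])
        assert bool(res["small_effect"].iloc[0])

    def test_passenger_arm_excluded(self):
        res = self._run(1000.0, 8000.0, dominance={"g": "passenger"})
        assert not bool(res["significant"].iloc[0])
        assert bool(res["passenger"].iloc[0])

    def test_clean_large_effect_is_significant(self):
        res = self._run(1000.0, 4000.0)
        assert bool(res["significant"].iloc[0])
        assert de_table(res).shape[0] == 1


class TestErrorControlAndPower:
    def test_null_fdr_and_planted_effect_recovery(self):
        """2,000 matures, n=4v4, alpha=0.1: null padj<=0.05 fraction <= 0.05;
        planted |lfc|=2 at baseMean >= 100 recovered with sensitivity >= 0.9
        and empirical FDR <= 0.1 under the reporting filters."""
        rng = np.random.default_rng(7)
        n_genes, n = 2000, 4
        mu = rng.uniform(100, 2000, n_genes)
        true_de = np.zeros(n_genes, dtype=bool)
        true_de[:200] = True
        lfc_sign = np.where(rng.random(200) < 0.5, 1.0, -1.0)
        mu_b = mu.copy()
        mu_b[:200] = mu[:200] * (2.0 ** (2.0 * lfc_sign))
        a = _nb_counts(rng, mu, 0.1, n)
        b = _nb_counts(rng, mu_b, 0.1, n)
        counts = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)])
        con = Contrast("c", [f"a{i}" for i in range(n)], [f"b{i}" for i in range(n)])

        null_res = run_de(counts[~true_de].copy(), con)
        assert (null_res["padj"] <= 0.05).mean() <= 0.05

        res = run_de(counts, con)
        called = res["significant"].to_numpy()
        sens = called[:200].mean()
        fdr = (called & ~true_de).sum() / max(called.sum(), 1)
        assert sens >= 0.9
        assert fdr <= 0.1
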