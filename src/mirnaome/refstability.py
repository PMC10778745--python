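"""Reference-gene stability: prescreen, four algorithms, rank aggregation.

Candidate reference miRNAs are prescreened from sequencing data (moderate
to high abundance, 2,500-130,000 normalized counts, and relative standard
deviation <= 0.3).  Stability of qPCR candidates is then scored by four
established methods and the rankings combined RefFinder-style as the
geometric mean of the four per-method ranks (average ranks on ties):

* geNorm M — mean SD of pairwise log2 expression ratios (lower = stabler);
* NormFinder — model-based variance decomposition (with groups: |intergroup
  effect| plus the intragroup-variance SE term; without: the gene-specific
  variance component after removing the shared sample effect);
* BestKeeper — SD and CV of raw Cq plus correlation with the BestKeeper
  index (per-sample mean Cq); ranked by ascending SD;
* delta-Ct — mean over partners of the SD of pairwise Cq differences.

Expression enters geNorm/NormFinder as relative quantities
q = E^(Cq_min - Cq) per assay (E the assay efficiency, default 2.0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def rsd(values) -> float:
    """Relative standard deviation (coefficient of variation), SD(n-1)/mean."""
    x = np.asarray(values, dtype=float)
    mean = x.mean()
    if mean <= 0:
        raise ValueError("RSD undefined for non-positive mean")
    if x.size < 2:
        return 0.0
    return float(x.std(ddof=1) / mean)


def prescreen_candidates(norm_counts: pd.DataFrame, low: float = 2_500.0,
                         high: float = 130_000.0, max_rsd: float = 0.3) -> pd.DataFrame:
    """Matures with overall mean in [low, high] and RSD <= max_rsd (inclusive)."""
    means = norm_counts.mean(axis=1)
    sds = norm_counts.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsds = np.where(means > 0, sds / means, np.inf)
    keep = (means >= low) & (means <= high) & (rsds <= max_rsd)
    out = pd.DataFrame({"mean": means, "rsd": rsds}, index=norm_counts.index)
    return out[keep].sort_values("rsd")


def cq_to_quantities(cq: pd.DataFrame, efficiencies: dict[str, float] | None = None,
                     default_efficiency: float = 2.0) -> pd.DataFrame:
    """Relative quantities q = E^(Cq_min - Cq), samples x assays.

    ``cq`` is a long table with columns sample/assay/Cq.
    """
    wide = cq.pivot_table(index="sample", columns="assay", values="Cq")
    effs = {a: (efficiencies or {}).get(a, default_efficiency) for a in wide.columns}
    q = pd.DataFrame(index=wide.index, columns=wide.columns, dtype=float)
    for a in wide.columns:
        q[a] = np.power(effs[a], wide[a].min() - wide[a])
    return q


def genorm_m(quantities: pd.DataFrame) -> pd.Series:
    """geNorm expression stability M per candidate (single pass, no exclusion).

    M_j = mean over k != j of SD_samples(log2(q_j / q_k)).
    """
    if quantities.shape[1] < 3:
        raise ValueError("geNorm needs at least 3 candidates")
    if quantities.shape[0] < 2:
        raise ValueError("geNorm needs at least 2 samples")
    logq = np.log2(quantities.to_numpy(float))
    n = logq.shape[1]
    m_values = []
    for j in range(n):
        sds = [np.std(logq[:, j] - logq[:, k], ddof=1) for k in range(n) if k != j]
        m_values.append(float(np.mean(sds)))
    return pd.Series(m_values, index=quantities.columns, name="genorm_M")


def genorm_pairwise_v(quantities: pd.DataFrame, pair: tuple[str, str]) -> float:
    """Pairwise variation V of a two-gene combination (SD of their log2 ratio).

    Used as an approximation of the two-gene combined stability value.
    """
    logr = np.log2(quantities[pair[0]] / quantities[pair[1]])
    return float(np.std(logr, ddof=1))


def normfinder_stability(quantities: pd.DataFrame,
                         groups: dict[str, str] | None = None) -> pd.Series:
    """NormFinder-style stability rho per candidate (lower = stabler).

    Operates on log2 quantities.  With groups: rho_j = mean_g |d_jg| +
    mean_g sqrt(v_jg / n_g), where d_jg is the gene-by-group interaction
    (intergroup effect) and v_jg the intragroup residual variance.  Without
    groups: sqrt of the gene-specific variance component, i.e. the variance
    of the candidate after removing the shared per-sample effect, floored
    at zero.
    """
    if quantities.shape[0] < 2:
        raise ValueError("NormFinder needs at least 2 samples")
    if quantities.shape[1] < 2:
        raise ValueError("NormFinder needs at least 2 candidates")
    y = np.log2(quantities.to_numpy(float))
    n_samples, n_genes = y.shape
    sample_eff = y.mean(axis=1, keepdims=True)   # shared template-input effect
    z = y - sample_eff
    if groups is None:
        var_total = z.var(axis=0, ddof=1)
        rho = np.sqrt(np.maximum(var_total, 0.0))
        return pd.Series(rho, index=quantities.columns, name="normfinder_rho")
    sample_names = list(quantities.index)
    labels = np.array([groups[s] for s in sample_names])
    rho = np.zeros(n_genes)
    grand = z.mean(axis=0)
    for j in range(n_genes):
        terms_d, terms_se = [], []
        for g in np.unique(labels):
            zg = z[labels == g, j]
            n_g = zg.size
            d_jg = zg.mean() - grand[j]
            v_jg = zg.var(ddof=1) if n_g > 1 else 0.0
            terms_d.append(abs(d_jg))
            terms_se.append(np.sqrt(v_jg / n_g))
        rho[j] = float(np.mean(terms_d) + np.mean(terms_se))
    return pd.Series(rho, index=quantities.columns, name="normfinder_rho")


def bestkeeper_stats(cq: pd.DataFrame) -> pd.DataFrame:
    """BestKeeper per-candidate SD and CV of raw Cq and correlation to the index.

    The index is the per-sample arithmetic mean Cq over candidates
    (geometric mean of relative quantities).  A constant index leaves r
    undefined (NaN).  Candidates rank by ascending SD.
    """
    wide = cq.pivot_table(index="sample", columns="assay", values="Cq")
    if wide.shape[0] < 2:
        raise ValueError("BestKeeper needs at least 2 samples")
    index_cq = wide.mean(axis=1)
    rows = []
    for a in wide.columns:
        sd = float(wide[a].std(ddof=1))
        cv = float(sd / wide[a].mean() * 100.0)
        if index_cq.std(ddof=1) == 0 or wide[a].std(ddof=1) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(wide[a], index_cq)[0])
        rows.append({"assay": a, "sd": sd, "cv_percent": cv, "r": r})
    return pd.DataFrame(rows).set_index("assay")


def delta_ct_stability(cq: pd.DataFrame) -> pd.Series:
    """Mean pairwise delta-Ct SD per candidate (lower = stabler)."""
    wide = cq.pivot_table(index="sample", columns="assay", values="Cq")
    if wide.shape[1] < 2:
        raise ValueError("delta-Ct needs at least 2 candidates")
    cols = list(wide.columns)
    out = {}
    for a in cols:
        sds = [float((wide[a] - wide[b]).std(ddof=1)) for b in cols if b != a]
        out[a] = float(np.mean(sds))
    return pd.Series(out, name="delta_ct_sd")


def aggregate_geomean_ranks(method_ranks: pd.DataFrame) -> pd.DataFrame:
    """RefFinder-style aggregation: G = (prod of the four ranks)^(1/m).

    ``method_ranks``: candidates x methods matrix of ranks (average ranks
    on ties); any missing value raises.  Returns geomean rank G and the
    final ranking by ascending G.
    """
    if method_ranks.isna().any().any():
        raise ValueError("every method must provide a complete ranking")
    g = np.power(method_ranks.prod(axis=1), 1.0 / method_ranks.shape[1])
    out = pd.DataFrame({"geomean_rank": g})
    out["final_rank"] = stats.rankdata(g)
    return out.sort_values("geomean_rank")


def stability_report(cq: pd.DataFrame, groups: dict[str, str] | None = None,
                     efficiencies: dict[str, float] | None = None,
                     default_efficiency: float = 2.0) -> pd.DataFrame:
    """All four stability methods plus the geometric-mean aggregate ranking."""
    q = cq_to_quantities(cq, efficiencies, default_efficiency)
    m = genorm_m(q)
    rho = normfinder_stability(q, groups)
    bk = bestkeeper_stats(cq)
    dct = delta_ct_stability(cq)
    scores = pd.DataFrame({
        "genorm_M": m, "normfinder_rho": rho,
        "bestkeeper_sd": bk["sd"], "bestkeeper_r": bk["r"], "delta_ct_sd": dct,
    })
    ranks = pd.DataFrame({
        "genorm": stats.rankdata(scores["genorm_M"]),
        "normfinder": stats.rankdata(scores["normfinder_rho"]),
        "bestkeeper": stats.rankdata(scores["bestkeeper_sd"]),
        "delta_ct": stats.rankdata(scores["delta_ct_sd"]),
    }, index=scores.index)
    agg = aggregate_geomean_ranks(ranks)
    report = scores.join(ranks, rsuffix="_rank").join(agg)
    return report.sort_values("geomean_rank")
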