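"""Two-group negative-binomial Wald tests with BH correction and filtering.

The model is the standard NB log-link contrast: for group means mu_A, mu_B
estimated from size-factor-normalized counts,

    log2FC = log2((mu_B + c) / (mu_A + c)),      c = 0.5 pseudocount
    Var(ln mu_g) ~= (1/n_g) (1/mu_g + alpha)     (delta method, NB variance)
    W = log2FC / SE,   SE = sqrt(V_A + V_B) / ln 2,   p = 2 Phi(-|W|)

with a single method-of-moments dispersion alpha per gene.  This is a
deliberately simple, fully specified Wald test: no empirical-Bayes
dispersion shrinkage and no fold-change shrinkage.  Benjamini-Hochberg
adjustment is applied per contrast over the testable genes only, after
removing untestable (all-zero) and low-count genes.

The study design mirrors a developmental/organ small-RNA survey: pooled
early stages vs pooled larvae (n=4 vs 4), the two fingerling stages
(n=2 vs 2), and each adult organ against the pool of the other three
(n=2 vs 6); liver is never a focal organ (one liver library failed QC in
the emulated design) but remains in the organ pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: contrast name -> (focal group labels A, group labels B)
STUDY_CONTRASTS: dict[str, tuple[list[str], list[str]]] = {
    "early_vs_larvae": (["eyed_egg", "larvae_2dph"], ["larvae_15dph", "larvae_26dph"]),
    "fingerling_3g_vs_35g": (["fingerling_3g"], ["fingerling_35g"]),
    "head_kidney_vs_rest": (["head_kidney"], ["spleen", "gills", "liver"]),
    "spleen_vs_rest": (["spleen"], ["head_kidney", "gills", "liver"]),
    "gills_vs_rest": (["gills"], ["head_kidney", "spleen", "liver"]),
}

EXCLUDED_FOCAL_ORGANS = ("liver",)


@dataclass
class Contrast:
    name: str
    samples_a: list[str]
    samples_b: list[str]

    def __post_init__(self) -> None:
        if set(self.samples_a) & set(self.samples_b):
            raise ValueError(f"contrast {self.name}: overlapping groups")
        if len(self.samples_a) < 2 or len(self.samples_b) < 2:
            raise ValueError(f"contrast {self.name}: each side needs >= 2 samples")


def define_contrasts(sample_sheet: pd.DataFrame,
                     focal_organs: tuple[str, ...] | None = None) -> list[Contrast]:
    """Build the study's standard contrasts from a sample sheet.

    ``sample_sheet`` needs columns ``sample`` and ``group``.  Requesting an
    excluded organ (liver) as focal raises.  Missing groups raise with the
    group named.
    """
    by_group: dict[str, list[str]] = {}
    for s, g in zip(sample_sheet["sample"], sample_sheet["group"]):
        by_group.setdefault(g, []).append(s)

    if focal_organs is not None:
        for organ in focal_organs:
            if organ in EXCLUDED_FOCAL_ORGANS:
                raise ValueError(
                    f"{organ} cannot be a focal organ: it is excluded from the "
                    f"organ contrasts (failed library QC in the study design)")

    contrasts = []
    for name, (ga, gb) in STUDY_CONTRASTS.items():
        missing = [g for g in ga + gb if g not in by_group]
        if missing:
            raise ValueError(f"contrast {name}: missing group(s) {missing}")
        if focal_organs is not None and name.endswith("_vs_rest"):
            if name.split("_vs_")[0] not in focal_organs:
                continue
        samples_a = [s for g in ga for s in by_group[g]]
        samples_b = [s for g in gb for s in by_group[g]]
        contrasts.append(Contrast(name, samples_a, samples_b))
    return contrasts


def custom_contrast(name: str, samples_a: list[str], samples_b: list[str]) -> Contrast:
    """A user-specified contrast, accepted verbatim."""
    return Contrast(name, list(samples_a), list(samples_b))


def estimate_dispersion(norm_counts: pd.DataFrame, contrast: Contrast,
                        floor: float = 1e-8) -> pd.Series:
    """Per-gene method-of-moments NB dispersion from within-group scatter.

    alpha = max(floor, (pooled within-group variance - mean) / mean^2); the
    pooled variance weights group variances by their degrees of freedom.
    """
    a = norm_counts[contrast.samples_a].to_numpy(float)
    b = norm_counts[contrast.samples_b].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    pooled_var = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    mean = np.concatenate([a, b], axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / np.square(mean)
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    return pd.Series(np.maximum(alpha, floor), index=norm_counts.index, name="alpha")


def wald_lfc_test(norm_counts: pd.DataFrame, contrast: Contrast,
                  alpha: pd.Series | float, pseudocount: float = 0.5) -> pd.DataFrame:
    """Wald log2 fold-change test for one contrast.

    Returns a per-gene frame with baseMean, mean_a, mean_b, log2fc, se,
    wald, pvalue and an ``untestable`` flag for genes with zero counts in
    both groups (their statistics are NaN).
    """
    a = norm_counts[contrast.samples_a].to_numpy(float)
    b = norm_counts[contrast.samples_b].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)
    alpha_vec = (alpha.reindex(norm_counts.index).to_numpy(float)
                 if isinstance(alpha, pd.Series) else np.full(len(norm_counts), float(alpha)))

    c = pseudocount
    lfc = np.log2((mu_b + c) / (mu_a + c))
    var_a = (1.0 / na) * (1.0 / (mu_a + c) + alpha_vec)
    var_b = (1.0 / nb) * (1.0 / (mu_b + c) + alpha_vec)
    se = np.sqrt(var_a + var_b) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))

    untestable = (mu_a == 0) & (mu_b == 0)
    out = pd.DataFrame({
        "baseMean": (mu_a * na + mu_b * nb) / (na + nb),
        "mean_a": mu_a, "mean_b": mu_b,
        "log2fc": lfc, "se": se, "wald": wald, "pvalue": pvalue,
        "untestable": untestable,
    }, index=norm_counts.index)
    out.loc[untestable, ["log2fc", "se", "wald", "pvalue"]] = np.nan
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def run_de(norm_counts: pd.DataFrame, contrast: Contrast,
           dominance: dict[str, str] | None = None,
           alpha: pd.Series | float | None = None,
           min_normalized: float = 30.0, min_abs_lfc: float = 1.0,
           max_padj: float = 0.05, pseudocount: float = 0.5,
           dispersion_floor: float = 1e-8) -> pd.DataFrame:
    """Full DE pass for one contrast: test, adjust, filter.

    Exclusion flags: ``low_count`` (neither group mean >= min_normalized),
    ``small_effect`` (|log2FC| < min_abs_lfc), ``passenger`` (arm labelled
    passenger by dominance).  ``significant`` requires padj <= max_padj and
    no exclusion flag.  BH runs over testable, non-low-count genes only.
    """
    if alpha is None:
        alpha = estimate_dispersion(norm_counts, contrast, floor=dispersion_floor)
    res = wald_lfc_test(norm_counts, contrast, alpha, pseudocount)
    res["low_count"] = ~((res["mean_a"] >= min_normalized) | (res["mean_b"] >= min_normalized))
    res["small_effect"] = ~(np.abs(res["log2fc"]) >= min_abs_lfc)
    dominance = dominance or {}
    res["passenger"] = [dominance.get(g, "") == "passenger" for g in res.index]

    res["padj"] = np.nan
    adjustable = ~res["untestable"] & ~res["low_count"]
    if adjustable.any():
        res.loc[adjustable, "padj"] = bh_adjust(res.loc[adjustable, "pvalue"].to_numpy())
    res["significant"] = (
        adjustable & (res["padj"] <= max_padj)
        & ~res["small_effect"] & ~res["passenger"]
    )
    return res


def de_table(res: pd.DataFrame) -> pd.DataFrame:
    """Significant genes only, sorted by fold change (reporting layout)."""
    sig = res[res["significant"]].copy()
    return sig.sort_values("log2fc", ascending=False)[["baseMean", "log2fc", "padj"]]
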