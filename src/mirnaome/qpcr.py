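"""Efficiency-corrected delta-Cq quantification and group comparison.

The quantification model is the standard efficiency-corrected delta-Cq:
RQ = E^(Cq_cal - Cq) with the per-assay calibrator the minimum Cq across
retained samples (the maximally expressed sample), and E the assay
efficiency from a dilution standard curve (E = 10^(-1/slope), default 2.0
when no curve is supplied).  Target RQs are normalized to the geometric
mean of two reference-assay RQs (NRQ); group differences use a two-sided
pooled-variance Student's t-test.  Samples with Cq above 30.0 are excluded
before any calculation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def exclude_high_cq(cq: pd.DataFrame, cutoff: float = 30.0) -> pd.DataFrame:
    """Flag entries with Cq strictly above the cutoff as excluded."""
    out = cq.copy()
    out["excluded"] = out["Cq"] > cutoff
    return out


def efficiency_from_dilution(log10_dilution, cq_values) -> tuple[float, float]:
    """(slope, E) from an ordinary least-squares standard curve.

    E = 10^(-1/slope); a nonnegative slope is an invalid standard curve.
    """
    x = np.asarray(log10_dilution, dtype=float)
    y = np.asarray(cq_values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 dilution points")
    slope = float(np.polyfit(x, y, 1)[0])
    if slope >= 0:
        raise ValueError(f"invalid standard curve: nonnegative slope {slope:.4g}")
    return slope, float(10.0 ** (-1.0 / slope))


def relative_quantity(cq: pd.Series | np.ndarray, efficiency: float = 2.0,
                      calibrator_cq: float | None = None) -> np.ndarray:
    """RQ = E^(Cq_cal - Cq); calibrator defaults to the minimum Cq supplied."""
    if efficiency <= 1:
        raise ValueError("efficiency must exceed 1")
    x = np.asarray(cq, dtype=float)
    cal = float(np.nanmin(x)) if calibrator_cq is None else calibrator_cq
    return np.power(efficiency, cal - x)


def rq_table(cq: pd.DataFrame, efficiencies: dict[str, float] | None = None,
             default_efficiency: float = 2.0, cutoff: float = 30.0) -> pd.DataFrame:
    """Per-(sample, assay) RQ after the Cq ceiling; excluded entries carry no RQ."""
    out = exclude_high_cq(cq, cutoff)
    out["RQ"] = np.nan
    for assay, sub in out.groupby("assay"):
        keep = sub.index[~sub["excluded"]]
        if len(keep) == 0:
            continue
        eff = (efficiencies or {}).get(assay, default_efficiency)
        out.loc[keep, "RQ"] = relative_quantity(out.loc[keep, "Cq"], eff)
    return out


def normalize_to_references(rq: pd.DataFrame, target: str,
                            references: tuple[str, str]) -> pd.DataFrame:
    """NRQ of a target assay: RQ / geometric mean of the two reference RQs.

    Samples missing either reference RQ are dropped (logged via the
    returned frame simply not containing them).
    """
    wide = rq.pivot_table(index="sample", columns="assay", values="RQ")
    for col in (target, *references):
        if col not in wide.columns:
            raise ValueError(f"assay {col} absent from RQ table")
    ref_geo = np.sqrt(wide[references[0]] * wide[references[1]])
    nrq = wide[target] / ref_geo
    out = pd.DataFrame({"NRQ": nrq}).dropna()
    out["target"] = target
    if "group" in rq.columns:
        grp = rq.drop_duplicates("sample").set_index("sample")["group"]
        out["group"] = grp.reindex(out.index)
    return out


def compare_groups(nrq: pd.DataFrame, group_a: str, group_b: str,
                   welch: bool = False) -> dict:
    """Fold change and two-sided Student's t between two groups of NRQs.

    Fold change is the ratio of group mean NRQs (B over A).  Identical
    zero-variance groups give t = 0, p = 1.
    """
    a = nrq.loc[nrq["group"] == group_a, "NRQ"].to_numpy(float)
    b = nrq.loc[nrq["group"] == group_b, "NRQ"].to_numpy(float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 retained samples per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(b, a, equal_var=not welch)
    return {"fold_change": float(b.mean() / a.mean()), "t": float(t),
            "p": float(p), "n_a": int(a.size), "n_b": int(b.size)}


def seq_qpcr_concordance(log10_fc_seq, log10_fc_qpcr) -> float:
    """Pearson r between paired sequencing and qPCR log10 fold changes."""
    x = np.asarray(log10_fc_seq, dtype=float)
    y = np.asarray(log10_fc_qpcr, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired fold changes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])
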