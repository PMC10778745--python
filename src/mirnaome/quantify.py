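"""Mature-level quantification: counting, normalization, abundance, diversity.

Reads are assigned to unique matures with a bounded-tolerance matcher
(<=1 mismatch, 5' offset <=2 nt, 3' offset <=5 nt — the isomiR envelope of a
mature), ties resolved deterministically.  Normalization is DESeq2-style
median-of-ratios with size factors rescaled to geometric mean 1;
counts-per-million is available as an alternative.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from mirnaome.annotation import UniqueMature

_EMPTY: frozenset = frozenset()


def _build_variant_index(matures: list[UniqueMature], max_off5: int, max_off3: int
                         ) -> dict[str, tuple[int, int, int]]:
    """Exact-substring fast path: trimmed variant -> (mature idx, mism, off5).

    Collisions keep the better assignment under the tie-break chain
    (fewest mismatches, smallest 5' offset, first mature in table order).
    """
    index: dict[str, tuple[int, int, int]] = {}
    for idx, m in enumerate(matures):
        L = len(m.sequence)
        for off5 in range(0, max_off5 + 1):
            for off3 in range(0, max_off3 + 1):
                sub = m.sequence[off5: L - off3]
                if len(sub) < 10:
                    continue
                prev = index.get(sub)
                if prev is None or (0, off5, idx) < (prev[1], prev[2], prev[0]):
                    index[sub] = (idx, 0, off5)
    return index


def _build_kmer_prefilter(matures: list[UniqueMature], k: int = 9
                          ) -> dict[str, set[int]]:
    """k-mer -> mature indices.  With <=1 mismatch over an overlap of >=18 nt
    a matching read always shares an exact run >= ceil(17/2) = 9 nt with the
    mature, so a read sharing no 9-mer can be dismissed without scanning."""
    table: dict[str, set[int]] = {}
    for idx, m in enumerate(matures):
        for i in range(len(m.sequence) - k + 1):
            table.setdefault(m.sequence[i:i + k], set()).add(idx)
    return table


def _slow_match(read: str, matures: list[UniqueMature], max_mism: int,
                max_off5: int, max_off3: int,
                candidate_idx: set[int] | None = None) -> int | None:
    """Full scan with mismatches and signed end offsets; returns mature idx."""
    best = None
    for idx, m in enumerate(matures):
        if candidate_idx is not None and idx not in candidate_idx:
            continue
        seq = m.sequence
        for shift in range(-max_off5, max_off5 + 1):
            # read position i aligns to mature position i + shift
            off3 = (len(read) + shift) - len(seq)
            if abs(off3) > max_off3:
                continue
            lo = max(0, -shift)
            hi = min(len(read), len(seq) - shift)
            if hi - lo < 10:
                continue
            mism = sum(1 for i in range(lo, hi) if read[i] != seq[i + shift])
            if mism <= max_mism:
                cand = (mism, abs(shift), idx)
                if best is None or cand < best:
                    best = cand
    return best[2] if best else None


def count_matures(reads_by_sample: dict[str, Counter], matures: list[UniqueMature],
                  max_mismatches: int = 1, max_offset5: int = 2,
                  max_offset3: int = 5) -> tuple[pd.DataFrame, pd.Series]:
    """Mature x sample raw count matrix plus per-sample unassigned tallies.

    Each read counts once; assignment ties are broken by fewest mismatches,
    then smallest 5' offset, then mature table order.
    """
    names = [m.name for m in matures]
    index = _build_variant_index(matures, max_offset5, max_offset3)
    prefilter = _build_kmer_prefilter(matures)
    k = 9
    samples = sorted(reads_by_sample)
    mat = np.zeros((len(matures), len(samples)), dtype=np.int64)
    unassigned = pd.Series(0, index=samples, dtype=np.int64)
    slow_cache: dict[str, int | None] = {}
    for j, sample in enumerate(samples):
        for seq, mult in reads_by_sample[sample].items():
            hit = index.get(seq)
            if hit is not None:
                mat[hit[0], j] += mult
                continue
            if seq not in slow_cache:
                cand: set[int] = set()
                for i in range(len(seq) - k + 1):
                    cand |= prefilter.get(seq[i:i + k], _EMPTY)
                slow_cache[seq] = (_slow_match(seq, matures, max_mismatches,
                                               max_offset5, max_offset3, cand)
                                   if cand else None)
            idx = slow_cache[seq]
            if idx is None:
                unassigned[sample] += mult
            else:
                mat[idx, j] += mult
    counts = pd.DataFrame(mat, index=names, columns=samples)
    return counts, unassigned


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Rows with any zero are excluded from the reference geometric means; if
    no all-positive row exists, the positive subset per sample is used
    (with a warning).
    """
    x = counts.to_numpy(float)
    positive = (x > 0).all(axis=1)
    if positive.any():
        ref = x[positive]
        log_geo = np.log(ref).mean(axis=1)
        ratios = np.log(ref) - log_geo[:, None]
        log_sf = np.median(ratios, axis=0)
    else:
        import warnings

        warnings.warn("no all-positive row; falling back to per-sample positive subset")
        log_sf = np.zeros(x.shape[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            log_geo_all = np.where(
                (x > 0).any(axis=1),
                np.nanmean(np.where(x > 0, np.log(x), np.nan), axis=1), np.nan)
        for j in range(x.shape[1]):
            mask = x[:, j] > 0
            log_sf[j] = np.median(np.log(x[mask, j]) - log_geo_all[mask])
    log_sf = log_sf - log_sf.mean()   # geometric mean of factors = 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, method: str = "median_of_ratios"
              ) -> tuple[pd.DataFrame, pd.Series]:
    """(normalized matrix, size factors); method 'median_of_ratios' or 'cpm'."""
    if method == "median_of_ratios":
        sf = compute_size_factors(counts)
    elif method == "cpm":
        sf = counts.sum(axis=0).astype(float) / 1e6
        sf.name = "size_factor"
    else:
        raise ValueError(f"unknown normalization method: {method}")
    return counts / sf, sf


def relative_abundance(norm_counts: pd.DataFrame, sample_groups: dict[str, str],
                       group: str, top_n: int = 20) -> pd.DataFrame:
    """Per-mature proportion of the group-mean normalized counts; top-N table.

    Proportions sum to one; matures beyond the top N are pooled as 'other'.
    """
    samples = [s for s, g in sample_groups.items() if g == group]
    if not samples:
        raise ValueError(f"group {group} has no samples")
    means = norm_counts[samples].mean(axis=1)
    total = means.sum()
    if total <= 0:
        raise ValueError(f"group {group} has no expression")
    prop = (means / total).sort_values(ascending=False)
    top = prop.iloc[:top_n]
    rows = [{"mature": name, "proportion": float(p)} for name, p in top.items()]
    if len(prop) > top_n:
        rows.append({"mature": "other", "proportion": float(prop.iloc[top_n:].sum())})
    return pd.DataFrame(rows)


def group_diversity(norm_counts: pd.DataFrame, sample_groups: dict[str, str],
                    threshold: float = 0.0) -> pd.Series:
    """Detected-mature count per group: normalized count > threshold in >=1 replicate."""
    groups = sorted(set(sample_groups.values()))
    out = {}
    for g in groups:
        samples = [s for s, grp in sample_groups.items() if grp == g]
        out[g] = int(((norm_counts[samples] > threshold).any(axis=1)).sum())
    return pd.Series(out, name="detected_matures")
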