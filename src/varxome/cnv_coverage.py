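"""Read-depth CNV detection by recursive binary segmentation of the
sample/reference coverage ratio in fixed-width bins.

Coverage from two libraries is binned (250 bp default), library-size
normalized, and the per-bin log2 ratio is segmented recursively: the best
split point of a segment is the one maximizing the pooled two-sample t
statistic between its two halves, accepted when significant at `alpha`
after Bonferroni correction over the candidate split points of that scan.
Segments with mean sample/reference ratio < 0.4 are deletions and > 1.6
duplications. Calls are made robust to multi-mapping artifacts by running
at two read-ambiguity settings and keeping reciprocally overlapping calls,
and strain-specific by removing calls shared between strains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEL_RATIO = 0.4
DUP_RATIO = 1.6
DEFAULT_BIN = 250
DEFAULT_MIN_SEG = 1000  # bp; 4 bins at the default bin size
DEFAULT_ALPHA = 0.01
PSEUDOCOUNT = 0.5
RECIPROCAL_OVERLAP = 0.5


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start: int
    end: int
    mean_ratio: float
    cnv_class: str  # DEL | DUP | neutral
    ambiguity_level: int = 1
    n_bins: int = 0


def classify_ratio(ratio: float, low: float = DEL_RATIO, high: float = DUP_RATIO) -> str:
    if ratio < low:
        return "DEL"
    if ratio > high:
        return "DUP"
    return "neutral"


# ------------------------------------------------------------------ binning


def bin_counts(
    reads: pd.DataFrame,
    genome_length: int,
    bin_size: int = DEFAULT_BIN,
    ambiguity: int = 1,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Count read starts per bin, excluding reads with more genomic hits
    than `ambiguity` allows. `reads` needs columns (chrom, pos, n_hits)."""
    if ambiguity < 1:
        raise ValueError("ambiguity must be >= 1")
    starts = np.arange(0, genome_length, bin_size)
    ends = np.minimum(starts + bin_size, genome_length)
    kept = reads[(reads["n_hits"] <= ambiguity) & (reads["chrom"] == chrom)]
    idx = (kept["pos"].to_numpy() // bin_size).astype(int)
    counts = np.bincount(idx, minlength=len(starts))[: len(starts)]
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "count": counts}
    )


def combine_tracks(sample: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    df = sample[["chrom", "start", "end"]].copy()
    df["sample_count"] = sample["count"].to_numpy()
    df["ref_count"] = reference["count"].to_numpy()
    return df


# -------------------------------------------------------------- segmentation


def _interval_t(
    c1: np.ndarray, c2: np.ndarray, n: int, lengths: np.ndarray
) -> tuple[int, int, float, int]:
    """Best (start, length) interval-vs-rest pooled t over the given
    candidate lengths; returns (i, L, |t|, n_candidates)."""
    tot, tot2 = c1[-1], c2[-1]
    best = (0, 0, 0.0)
    n_cand = 0
    for L in lengths:
        if L >= n:
            continue
        sums = c1[L:] - c1[:-L] if L < n else np.array([tot])
        sums = np.concatenate([[c1[L - 1]], sums])
        ss = np.concatenate([[c2[L - 1]], c2[L:] - c2[:-L]])
        n_out = n - L
        m_in = sums / L
        m_out = (tot - sums) / n_out
        pooled = (ss - sums ** 2 / L) + (
            (tot2 - ss) - (tot - sums) ** 2 / n_out
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(np.maximum(pooled, 0) / (n - 2) * (1 / L + 1 / n_out))
            t = np.abs(m_in - m_out) / se
        t = np.where(np.isfinite(t), t, np.where(m_in != m_out, np.inf, 0.0))
        n_cand += len(t)
        i = int(np.argmax(t))
        if t[i] > best[2]:
            best = (i, int(L), float(t[i]))
    return best[0], best[1], best[2], n_cand


def _candidate_lengths(min_bins: int, l_max: int) -> np.ndarray:
    """Dense short lengths plus a geometric grid for long intervals."""
    dense = np.arange(min_bins, min(65, l_max + 1))
    out = list(dense)
    L = 64
    while L < l_max:
        L = int(np.ceil(L * 1.25))
        out.append(min(L, l_max))
    return np.unique(np.asarray(out, dtype=int))


def _best_interval(
    x: np.ndarray, min_bins: int, max_scan_bins: int
) -> tuple[int, int, float, int]:
    """CBS-style scan: best contiguous interval against the rest of the
    segment (an interval touching a segment end is a single split).
    Coarse geometric length grid, then exact local refinement."""
    n = len(x)
    l_max = min(n - min_bins, max_scan_bins)
    if l_max < min_bins:
        return -1, -1, 0.0, 0
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    i0, L0, t0, n_cand = _interval_t(c1, c2, n, _candidate_lengths(min_bins, l_max))
    if L0 == 0:
        return -1, -1, 0.0, n_cand
    # refine around the coarse optimum on an exact small grid
    step = max(2, L0 // 8)
    best = (i0, L0, t0)
    for L in range(max(min_bins, L0 - step), min(l_max, L0 + step) + 1):
        for i in range(max(0, i0 - step), min(n - L, i0 + step) + 1):
            s = c1[i + L - 1] - (c1[i - 1] if i else 0.0)
            ss = c2[i + L - 1] - (c2[i - 1] if i else 0.0)
            n_out = n - L
            m_in = s / L
            m_out = (c1[-1] - s) / n_out
            pooled = (ss - s ** 2 / L) + ((c2[-1] - ss) - (c1[-1] - s) ** 2 / n_out)
            se2 = max(pooled, 0) / (n - 2) * (1 / L + 1 / n_out)
            if se2 == 0:
                t = np.inf if m_in != m_out else 0.0
            else:
                t = abs(m_in - m_out) / np.sqrt(se2)
            if t > best[2]:
                best = (i, L, t)
    return best[0], best[1], best[2], n_cand


def segment(
    track: pd.DataFrame,
    min_seg_len: int = DEFAULT_MIN_SEG,
    alpha: float = DEFAULT_ALPHA,
    bin_size: int | None = None,
    low: float = DEL_RATIO,
    high: float = DUP_RATIO,
    ambiguity_level: int = 1,
    max_scan_bins: int = 2000,
) -> list[CnvSegment]:
    """Segment a two-library coverage track into copy-ratio segments.

    `track` has columns (chrom, start, end, sample_count, ref_count). Both
    libraries are normalized to equal totals, per-bin log2 ratios use a
    pseudocount of 0.5, and splits recurse while the halves differ at the
    Bonferroni-corrected `alpha` level and both sides stay >= min_seg_len.
    """
    if bin_size is None:
        bin_size = int((track["end"] - track["start"]).iloc[0])
    min_bins = max(1, min_seg_len // bin_size)
    out: list[CnvSegment] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        s = sub["sample_count"].to_numpy(dtype=float)
        r = sub["ref_count"].to_numpy(dtype=float)
        ts, tr = s.sum(), r.sum()
        if ts <= 0 or tr <= 0:
            raise ValueError("both libraries need positive totals")
        scale = tr / ts
        x = np.log2((s * scale + PSEUDOCOUNT) / (r + PSEUDOCOUNT))
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        n = len(x)

        boundaries = [0, n]

        def rec(lo: int, hi: int) -> None:
            if hi - lo < 2 * min_bins:
                return
            i, L, t, n_cand = _best_interval(x[lo:hi], min_bins, max_scan_bins)
            if L <= 0 or n_cand == 0:
                return
            df = (hi - lo) - 2
            crit = stats.t.isf(alpha / (2 * n_cand), df)
            if t > crit:
                cuts = [lo + i, lo + i + L]
                for c in cuts:
                    if lo < c < hi:
                        boundaries.append(c)
                pieces = sorted({lo, hi, *[c for c in cuts if lo < c < hi]})
                for a, b in zip(pieces[:-1], pieces[1:]):
                    if (a, b) != (lo, hi):
                        rec(a, b)

        rec(0, n)
        boundaries = sorted(set(boundaries))
        for lo, hi in zip(boundaries[:-1], boundaries[1:]):
            seg_ratio = (s[lo:hi].sum() * scale + PSEUDOCOUNT) / (
                r[lo:hi].sum() + PSEUDOCOUNT
            )
            out.append(
                CnvSegment(
                    chrom=chrom,
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    mean_ratio=float(seg_ratio),
                    cnv_class=classify_ratio(seg_ratio, low, high),
                    ambiguity_level=ambiguity_level,
                    n_bins=hi - lo,
                )
            )
    return out


def cnv_calls(segments: Sequence[CnvSegment]) -> list[CnvSegment]:
    return [s for s in segments if s.cnv_class != "neutral"]


# ------------------------------------------------------------- consensus


def _reciprocal(a: CnvSegment, b: CnvSegment, frac: float) -> bool:
    if a.chrom != b.chrom or a.cnv_class != b.cnv_class:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    return ov > 0 and ov >= frac * (a.end - a.start) and ov >= frac * (b.end - b.start)


def consensus(
    calls_amb1: Sequence[CnvSegment],
    calls_amb10: Sequence[CnvSegment],
    min_reciprocal: float = RECIPROCAL_OVERLAP,
) -> list[CnvSegment]:
    """Keep calls reciprocally overlapping (>= 50%) a same-class call in the
    other ambiguity set; the reported span is the intersection."""
    out = []
    for a in calls_amb1:
        for b in calls_amb10:
            if _reciprocal(a, b, min_reciprocal):
                out.append(
                    CnvSegment(
                        chrom=a.chrom,
                        start=max(a.start, b.start),
                        end=min(a.end, b.end),
                        mean_ratio=(a.mean_ratio + b.mean_ratio) / 2,
                        cnv_class=a.cnv_class,
                        ambiguity_level=0,
                        n_bins=min(a.n_bins, b.n_bins),
                    )
                )
                break
    return out


def remove_shared(
    calls_strain1: Sequence[CnvSegment],
    calls_strain2: Sequence[CnvSegment],
    min_reciprocal: float = RECIPROCAL_OVERLAP,
) -> tuple[list[CnvSegment], list[CnvSegment]]:
    """Drop calls reciprocally overlapping a same-class call in the other
    strain from both lists (shared CNVs are reference artifacts)."""
    keep1 = [
        a
        for a in calls_strain1
        if not any(_reciprocal(a, b, min_reciprocal) for b in calls_strain2)
    ]
    keep2 = [
        b
        for b in calls_strain2
        if not any(_reciprocal(b, a, min_reciprocal) for a in calls_strain1)
    ]
    return keep1, keep2
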