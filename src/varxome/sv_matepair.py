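"""Structural-variant calling from long mate-pair (LMP) libraries.

Pairs mapping at an unexpected distance or orientation are classified
against an empirical library profile (median insert and 1%/99% distance
tails): distance beyond the upper 1% tail supports a deletion, below the
lower tail an insertion, everted order a tandem duplication, and a single
flipped strand an inversion. Calls need >= 3 independent supporting pairs;
duplications must exceed 3,100 bp; deletion candidates additionally pass
the spanning-insert criterion (median(case) - median(control)) /
median(case) > 0.25 and are dropped when also supported in the control
library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

MIN_SUPPORT = 3
MIN_DUP_SIZE = 3100
MEDIAN_STAT_THRESHOLD = 0.25
TAIL_FRACTION = 0.01


@dataclass(frozen=True)
class LibraryProfile:
    library_id: str
    median_insert: float
    lower_tail_1pct: float
    upper_tail_1pct: float
    expected_orientation: str = "FR"  # left-mate strand, right-mate strand
    degenerate: bool = False


@dataclass(frozen=True)
class SvCall:
    type: str  # DEL | DUP | INV | INS
    chrom: str
    start: int
    end: int
    support: int
    median_ratio_stat: float | None = None
    unfiltered: bool = False  # no control library available


# ------------------------------------------------------------- profiling


def profile_library(
    pairs: pd.DataFrame,
    expected_orientation: str = "FR",
    tail: float = TAIL_FRACTION,
    min_pairs: int = 1000,
) -> LibraryProfile:
    """Empirical insert-size profile from same-chromosome pairs with the
    expected orientation."""
    conc = pairs[
        (pairs["chrom1"] == pairs["chrom2"])
        & (pairs["strand1"] == expected_orientation[0].translate(_STRAND))
        & (pairs["strand2"] == expected_orientation[1].translate(_STRAND))
    ]
    d = (conc["pos2"] - conc["pos1"]).to_numpy(dtype=float)
    if len(d) < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} expected-orientation pairs, got {len(d)}"
        )
    lo = float(np.quantile(d, tail))
    hi = float(np.quantile(d, 1 - tail))
    med = float(np.median(d))
    lib = str(pairs["library_id"].iloc[0]) if "library_id" in pairs else "lib"
    return LibraryProfile(
        library_id=lib,
        median_insert=med,
        lower_tail_1pct=lo,
        upper_tail_1pct=hi,
        expected_orientation=expected_orientation,
        degenerate=not (lo < med < hi),
    )


_STRAND = str.maketrans("FR", "+-")


def _expected_strands(orientation: str) -> tuple[str, str]:
    return orientation[0].translate(_STRAND), orientation[1].translate(_STRAND)


# ----------------------------------------------------------- classification


def classify_pair(pair, profile: LibraryProfile) -> str:
    """Total classification of one normalized (pos1 <= pos2) pair into
    {concordant, del_support, ins_support, dup_support, inv_support,
    interchrom}."""
    get = pair.get if isinstance(pair, dict) else lambda k, _p=pair: getattr(_p, k)
    if get("chrom1") != get("chrom2"):
        return "interchrom"
    e1, e2 = _expected_strands(profile.expected_orientation)
    s1, s2 = get("strand1"), get("strand2")
    if (s1, s2) == (e1, e2):
        d = get("pos2") - get("pos1")
        if d > profile.upper_tail_1pct:
            return "del_support"
        if d < profile.lower_tail_1pct:
            return "ins_support"
        return "concordant"
    if (s1, s2) == (e2, e1):
        return "dup_support"
    return "inv_support"  # exactly one end flipped (s1 == s2)


def classify_pairs(pairs: pd.DataFrame, profile: LibraryProfile) -> pd.DataFrame:
    """Vectorized classify_pair over a pair table; adds a `sv_class` column."""
    e1, e2 = _expected_strands(profile.expected_orientation)
    same = (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
    s1 = pairs["strand1"].to_numpy()
    s2 = pairs["strand2"].to_numpy()
    d = (pairs["pos2"] - pairs["pos1"]).to_numpy()
    cls = np.full(len(pairs), "inv_support", dtype=object)
    expected = (s1 == e1) & (s2 == e2)
    everted = (s1 == e2) & (s2 == e1)
    cls[expected & (d > profile.upper_tail_1pct)] = "del_support"
    cls[expected & (d < profile.lower_tail_1pct)] = "ins_support"
    cls[
        expected
        & (d >= profile.lower_tail_1pct)
        & (d <= profile.upper_tail_1pct)
    ] = "concordant"
    cls[everted] = "dup_support"
    cls[~same] = "interchrom"
    out = pairs.copy()
    out["sv_class"] = cls
    return out


# -------------------------------------------------------------- clustering


def _connected_clusters(intervals: pd.DataFrame) -> list[pd.DataFrame]:
    """Connected components of the interval-overlap graph over rows with
    (pos1, pos2) intervals, found by a sweep over sorted start positions."""
    if len(intervals) == 0:
        return []
    sub = intervals.sort_values("pos1")
    clusters = []
    current = [0]
    rows = sub.reset_index(drop=True)
    max_end = rows.loc[0, "pos2"]
    for i in range(1, len(rows)):
        if rows.loc[i, "pos1"] < max_end:
            current.append(i)
            max_end = max(max_end, rows.loc[i, "pos2"])
        else:
            clusters.append(rows.iloc[current])
            current = [i]
            max_end = rows.loc[i, "pos2"]
    clusters.append(rows.iloc[current])
    return clusters


def _inner_span(cluster: pd.DataFrame) -> tuple[int, int]:
    start = int(cluster["pos1"].max())
    end = int(cluster["pos2"].min())
    if start >= end:  # discordant cluster without a common core
        start = int(cluster["pos1"].median())
        end = int(cluster["pos2"].median())
    return start, end


# ----------------------------------------------------------------- calling


def call_deletions(
    classified_case: pd.DataFrame,
    profile_case: LibraryProfile,
    classified_control: pd.DataFrame | None = None,
    profile_control: LibraryProfile | None = None,
    min_support: int = MIN_SUPPORT,
    median_stat_threshold: float = MEDIAN_STAT_THRESHOLD,
) -> list[SvCall]:
    """Deletions from clusters of >= 3 mutually overlapping long-distance
    pairs, validated by the case-vs-control spanning-insert median statistic
    and by absence of support in the control library."""
    del_pairs = classified_case[classified_case["sv_class"] == "del_support"]
    no_control = classified_control is None
    if no_control:
        warnings.warn("control library absent: deletion calls are unfiltered")
    ctrl_del = (
        None
        if no_control
        else classified_control[classified_control["sv_class"] == "del_support"]
    )
    calls = []
    for chrom, sub in del_pairs.groupby("chrom1", sort=False):
        for cluster in _connected_clusters(sub):
            if len(cluster) < min_support:
                continue
            start, end = _inner_span(cluster)
            mid = (start + end) // 2
            if no_control:
                calls.append(
                    SvCall("DEL", chrom, start, end, len(cluster), None, True)
                )
                continue
            span_case = classified_case[
                (classified_case["chrom1"] == chrom)
                & (classified_case["pos1"] <= mid)
                & (classified_case["pos2"] >= mid)
            ]
            span_ctrl = classified_control[
                (classified_control["chrom1"] == chrom)
                & (classified_control["pos1"] <= mid)
                & (classified_control["pos2"] >= mid)
            ]
            if len(span_case) == 0:
                continue
            med_case = float((span_case["pos2"] - span_case["pos1"]).median())
            if len(span_ctrl) == 0:
                # nothing local in the control: fall back to its library median
                med_ctrl = (
                    profile_control.median_insert
                    if profile_control is not None
                    else profile_case.median_insert
                )
            else:
                med_ctrl = float((span_ctrl["pos2"] - span_ctrl["pos1"]).median())
            stat = (med_case - med_ctrl) / med_case if med_case > 0 else 0.0
            if stat <= median_stat_threshold:
                continue
            ctrl_support = ctrl_del[
                (ctrl_del["chrom1"] == chrom)
                & (ctrl_del["pos1"] < end)
                & (ctrl_del["pos2"] > start)
            ]
            if len(ctrl_support) >= min_support:
                continue
            calls.append(SvCall("DEL", chrom, start, end, len(cluster), stat))
    return calls


def call_duplications(
    classified: pd.DataFrame,
    min_support: int = MIN_SUPPORT,
    min_size: int = MIN_DUP_SIZE,
) -> list[SvCall]:
    """Tandem duplications from clusters of >= 3 everted pairs whose implied
    span exceeds `min_size`."""
    dup_pairs = classified[classified["sv_class"] == "dup_support"]
    calls = []
    for chrom, sub in dup_pairs.groupby("chrom1", sort=False):
        for cluster in _connected_clusters(sub):
            if len(cluster) < min_support:
                continue
            start = int(cluster["pos1"].min())
            end = int(cluster["pos2"].max())
            if end - start > min_size:
                calls.append(SvCall("DUP", chrom, start, end, len(cluster)))
    return calls


def call_inversions(
    classified: pd.DataFrame, min_support: int = MIN_SUPPORT
) -> list[SvCall]:
    """Inversions from clusters of >= 3 single-strand-flipped pairs with
    both breakpoints covered (>= 1 ++ pair and >= 1 -- pair)."""
    inv_pairs = classified[classified["sv_class"] == "inv_support"]
    calls = []
    for chrom, sub in inv_pairs.groupby("chrom1", sort=False):
        for cluster in _connected_clusters(sub):
            if len(cluster) < min_support:
                continue
            plus = cluster[cluster["strand1"] == "+"]
            minus = cluster[cluster["strand1"] == "-"]
            if len(plus) == 0 or len(minus) == 0:
                continue
            start = int(plus["pos1"].max())
            end = int(minus["pos2"].min())
            if start >= end:
                start = int(cluster["pos1"].min())
                end = int(cluster["pos2"].max())
            calls.append(SvCall("INV", chrom, start, end, len(cluster)))
    return calls


def call_insertions(
    classified: pd.DataFrame,
    profile: LibraryProfile,
    min_support: int = MIN_SUPPORT,
    min_size_factor: float = 1.5,
) -> list[SvCall]:
    """Insertions from clusters of >= 3 short-distance pairs; the implied
    size is the median shortfall against the library median insert.

    By construction of the empirical 1% tail, ~1% of perfectly normal
    pairs are short; a cluster is only called when its median shortfall
    exceeds `min_size_factor` times the lower-tail spread of the library,
    so the implied insertion is larger than what library noise produces.
    """
    ins_pairs = classified[classified["sv_class"] == "ins_support"]
    min_shortfall = min_size_factor * (
        profile.median_insert - profile.lower_tail_1pct
    )
    calls = []
    for chrom, sub in ins_pairs.groupby("chrom1", sort=False):
        for cluster in _connected_clusters(sub):
            if len(cluster) < min_support:
                continue
            start, end = _inner_span(cluster)
            shortfall = profile.median_insert - (
                cluster["pos2"] - cluster["pos1"]
            ).median()
            if shortfall < min_shortfall:
                continue
            calls.append(
                SvCall(
                    "INS",
                    chrom,
                    start,
                    end,
                    len(cluster),
                    median_ratio_stat=float(shortfall),
                )
            )
    return calls


def call_all(
    pairs_case: pd.DataFrame,
    pairs_control: pd.DataFrame | None = None,
    expected_orientation: str = "FR",
    min_support: int = MIN_SUPPORT,
) -> list[SvCall]:
    """Profile, classify and call DEL/DUP/INV/INS for a case library with
    optional control subtraction."""
    prof_case = profile_library(pairs_case, expected_orientation)
    cls_case = classify_pairs(pairs_case, prof_case)
    cls_ctrl = prof_ctrl = None
    if pairs_control is not None:
        prof_ctrl = profile_library(pairs_control, expected_orientation)
        cls_ctrl = classify_pairs(pairs_control, prof_ctrl)
    calls = call_deletions(
        cls_case, prof_case, cls_ctrl, prof_ctrl, min_support=min_support
    )
    calls += call_duplications(cls_case, min_support=min_support)
    calls += call_inversions(cls_case, min_support=min_support)
    calls += call_insertions(cls_case, prof_case, min_support=min_support)
    if cls_ctrl is not None:
        ctrl_calls = (
            call_duplications(cls_ctrl, min_support=min_support)
            + call_inversions(cls_ctrl, min_support=min_support)
            + call_insertions(cls_ctrl, prof_ctrl, min_support=min_support)
        )
        calls = [
            c
            for c in calls
            if c.type == "DEL"
            or not any(
                k.type == c.type
                and k.chrom == c.chrom
                and k.start < c.end
                and k.end > c.start
                for k in ctrl_calls
            )
        ]
    return calls
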