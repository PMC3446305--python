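"""Differential splicing from exon-exon junction usage.

A junction reference is built from every ordered pair of exons of a gene
(donor before acceptor in transcription order, genomic distance <= 1 Mb) by
joining the last `flank_k` bases of the donor exon to the first `flank_k`
bases of the acceptor. Junction-spanning reads are kept when they map
uniquely with < 5 mismatches and overhang the joint on both sides;
junctions whose flanking exon ends carry a strain-unique SNV are excluded
as mapping-biased. Differential usage is scored with the A statistic
A = log2(strain1) - log2(strain2) on strain-summed normalized counts with a
0.25 pseudocount; |A| > 4 with >= 4 reads in one strain calls a junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MAX_JUNCTION_DIST = 1_000_000
MAX_MISMATCHES = 5
PSEUDOCOUNT = 0.25
A_THRESHOLD = 4.0
MIN_READS = 4
MIN_OVERHANG = 5

from .synthetic_data import revcomp


@dataclass(frozen=True)
class JunctionRecord:
    gene_id: str
    donor_idx: int  # transcription-order exon index
    acceptor_idx: int
    donor_end: int  # genomic junction key
    acceptor_start: int
    annotated: bool  # adjacent exons
    sequence: str | None = None

    @property
    def key(self) -> tuple:
        return (self.gene_id, self.donor_idx, self.acceptor_idx)


# ---------------------------------------------------------------- reference


def build_junction_reference(
    gene_models: Sequence,
    genome: str | None = None,
    flank_k: int = 45,
    max_dist: int = MAX_JUNCTION_DIST,
) -> list[JunctionRecord]:
    """Junctions for all ordered same-gene exon pairs within `max_dist`.

    Exons shorter than `flank_k` contribute their full length. Identical
    sequences are deduplicated (first junction kept) when a genome is
    supplied. Single-exon genes contribute nothing.
    """
    if flank_k < 10:
        raise ValueError("flank_k must be >= 10")
    out: list[JunctionRecord] = []
    seen_seq: set[str] = set()
    for g in gene_models:
        order = g.exons_in_transcription_order()
        for i in range(len(order) - 1):
            for j in range(i + 1, len(order)):
                (ds, de), (as_, ae) = order[i], order[j]
                if g.strand == "+":
                    dist = as_ - de
                    donor_end, acceptor_start = de, as_
                else:
                    dist = ds - ae
                    donor_end, acceptor_start = ds, ae
                if dist > max_dist:
                    continue
                seq = None
                if genome is not None:
                    if g.strand == "+":
                        left = genome[max(ds, de - flank_k) : de]
                        right = genome[as_ : min(ae, as_ + flank_k)]
                        seq = left + right
                    else:
                        left = revcomp(genome[ds : min(de, ds + flank_k)])
                        right = revcomp(genome[max(as_, ae - flank_k) : ae])
                        seq = left + right
                    if seq in seen_seq:
                        continue
                    seen_seq.add(seq)
                out.append(
                    JunctionRecord(
                        gene_id=g.gene_id,
                        donor_idx=i,
                        acceptor_idx=j,
                        donor_end=donor_end,
                        acceptor_start=acceptor_start,
                        annotated=(j == i + 1),
                        sequence=seq,
                    )
                )
    return out


# ----------------------------------------------------------------- counting


def count_junction_reads(
    placements: pd.DataFrame,
    flank_k: int,
    read_length: int = 50,
    max_mismatches: int = MAX_MISMATCHES,
    unique_only: bool = True,
    min_overhang: int = MIN_OVERHANG,
) -> pd.DataFrame:
    """Filter junction placements and count reads per junction per sample.

    `placements` columns: (sample, junction_id, n_hits, mismatches,
    offset); `offset` is the read start within the junction sequence whose
    joint sits at position `flank_k`. Retained reads map uniquely, have
    < max_mismatches mismatches, and overhang the joint by >= min_overhang
    on both sides.
    """
    ok = placements["mismatches"] < max_mismatches
    if unique_only:
        ok &= placements["n_hits"] == 1
    left = flank_k - placements["offset"]
    right = placements["offset"] + read_length - flank_k
    ok &= (left >= min_overhang) & (right >= min_overhang)
    kept = placements[ok]
    return (
        kept.groupby(["junction_id", "sample"])
        .size()
        .unstack(fill_value=0)
    )


# ---------------------------------------------------------------- exclusion


def exclude_biased(
    junctions: Sequence[JunctionRecord],
    snvs: Sequence[tuple[str, int]],
    gene_models: Sequence,
    flank_k: int,
) -> list[JunctionRecord]:
    """Drop junctions with a strain-unique SNV within `flank_k` bases of
    either exon end used to build them (`snvs` are (chrom, pos) 1-based)."""
    by_gene = {g.gene_id: g for g in gene_models}
    snv_pos: dict[str, np.ndarray] = {}
    for chrom, pos in snvs:
        snv_pos.setdefault(chrom, []).append(pos - 1)  # to 0-based
    snv_pos = {c: np.sort(np.asarray(p)) for c, p in snv_pos.items()}

    def has_snv(chrom: str, lo: int, hi: int) -> bool:
        arr = snv_pos.get(chrom)
        if arr is None:
            return False
        i = np.searchsorted(arr, lo, side="left")
        return i < len(arr) and arr[i] < hi

    out = []
    for j in junctions:
        g = by_gene[j.gene_id]
        order = g.exons_in_transcription_order()
        (ds, de) = order[j.donor_idx]
        (as_, ae) = order[j.acceptor_idx]
        if g.strand == "+":
            donor_iv = (max(ds, de - flank_k), de)
            acceptor_iv = (as_, min(ae, as_ + flank_k))
        else:
            donor_iv = (ds, min(de, ds + flank_k))
            acceptor_iv = (max(as_, ae - flank_k), ae)
        if has_snv(g.chrom, *donor_iv) or has_snv(g.chrom, *acceptor_iv):
            continue
        out.append(j)
    return out


# ----------------------------------------------------------- differential


def a_statistic(n1: float, n2: float, pseudocount: float = PSEUDOCOUNT) -> float:
    return float(np.log2(n1 + pseudocount) - np.log2(n2 + pseudocount))


def call_differential(
    junction_counts: pd.DataFrame,
    labels: Mapping[str, str],
    junctions: Sequence[JunctionRecord] | None = None,
    sample_totals: pd.Series | None = None,
    pseudocount: float = PSEUDOCOUNT,
    a_threshold: float = A_THRESHOLD,
    min_reads: int = MIN_READS,
) -> pd.DataFrame:
    """Differential junctions by the A statistic.

    `junction_counts` is junction x sample (indexed by junction key or id);
    `sample_totals` are per-sample gene-mapped read totals used for
    mean-total normalization (raw counts are used when omitted, i.e. equal
    totals). A junction is called when |A| > a_threshold and its larger
    strain raw count >= min_reads. Junctions with zero reads in both
    strains are skipped.
    """
    strains = sorted(set(labels.values()))
    if len(strains) != 2:
        raise ValueError("exactly two strains required")
    counts = junction_counts.astype(float)
    if sample_totals is not None:
        scale = sample_totals.mean() / sample_totals
        norm = counts * scale[counts.columns]
    else:
        norm = counts
    cols1 = [c for c in counts.columns if labels[c] == strains[0]]
    cols2 = [c for c in counts.columns if labels[c] == strains[1]]
    raw1 = junction_counts[cols1].sum(axis=1)
    raw2 = junction_counts[cols2].sum(axis=1)
    s1 = norm[cols1].sum(axis=1)
    s2 = norm[cols2].sum(axis=1)
    present = (raw1 + raw2) > 0
    a = np.log2(s1 + pseudocount) - np.log2(s2 + pseudocount)
    called = present & (a.abs() > a_threshold) & (
        pd.concat([raw1, raw2], axis=1).max(axis=1) >= min_reads
    )
    annotated = None
    if junctions is not None:
        flag = {j.key: j.annotated for j in junctions}
        annotated = [flag.get(k, None) for k in junction_counts.index]
    out = pd.DataFrame(
        {
            f"raw_{strains[0]}": raw1,
            f"raw_{strains[1]}": raw2,
            "A": a,
            "present": present,
            "called": called,
        },
        index=junction_counts.index,
    )
    if annotated is not None:
        out["annotated"] = annotated
    return out[out["present"]].drop(columns="present")
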