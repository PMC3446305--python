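"""Pileup-based SNV/indel calling by a filter cascade on the percentage of
non-reference reads (pnr), plus three-genome cross-filtering, two-caller
intersection and the heterozygous-SNV window-density analysis.

Decision rules: variant alleles need >= 3 supporting reads with mapping
quality > 30; reads mapping to multiple locations and clonal duplicates
(same start and strand) are discarded before counting; pnr < 10 is called
reference, 25 <= pnr <= 75 heterozygous (subject to a 3x-median-coverage
cap), pnr > 75 homozygous, and indels need pnr >= 40; SNVs within 10 bp of
an indel are masked. The pnr zones [10,25) and calls lacking high-quality
support are no-calls, and no-calls block strain-uniqueness: a variant is
strain-unique only when the other two genomes are explicitly called
reference at that position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HOM_PNR = 75.0
HET_PNR_LO = 25.0
REF_PNR = 10.0
INDEL_PNR = 40.0
MIN_HQ_SUPPORT = 3
COVERAGE_CAP_FOLD = 3.0
INDEL_MASK_BP = 10
MAX_INDEL_LEN = 10  # indels in this pipeline are < 11 bp


@dataclass(frozen=True)
class SiteSummary:
    chrom: str
    pos: int  # 1-based
    ref_base: str
    allele_counts: Mapping[str, int]
    hq_allele_counts: Mapping[str, int]
    depth: int
    indel_alleles: Mapping[str, int] | None = None
    hq_indel_alleles: Mapping[str, int] | None = None


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    type: str  # SNV | INS | DEL
    zygosity: str  # hom | het
    pnr: float
    support: int  # hq variant reads
    strain: str = "unknown"


def variant_type(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNV"
    return "INS" if len(alt) > len(ref) else "DEL"


# ------------------------------------------------------------ read filters


def filter_reads(reads: Iterable) -> list:
    """Drop multi-mapped reads and clonal duplicates.

    Each read record needs attributes/keys (start, strand, n_hits, mapq,
    allele). Among reads sharing (start, strand) exactly one is kept (the
    first in input order, so retention is deterministic).
    """
    seen: set[tuple] = set()
    kept = []
    for r in reads:
        get = r.get if isinstance(r, dict) else lambda k, _r=r: getattr(_r, k)
        if get("n_hits") > 1:
            continue
        key = (get("start"), get("strand"))
        if key in seen:
            continue
        seen.add(key)
        kept.append(r)
    return kept


# ------------------------------------------------------------- site calls


def call_site(site: SiteSummary, median_coverage: float) -> str:
    """Classify one site: reference / hom_SNV / het_SNV / hom_indel / no_call.

    The coverage cap (depth <= 3x median) applies to heterozygous
    candidates only.
    """
    if median_coverage <= 0:
        raise ValueError("median_coverage must be positive")
    if site.depth == 0:
        return "no_call"
    ref = site.ref_base
    indels = site.indel_alleles or {}
    hq_indels = site.hq_indel_alleles or {}
    indel_reads = sum(indels.values())
    if indel_reads:
        top_indel = max(indels, key=lambda a: indels[a])
        pnr_i = 100.0 * indel_reads / site.depth
        if pnr_i >= INDEL_PNR and hq_indels.get(top_indel, 0) >= MIN_HQ_SUPPORT:
            return "hom_indel"
    nonref = site.depth - site.allele_counts.get(ref, 0) - indel_reads
    pnr = 100.0 * (nonref + indel_reads) / site.depth
    alts = {a: c for a, c in site.allele_counts.items() if a != ref and c > 0}
    if pnr < REF_PNR:
        return "reference"
    if not alts:
        return "no_call"
    top_alt = max(alts, key=lambda a: alts[a])
    hq = (site.hq_allele_counts or {}).get(top_alt, 0)
    if pnr > HOM_PNR:
        return "hom_SNV" if hq >= MIN_HQ_SUPPORT else "no_call"
    if HET_PNR_LO <= pnr <= HOM_PNR:
        if site.depth > COVERAGE_CAP_FOLD * median_coverage:
            return "no_call"
        return "het_SNV" if hq >= MIN_HQ_SUPPORT else "no_call"
    return "no_call"


def median_coverage(sites: pd.DataFrame) -> float:
    """Genome-wide median depth over covered positions."""
    d = sites["depth"].to_numpy()
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("no covered positions")
    return float(np.median(d))


def call_sites(sites: pd.DataFrame, med_cov: float | None = None) -> pd.DataFrame:
    """Vectorized pnr cascade over a site-summary table.

    Input columns: chrom, pos, ref, alt, ref_count, alt_count, hq_alt,
    indel_count, hq_indel, indel_ref, indel_alt, depth (as produced by
    ``synthetic_data.simulate_site_summaries``). Returns the table with a
    ``label`` column; equivalent site by site to :func:`call_site`.
    """
    if med_cov is None:
        med_cov = median_coverage(sites)
    depth = sites["depth"].to_numpy()
    alt = sites["alt_count"].to_numpy()
    hq_alt = sites["hq_alt"].to_numpy()
    indel = sites["indel_count"].to_numpy()
    hq_indel = sites["hq_indel"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pnr = np.where(depth > 0, 100.0 * (alt + indel) / np.maximum(depth, 1), 0.0)
        pnr_i = np.where(depth > 0, 100.0 * indel / np.maximum(depth, 1), 0.0)
    label = np.full(len(sites), "no_call", dtype=object)
    covered = depth > 0
    is_indel_call = covered & (pnr_i >= INDEL_PNR) & (hq_indel >= MIN_HQ_SUPPORT)
    label[is_indel_call] = "hom_indel"
    rest = covered & ~is_indel_call
    label[rest & (pnr < REF_PNR)] = "reference"
    has_alt = alt > 0
    hom = rest & (pnr > HOM_PNR) & has_alt & (hq_alt >= MIN_HQ_SUPPORT)
    label[hom] = "hom_SNV"
    het = (
        rest
        & (pnr >= HET_PNR_LO)
        & (pnr <= HOM_PNR)
        & has_alt
        & (hq_alt >= MIN_HQ_SUPPORT)
        & (depth <= COVERAGE_CAP_FOLD * med_cov)
    )
    label[het] = "het_SNV"
    out = sites.copy()
    out["pnr"] = pnr
    out["label"] = label
    return out


def site_row_to_summary(row) -> SiteSummary:
    """Adapter from a site-summary table row to the SiteSummary dataclass."""
    ref = row["ref"]
    alleles = {ref: int(row["ref_count"])}
    hq = {ref: int(row.get("hq_ref", row["ref_count"]))}
    if row["alt_count"] > 0:
        alleles[row["alt"]] = int(row["alt_count"])
        hq[row["alt"]] = int(row["hq_alt"])
    indels = hq_indels = None
    if row["indel_count"] > 0:
        key = f"{row['indel_ref']}>{row['indel_alt']}"
        indels = {key: int(row["indel_count"])}
        hq_indels = {key: int(row["hq_indel"])}
    return SiteSummary(
        chrom=row["chrom"],
        pos=int(row["pos"]),
        ref_base=ref,
        allele_counts=alleles,
        hq_allele_counts=hq,
        depth=int(row["depth"]),
        indel_alleles=indels,
        hq_indel_alleles=hq_indels,
    )


def calls_from_labels(labeled: pd.DataFrame, strain: str) -> list[VariantCall]:
    """Materialize VariantCall records for the variant labels of call_sites."""
    out = []
    var = labeled[labeled["label"].isin(["hom_SNV", "het_SNV", "hom_indel"])]
    for row in var.itertuples(index=False):
        if row.label == "hom_indel":
            ref, alt = row.indel_ref, row.indel_alt
            out.append(
                VariantCall(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=ref,
                    alt=alt,
                    type=variant_type(ref, alt),
                    zygosity="hom",
                    pnr=float(row.pnr),
                    support=int(row.hq_indel),
                    strain=strain,
                )
            )
        else:
            out.append(
                VariantCall(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    type="SNV",
                    zygosity="hom" if row.label == "hom_SNV" else "het",
                    pnr=float(row.pnr),
                    support=int(row.hq_alt),
                    strain=strain,
                )
            )
    return out


# ------------------------------------------------------- indel proximity


def mask_snvs_near_indels(
    calls: Sequence[VariantCall],
    candidate_indel_positions: Sequence[tuple[str, int]] = (),
    window: int = INDEL_MASK_BP,
) -> list[VariantCall]:
    """Remove SNVs within `window` bp (inclusive) of any called or candidate
    indel on the same chromosome; indel calls pass through untouched."""
    indel_pos: dict[str, list[int]] = {}
    for c in calls:
        if c.type != "SNV":
            indel_pos.setdefault(c.chrom, []).append(c.pos)
    for chrom, pos in candidate_indel_positions:
        indel_pos.setdefault(chrom, []).append(pos)
    for v in indel_pos.values():
        v.sort()
    out = []
    for c in calls:
        if c.type != "SNV":
            out.append(c)
            continue
        positions = indel_pos.get(c.chrom, [])
        i = np.searchsorted(positions, c.pos)
        near = False
        for j in (i - 1, i):
            if 0 <= j < len(positions) and abs(positions[j] - c.pos) <= window:
                near = True
        if not near:
            out.append(c)
    return out


# -------------------------------------------------- three-genome filter


def strain_unique(
    calls_by_strain: Mapping[str, Sequence[VariantCall]],
    labels_by_strain: Mapping[str, pd.DataFrame],
) -> dict[str, list[VariantCall]]:
    """Keep variants called in exactly one strain and explicitly called
    reference (not merely uncovered or no_call) in the two other genomes.

    `labels_by_strain` maps every strain (including the reference
    resequencing pseudo-strain) to a call_sites output table.
    """
    if len(labels_by_strain) < 3:
        raise ValueError("cross-filtering needs three call sets")
    ref_sets = {
        s: set(
            zip(df.loc[df["label"] == "reference", "chrom"],
                df.loc[df["label"] == "reference", "pos"])
        )
        for s, df in labels_by_strain.items()
    }
    out: dict[str, list[VariantCall]] = {}
    for strain, calls in calls_by_strain.items():
        others = [s for s in labels_by_strain if s != strain]
        kept = [
            c
            for c in calls
            if all((c.chrom, c.pos) in ref_sets[o] for o in others)
        ]
        out[strain] = kept
    return out


# ------------------------------------------------------ caller intersection


def left_align(
    ref: str, alt: str, pos: int, sequence_before: str = ""
) -> tuple[int, str, str]:
    """Minimal left-aligned representation of an (anchored) indel.

    Trims shared suffix and prefix bases down to the anchored minimal form,
    then, when reference context ending just before `pos` (1-based) is
    supplied, shifts the indel left through repeated sequence.
    """
    r, a, ctx = ref, alt, sequence_before
    while r and a and r[-1] == a[-1]:
        if len(r) == 1 or len(a) == 1:
            if not ctx:
                break
            b = ctx[-1]
            ctx = ctx[:-1]
            r, a = b + r[:-1], b + a[:-1]
            pos -= 1
        else:
            r, a = r[:-1], a[:-1]
    while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos += 1
    return pos, r, a


def intersect_callsets(
    primary: Sequence[VariantCall], secondary: Sequence[VariantCall]
) -> list[VariantCall]:
    """Consensus of two call sets: records matching on (chrom, pos, alt,
    strain); indels are compared on their minimally trimmed representation."""

    def key(c: VariantCall):
        pos, r, a = left_align(c.ref, c.alt, c.pos)
        return (c.chrom, pos, r, a, c.strain)

    sec = {key(c) for c in secondary}
    return [c for c in primary if key(c) in sec]


# ---------------------------------------------------- het-window analysis


@dataclass
class WindowAnalysis:
    fraction_in_dense: float | None
    n_total: int
    windows: pd.DataFrame  # chrom, start, end, n_het_snvs, dense
    top_windows: pd.DataFrame
    duplication_overlap_fraction: float | None = None


def het_window_analysis(
    het_snvs: Sequence[tuple[str, int]],
    chrom_lengths: Mapping[str, int],
    window: int = 100_000,
    dense_if_more_than: int = 3,
    top_fraction: float = 0.01,
    duplications: Sequence[tuple[str, int, int]] | None = None,
) -> WindowAnalysis:
    """Tile chromosomes in fixed windows, count heterozygous SNVs per
    window, and report the fraction of SNVs in dense (> threshold) windows,
    the top-`top_fraction` windows by count, and optionally the fraction of
    those dense regions overlapping a duplication set."""
    frames = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, window)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + window, length),
                }
            )
        )
    windows = pd.concat(frames, ignore_index=True)
    counts = {chrom: np.zeros((length + window - 1) // window, dtype=int)
              for chrom, length in chrom_lengths.items()}
    n_total = 0
    for chrom, pos in het_snvs:
        counts[chrom][(pos - 1) // window] += 1
        n_total += 1
    windows["n_het_snvs"] = np.concatenate(
        [counts[chrom] for chrom in chrom_lengths]
    )
    windows["dense"] = windows["n_het_snvs"] > dense_if_more_than
    if n_total == 0:
        fraction = None
    else:
        fraction = float(
            windows.loc[windows["dense"], "n_het_snvs"].sum() / n_total
        )
    n_top = max(1, int(round(top_fraction * len(windows))))
    occupied = windows[windows["n_het_snvs"] > 0]
    top = occupied.nlargest(min(n_top, len(occupied)), "n_het_snvs")
    dup_frac = None
    if duplications is not None and len(top):
        hits = 0
        for row in top.itertuples(index=False):
            if any(
                d[0] == row.chrom and d[1] < row.end and d[2] > row.start
                for d in duplications
            ):
                hits += 1
        dup_frac = hits / len(top)
    return WindowAnalysis(fraction, n_total, windows, top, dup_frac)


def simulate_random_positions(
    n: int, chrom_lengths: Mapping[str, int], seed: int
) -> list[tuple[str, int]]:
    """n positions uniform over the genome; 1-based, reproducible per seed."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    cum = np.cumsum(lengths)
    draws = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, draws, side="right")
    offsets = draws - (cum[idx] - lengths[idx])
    return [(chroms[i], int(o) + 1) for i, o in zip(idx, offsets)]


def dense_window_percentage(
    n_snvs: int,
    chrom_lengths: Mapping[str, int],
    seed: int,
    n_replicates: int = 100,
    window: int = 100_000,
    dense_if_more_than: int = 3,
) -> float:
    """Mean percentage of uniformly placed SNVs that land in windows with
    more than `dense_if_more_than` SNVs, over seeded replicates."""
    rng = np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    n_win = (lengths + window - 1) // window
    offsets = np.concatenate([[0], np.cumsum(n_win)])
    cum = np.cumsum(lengths)
    total_windows = int(offsets[-1])
    fracs = np.empty(n_replicates)
    for r in range(n_replicates):
        draws = rng.integers(0, cum[-1], size=n_snvs)
        ci = np.searchsorted(cum, draws, side="right")
        w = offsets[ci] + (draws - (cum[ci] - lengths[ci])) // window
        counts = np.bincount(w, minlength=total_windows)
        fracs[r] = counts[counts > dense_if_more_than].sum() / n_snvs
    return float(fracs.mean() * 100.0)
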