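"""Variant consequence classification and variant-to-expression statistics.

A simplified consequence classifier evaluates small variants against gene
models at codon level (stop gain/loss, missense, synonymous, frameshift,
in-frame indel), flags the two intronic bases next to each exon as
essential splice sites, and assigns UTR / 5-kb-upstream / intronic /
intergenic positions by interval. SV-gene overlaps distinguish full from
partial duplications and deletions. On top of these, the module computes
the integration statistics: the predictive value of each variant class
(fraction of expressed variant-bearing genes that are differentially
expressed), upstream small-variant density in DE versus non-DE genes,
allele-specific expression calls at heterozygous exonic SNVs, and
intronic repeat-rich deletions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .synthetic_data import GeneModel

SEVERITY_ORDER = [
    "stop_gain",
    "frameshift",
    "stop_loss",
    "essential_splice",
    "missense",
    "inframe_indel",
    "synonymous",
    "utr5",
    "utr3",
    "upstream5kb",
    "intronic",
    "intergenic",
]
_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}
STOP_VARIANT_CLASSES = {"stop_gain", "frameshift", "essential_splice"}
UPSTREAM_WINDOW = 5000
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Consequence:
    variant_id: str
    gene_id: str | None
    consequence: str


@dataclass(frozen=True)
class SvGeneOverlap:
    sv_id: str
    gene_id: str
    relation: str  # full_dup | partial_dup | full_del | partial_del | other


def most_severe(classes: Sequence[str]) -> str:
    return min(classes, key=lambda c: _RANK[c])


# --------------------------------------------------------- small variants


def _cds_positions(gene: GeneModel) -> list[int]:
    """Genomic positions of the CDS in transcription (translation) order."""
    ivs = gene.cds_intervals()
    if gene.strand == "+":
        return [p for s, e in ivs for p in range(s, e)]
    return [p for s, e in reversed(ivs) for p in range(e - 1, s - 1, -1)]


def _codon_classes(
    gene: GeneModel, genome: str, p0: int, ref: str, alt: str
) -> str:
    pos_list = _cds_positions(gene)
    idx = pos_list.index(p0)
    ci = idx // 3
    codon_pos = pos_list[ci * 3 : ci * 3 + 3]
    if len(codon_pos) < 3:
        return "synonymous"  # truncated terminal codon in the model
    bases = [genome[p] for p in codon_pos]
    within = idx % 3
    if gene.strand == "-":
        bases = [b.translate(_COMP) for b in bases]
        alt_t = alt.translate(_COMP)
    else:
        alt_t = alt
    ref_codon = "".join(bases)
    alt_codon = ref_codon[:within] + alt_t + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop_gain"
    if ref_aa == "*":
        return "stop_loss"
    return "missense"


def classify_small_variant(
    variant,
    gene_models: Sequence[GeneModel],
    genome: str,
    upstream_window: int = UPSTREAM_WINDOW,
) -> list[Consequence]:
    """Most-severe consequence of one variant per overlapping gene.

    `variant` carries (chrom, pos [1-based], ref, alt); SNVs are evaluated
    at codon level inside CDS, indels by the mod-3 rule. A variant hitting
    no gene annotation is intergenic.
    """
    is_snv = len(variant.ref) == 1 and len(variant.alt) == 1
    # 0-based position of the first changed base (indels are anchored)
    p0 = variant.pos - 1 if is_snv else variant.pos
    vid = f"{variant.chrom}:{variant.pos}:{variant.ref}>{variant.alt}"
    out = []
    for g in gene_models:
        if g.chrom != variant.chrom:
            continue
        us, ue = g.upstream_interval(upstream_window)
        if not (min(g.start, us) <= p0 < max(g.end, ue)):
            continue
        classes = []
        if us <= p0 < ue:
            classes.append("upstream5kb")
        if g.start <= p0 < g.end:
            in_cds = any(s <= p0 < e for s, e in g.cds_intervals())
            if in_cds:
                if is_snv:
                    classes.append(
                        _codon_classes(g, genome, p0, variant.ref, variant.alt)
                    )
                else:
                    indel_len = abs(len(variant.ref) - len(variant.alt))
                    classes.append(
                        "frameshift" if indel_len % 3 else "inframe_indel"
                    )
            else:
                utr5, utr3 = g.utr_intervals()
                in_exon = any(s <= p0 < e for s, e in g.exons)
                if in_exon:
                    if any(s <= p0 < e for s, e in utr5):
                        classes.append("utr5")
                    elif any(s <= p0 < e for s, e in utr3):
                        classes.append("utr3")
                else:
                    splice = False
                    for is_, ie in g.introns():
                        if p0 in (is_, is_ + 1, ie - 2, ie - 1):
                            splice = True
                            break
                    classes.append("essential_splice" if splice else "intronic")
        if classes:
            out.append(Consequence(vid, g.gene_id, most_severe(classes)))
    if not out:
        out.append(Consequence(vid, None, "intergenic"))
    return out


def classify_variants(
    variants: Sequence, gene_models: Sequence[GeneModel], genome: str
) -> list[Consequence]:
    out = []
    for v in variants:
        out.extend(classify_small_variant(v, gene_models, genome))
    return out


# ------------------------------------------------------------ SV overlap


def overlap_svs(
    svs: Sequence[tuple], gene_models: Sequence[GeneModel]
) -> list[SvGeneOverlap]:
    """Gene overlap relations for SVs given as (type, chrom, start, end).

    CNV segments and mate-pair calls of the same type should be merged into
    one list before this analysis; containment of the full gene span makes
    a full_* relation, any other intersection partial_*.
    """
    out = []
    for i, (svtype, chrom, start, end) in enumerate(svs):
        sv_id = f"{svtype}:{chrom}:{start}-{end}"
        for g in gene_models:
            if g.chrom != chrom or g.end <= start or g.start >= end:
                continue
            if svtype in ("DUP", "DEL"):
                kind = "dup" if svtype == "DUP" else "del"
                full = start <= g.start and g.end <= end
                relation = f"{'full' if full else 'partial'}_{kind}"
            else:
                relation = "other"
            out.append(SvGeneOverlap(sv_id, g.gene_id, relation))
    return out


def sv_records(calls) -> list[tuple]:
    """Normalize CnvSegment / SvCall objects to (type, chrom, start, end)."""
    out = []
    for c in calls:
        svtype = getattr(c, "type", None) or getattr(c, "cnv_class", None)
        out.append((svtype, c.chrom, c.start, c.end))
    return out


# ------------------------------------------------------- predictive value


def predictive_value(
    consequences: Sequence[Consequence],
    sv_overlaps: Sequence[SvGeneOverlap],
    expressed: set[str],
    de: set[str],
    stop_group: bool = True,
) -> pd.DataFrame:
    """Per variant class: expressed genes carrying >= 1 variant of the
    class, the number of those differentially expressed, and their ratio
    (the class's predictive value; null when no gene is expressed)."""
    genes_by_class: dict[str, set[str]] = {}
    for c in consequences:
        if c.gene_id is not None:
            genes_by_class.setdefault(c.consequence, set()).add(c.gene_id)
    for o in sv_overlaps:
        genes_by_class.setdefault(o.relation, set()).add(o.gene_id)
    if stop_group:
        grouped = set()
        for cls in STOP_VARIANT_CLASSES:
            grouped |= genes_by_class.get(cls, set())
        genes_by_class["stop_variant"] = grouped
    rows = []
    for cls, genes in sorted(genes_by_class.items()):
        n_exp = len(genes & expressed)
        n_de = len(genes & expressed & de)
        rows.append(
            {
                "variant_class": cls,
                "n_expressed": n_exp,
                "n_de": n_de,
                "fraction": (n_de / n_exp) if n_exp else None,
            }
        )
    return pd.DataFrame(rows)


def predictive_fraction(n_de: int, n_expressed: int) -> float | None:
    """Predictive value of a class from its two counts."""
    if n_expressed <= 0:
        return None
    return n_de / n_expressed


# ------------------------------------------------------- upstream density


@dataclass
class UpstreamDensity:
    mean_snv_de: float
    mean_snv_other: float
    mean_indel_de: float
    mean_indel_other: float
    p_snv: float
    p_indel: float
    per_gene: pd.DataFrame


def upstream_density(
    variants: Sequence,
    gene_models: Sequence[GeneModel],
    de_genes: set[str],
    window: int = UPSTREAM_WINDOW,
) -> UpstreamDensity:
    """SNV and indel counts in the strand-aware [TSS - 5 kb, TSS) window of
    each gene, compared between DE and non-DE genes by a two-tailed
    two-sample t-test. Overlapping upstream windows count independently."""
    pos_by_chrom: dict[str, list[tuple[int, bool]]] = {}
    for v in variants:
        is_snv = len(v.ref) == 1 and len(v.alt) == 1
        pos_by_chrom.setdefault(v.chrom, []).append((v.pos - 1, is_snv))
    rows = []
    for g in gene_models:
        us, ue = g.upstream_interval(window)
        snv = indel = 0
        for p, is_snv in pos_by_chrom.get(g.chrom, []):
            if us <= p < ue:
                if is_snv:
                    snv += 1
                else:
                    indel += 1
        rows.append(
            {
                "gene_id": g.gene_id,
                "n_snv": snv,
                "n_indel": indel,
                "de": g.gene_id in de_genes,
            }
        )
    per_gene = pd.DataFrame(rows)
    de_mask = per_gene["de"]

    def _test(col: str) -> tuple[float, float, float]:
        a = per_gene.loc[de_mask, col].to_numpy(dtype=float)
        b = per_gene.loc[~de_mask, col].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            return float("nan"), float("nan"), float("nan")
        if a.var() == 0 and b.var() == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
            return a.mean(), b.mean(), p
        t = stats.ttest_ind(a, b, equal_var=True)
        return a.mean(), b.mean(), float(t.pvalue)

    ms_de, ms_o, p_s = _test("n_snv")
    mi_de, mi_o, p_i = _test("n_indel")
    return UpstreamDensity(ms_de, ms_o, mi_de, mi_o, p_s, p_i, per_gene)


# ------------------------------------------------- allele-specific expression


def allele_specific_expression(
    allele_counts: pd.DataFrame,
    min_cov: int = 8,
    min_minor_reads: int = 2,
    min_minor_frac: float = 0.1,
) -> pd.DataFrame:
    """Biallelic / monoallelic / uninformative call per heterozygous site.

    `allele_counts` columns: (chrom, pos, ref_count, alt_count). A site is
    biallelic when coverage >= min_cov and the minor allele has both
    >= min_minor_reads reads and >= min_minor_frac of the coverage.
    """
    out = allele_counts.copy()
    cov = out["ref_count"] + out["alt_count"]
    minor = out[["ref_count", "alt_count"]].min(axis=1)
    call = np.where(
        cov < min_cov,
        "uninformative",
        np.where(
            (minor >= min_minor_reads) & (minor >= min_minor_frac * cov),
            "biallelic",
            "monoallelic",
        ),
    )
    out["coverage"] = cov
    out["call"] = call
    return out


def ase_gene_summary(
    ase_calls: pd.DataFrame, gene_models: Sequence[GeneModel]
) -> pd.DataFrame:
    """Per-gene 'x of y exonic sites biallelic' summary."""
    rows = []
    for g in gene_models:
        sub = ase_calls[
            (ase_calls["chrom"] == g.chrom)
            & ase_calls["pos"].sub(1).apply(
                lambda p: any(s <= p < e for s, e in g.exons)
            )
        ]
        informative = sub[sub["call"] != "uninformative"]
        rows.append(
            {
                "gene_id": g.gene_id,
                "n_sites": len(informative),
                "n_biallelic": int((informative["call"] == "biallelic").sum()),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------- intronic repeat deletions


def intronic_repeat_deletions(
    deletions: Sequence[tuple],
    repeats: Sequence[tuple],
    gene_models: Sequence[GeneModel],
    min_repeat: int = 2000,
) -> pd.DataFrame:
    """Per deletion (chrom, start, end): total repeat overlap in bp,
    whether it lies entirely within one intron of some gene, and the flag
    for repeat-rich (> min_repeat bp) intronic deletions."""
    merged: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        merged.setdefault(r[0], []).append((r[1], r[2]))
    for chrom in merged:
        ivs = sorted(merged[chrom])
        out_ivs = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out_ivs[-1][1]:
                out_ivs[-1][1] = max(out_ivs[-1][1], e)
            else:
                out_ivs.append([s, e])
        merged[chrom] = [(s, e) for s, e in out_ivs]
    rows = []
    for chrom, start, end in deletions:
        rep = sum(
            max(0, min(end, e) - max(start, s))
            for s, e in merged.get(chrom, [])
        )
        intronic = any(
            g.chrom == chrom and any(s <= start and end <= e for s, e in g.introns())
            for g in gene_models
        )
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "repeat_bp": rep,
                "intronic": intronic,
                "flagged": intronic and rep > min_repeat,
            }
        )
    return pd.DataFrame(rows)
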