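"""File input/output helpers.

All in-memory coordinates are 0-based half-open. Emitted VCF and GFF3 are
1-based inclusive as the formats require; BED stays 0-based half-open.
Readers delegate to pyfaidx (FASTA), gffutils (GFF3), pysam (VCF) and
pandas (tabular); the writers here are small text emitters for objects this
package creates itself.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd


# ---------------------------------------------------------------- FASTA


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, rebuild=True)
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


# ---------------------------------------------------------------- GFF3


def write_gff3(path: str | os.PathLike, genes: Sequence) -> None:
    """Write GeneModel records as gene/mRNA/exon/CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tvarxome\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tvarxome\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for (s, e) in g.exons:
                fh.write(
                    f"{g.chrom}\tvarxome\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={mrna_id}\n"
                )
            for (s, e) in g.cds_intervals():
                fh.write(
                    f"{g.chrom}\tvarxome\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={mrna_id}\n"
                )


def read_gff3(path: str | os.PathLike):
    """Parse a GFF3 written by :func:`write_gff3` back into GeneModel objects."""
    import gffutils

    from .synthetic_data import GeneModel

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = tuple(
            sorted((f.start - 1, f.end) for f in db.children(g, featuretype="exon"))
        )
        cds = sorted((f.start - 1, f.end) for f in db.children(g, featuretype="CDS"))
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand,
                exons=exons,
                cds_start=cds[0][0],
                cds_end=cds[-1][1],
            )
        )
    return genes


# ---------------------------------------------------------------- BED / BEDPE


def write_bed(path: str | os.PathLike, rows: Iterable[tuple]) -> None:
    """Rows are (chrom, start, end, *extra) with 0-based half-open intervals."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | os.PathLike, names: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if names is not None:
        df.columns = list(names) + list(df.columns[len(names) :])
    else:
        base = ["chrom", "start", "end", "name", "score", "strand"]
        df.columns = base[: df.shape[1]] + list(df.columns[len(base) :])
    return df


# ---------------------------------------------------------------- TSV


def write_tsv(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------- VCF

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=PNR,Number=1,Type=Float,Description="Percent non-reference reads">
##INFO=<ID=HQSUP,Number=1,Type=Integer,Description="Variant reads with mapping quality > 30">
##INFO=<ID=STRAIN,Number=1,Type=String,Description="Strain carrying the variant">
##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity (hom or het)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(path: str | os.PathLike, calls: Sequence, contigs: Mapping[str, int] | None = None) -> None:
    """Write VariantCall records; `pos` is 1-based as in VCF."""
    with open(path, "w") as fh:
        lines = _VCF_HEADER.splitlines(keepends=True)
        fh.write(lines[0])
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.writelines(lines[1:])
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            info = f"PNR={c.pnr:.1f};HQSUP={c.support};STRAIN={c.strain};ZYG={c.zygosity}"
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n")


def read_vcf(path: str | os.PathLike, strain: str | None = None):
    """Read an (uncompressed) VCF into VariantCall records via pysam."""
    import pysam

    from .small_variants import VariantCall, variant_type

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else rec.ref
            info = dict(rec.info)
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    type=variant_type(rec.ref, alt),
                    zygosity=str(info.get("ZYG", "hom")),
                    pnr=float(info.get("PNR", 100.0)),
                    support=int(info.get("HQSUP", 0)),
                    strain=strain or str(info.get("STRAIN", "unknown")),
                )
            )
    return calls
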