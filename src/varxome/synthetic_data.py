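"""Truth-bearing synthetic data for every pipeline stage.

Generates a random genome with gene models, then per-stage inputs — pileup
site summaries, binned coverage tracks, mate-pair tables and RNA-seq count
tables — each with a known truth set, so that variant calling, CNV
segmentation, SV calling, differential expression and splicing analysis can
all be tested end-to-end without any external data.

Noise models are deliberately the simplest ones consistent with the data
types being emulated: Poisson site/bin coverage, Binomial allele sampling,
Normal mate-pair insert sizes and Gamma-Poisson (negative binomial) RNA-seq
counts. All internal coordinates are 0-based half-open; tables that emulate
pileup output carry a 1-based ``pos`` column, matching VCF convention.

Two strains ("strain1", emulating BN-Lx, and "strain2", emulating SHR) are
simulated against a reference-like third pseudo-strain ("reference") that
plays the role of the reference-strain resequencing data used for
cross-filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}

DEFAULT_STRAINS = ("strain1", "strain2", "reference")


class SizingError(ValueError):
    """Requested gene count cannot be packed into the requested genome."""


# ------------------------------------------------------------------ types


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of one gene. Coordinates 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted by genomic coordinate
    cds_start: int
    cds_end: int

    def cds_intervals(self) -> list[tuple[int, int]]:
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return out

    def utr_intervals(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(5'UTR, 3'UTR) exonic intervals, strand-aware."""
        left, right = [], []
        for s, e in self.exons:
            if s < self.cds_start:
                left.append((s, min(e, self.cds_start)))
            if e > self.cds_end:
                right.append((max(s, self.cds_end), e))
        return (left, right) if self.strand == "+" else (right, left)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    def upstream_interval(self, k: int) -> tuple[int, int]:
        if self.strand == "+":
            return (max(0, self.start - k), self.start)
        return (self.end, self.end + k)

    def exons_in_transcription_order(self) -> list[tuple[int, int]]:
        return list(self.exons) if self.strand == "+" else list(self.exons[::-1])


@dataclass
class TruthSet:
    """Ground truth embedded in a simulated study.

    variants: (chrom, pos0, ref, alt, strain, zygosity); indels use the
    VCF-style anchored representation (ref/alt share a leading base).
    cnvs: (chrom, start, end, copy_ratio, strain).
    svs: (type, chrom, start, end, strain), type in {DEL, DUP, INV, INS}.
    de_genes: (gene_id, true_fold_change) with fold = strain1/strain2 mean.
    splice_events: (gene_id, skipped_exon_index, strain), index in
    transcription order.  ase_sites: (chrom, pos0, allele_fraction).
    """

    variants: list = field(default_factory=list)
    cnvs: list = field(default_factory=list)
    svs: list = field(default_factory=list)
    de_genes: list = field(default_factory=list)
    splice_events: list = field(default_factory=list)
    ase_sites: list = field(default_factory=list)

    def to_json(self) -> dict:
        return asdict(self)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ------------------------------------------------------------------ genome


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n sense codons (no in-frame stop)."""
    out = []
    while len(out) < n:
        chunk = [
            "".join(c)
            for c in rng.choice(list("ACGT"), size=(n - len(out), 3))
        ]
        out.extend(c for c in chunk if c not in _STOPS)
    return "".join(out[:n])


def make_genome(
    length: int,
    n_genes: int,
    seed: int,
    chrom: str = "chr1",
    flank: int = 5000,
    n_repeats: int | None = None,
):
    """Random genome with `n_genes` multi-exon protein-coding gene models.

    Returns (sequence, genes, repeats) where repeats is a list of
    (chrom, start, end, family) intervals. Genes are non-overlapping, have
    >= 2 exons, UTRs, an ATG...stop CDS whose length is a multiple of 3,
    and at least `flank` bp of intergenic sequence on each side.
    """
    if length < 10_000:
        raise SizingError(f"genome length {length} < 10 kb")
    if n_genes < 1:
        raise SizingError("need at least one gene")
    slot = length // n_genes
    min_gene_span = 2 * 150 + 1 * 100 + 1  # 2 exons + 1 intron, lower bound
    if slot < 2 * flank + min_gene_span:
        raise SizingError(
            f"cannot place {n_genes} genes with {flank} bp flanks in {length} bp"
        )
    rng = np.random.default_rng(seed)
    genome = bytearray(rng.choice(_BASES, size=length).tobytes())

    genes: list[GeneModel] = []
    for i in range(n_genes):
        lo, hi = i * slot + flank, (i + 1) * slot - flank
        avail = hi - lo
        n_ex = int(rng.integers(2, 6))
        exon_lens = rng.integers(120, 400, size=n_ex)
        while exon_lens.sum() + (n_ex - 1) * 60 + 1 > avail:
            n_ex = max(2, n_ex - 1)
            exon_lens = rng.integers(120, 300, size=n_ex)
        intron_budget = avail - int(exon_lens.sum())
        max_intron = min(2000, max(60, intron_budget // max(1, n_ex - 1) - 1))
        intron_lens = rng.integers(60, max(61, max_intron), size=n_ex - 1)

        total_exonic = int(exon_lens.sum())
        u5 = int(rng.integers(20, min(100, exon_lens[0] - 10)))
        u3 = int(rng.integers(20, min(100, exon_lens[-1] - 10)))
        cds_len = total_exonic - u5 - u3
        u3 += cds_len % 3
        cds_len -= cds_len % 3
        mrna = (
            "".join(rng.choice(list("ACGT"), size=u5))
            + "ATG"
            + _random_codons(rng, cds_len // 3 - 2)
            + "TAA"
            + "".join(rng.choice(list("ACGT"), size=u3))
        )

        span = total_exonic + int(intron_lens.sum())
        gstart = lo + int(rng.integers(0, max(1, avail - span)))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        p = gstart
        for j, el in enumerate(exon_lens):
            exons.append((p, p + int(el)))
            p += int(el)
            if j < n_ex - 1:
                p += int(intron_lens[j])
        gend = exons[-1][1]

        # map transcript coordinates onto the genome
        order = exons if strand == "+" else exons[::-1]
        tpos = []
        for s, e in order:
            tpos.extend(range(s, e) if strand == "+" else range(e - 1, s - 1, -1))
        tpos = np.asarray(tpos)
        painted = mrna if strand == "+" else mrna.translate(_COMPLEMENT)
        for gp, base in zip(tpos, painted):
            genome[gp] = ord(base)
        cds_positions = tpos[u5 : u5 + cds_len]
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1}",
                chrom=chrom,
                start=gstart,
                end=gend,
                strand=strand,
                exons=tuple(exons),
                cds_start=int(cds_positions.min()),
                cds_end=int(cds_positions.max()) + 1,
            )
        )

    if n_repeats is None:
        n_repeats = max(2, length // 20_000)
    repeats = []
    fams = ["LINE", "LTR", "SINE"]
    for _ in range(n_repeats):
        rlen = int(rng.integers(300, 3000))
        rs = int(rng.integers(0, max(1, length - rlen)))
        repeats.append((chrom, rs, rs + rlen, fams[int(rng.integers(0, 3))]))
    repeats.sort(key=lambda r: r[1])
    return genome.decode(), genes, repeats


# -------------------------------------------------------- site summaries


def simulate_site_summaries(
    genome: str,
    truth_variants: Sequence[tuple],
    depth_mean: float,
    error_rate: float,
    seed: int,
    strains: Sequence[str] = DEFAULT_STRAINS,
    chrom: str = "chr1",
    hq_fraction: float = 0.95,
    het_fraction: float = 0.5,
    multimap_rate: float = 0.02,
    clonal_rate: float = 0.02,
) -> dict[str, pd.DataFrame]:
    """Per-strain pileup-style site summaries over every genome position.

    Each table has 1-based ``pos`` and columns ref/alt read counts, the
    subsets with mapping quality > 30 (``hq_*``), counts of discarded
    multi-mapped and clonal reads, and indel-supporting read counts.
    Homozygous alt sites draw alt reads Binomial(depth, 1 - error_rate),
    heterozygous Binomial(depth, het_fraction), reference sites
    Binomial(depth, error_rate).
    """
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    n = len(genome)
    for v in truth_variants:
        if not 0 <= v[1] < n:
            raise ValueError(f"truth position {v[1]} outside genome of {n} bp")
    ref_arr = np.frombuffer(genome.encode(), dtype="S1")
    out: dict[str, pd.DataFrame] = {}
    for si, strain in enumerate(strains):
        rng = np.random.default_rng([seed, si])
        depth = rng.poisson(depth_mean, size=n)
        alt_p = np.full(n, error_rate)
        alt_base = np.full(n, b"N", dtype="S1")
        # random error allele everywhere, overridden at truth sites
        shift = rng.integers(1, 4, size=n)
        alt_base = _BASES[(np.searchsorted(_BASES, ref_arr) + shift) % 4]
        is_indel = np.zeros(n, dtype=bool)
        indel_alt = np.empty(n, dtype=object)
        indel_ref = np.empty(n, dtype=object)
        for chrom_v, pos, ref, alt, v_strain, zyg in truth_variants:
            if v_strain not in ("all", "both", strain):
                continue
            if len(ref) == 1 and len(alt) == 1:
                alt_p[pos] = (1 - error_rate) if zyg == "hom" else het_fraction
                alt_base[pos] = alt.encode()
            else:
                is_indel[pos] = True
                indel_ref[pos] = ref
                indel_alt[pos] = alt
                alt_p[pos] = (1 - error_rate) if zyg == "hom" else het_fraction
        nonref = rng.binomial(depth, alt_p)
        alt_count = np.where(is_indel, 0, nonref)
        indel_count = np.where(is_indel, nonref, 0)
        ref_count = depth - nonref
        hq_alt = rng.binomial(alt_count, hq_fraction)
        hq_ref = rng.binomial(ref_count, hq_fraction)
        hq_indel = rng.binomial(indel_count, hq_fraction)
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.arange(1, n + 1),
                "ref": ref_arr.astype("U1"),
                "alt": alt_base.astype("U1"),
                "ref_count": ref_count,
                "alt_count": alt_count,
                "hq_ref": hq_ref,
                "hq_alt": hq_alt,
                "indel_count": indel_count,
                "hq_indel": hq_indel,
                "indel_ref": indel_ref,
                "indel_alt": indel_alt,
                "multimapped": rng.poisson(depth_mean * multimap_rate, size=n),
                "clonal": rng.poisson(depth_mean * clonal_rate, size=n),
                "depth": depth,
            }
        )
        out[strain] = df
    return out


# ------------------------------------------------------------- coverage


def simulate_coverage(
    genome_length: int,
    truth_cnvs: Sequence[tuple],
    bin_size: int,
    mean_per_bin: float,
    seed: int,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Binned Poisson coverage for a sample and a reference library.

    Sample bins overlapping a truth CNV have their Poisson mean scaled by
    the truth copy ratio (length-weighted for partial overlap); the
    reference track is flat.
    """
    if bin_size <= 0 or bin_size > genome_length:
        raise ValueError("bin_size must yield at least one bin")
    starts = np.arange(0, genome_length, bin_size)
    ends = np.minimum(starts + bin_size, genome_length)
    widths = (ends - starts) / bin_size
    ratio = np.ones(len(starts))
    for chrom_c, s, e, copy_ratio, _strain in truth_cnvs:
        ov = np.minimum(ends, e) - np.maximum(starts, s)
        frac = np.clip(ov, 0, None) / (ends - starts)
        ratio = ratio * (1 - frac) + copy_ratio * frac
    rng = np.random.default_rng(seed)
    sample = rng.poisson(mean_per_bin * ratio * widths)
    reference = rng.poisson(mean_per_bin * widths)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "sample_count": sample,
            "ref_count": reference,
        }
    )


# ------------------------------------------------------------ mate pairs


def simulate_matepairs(
    genome_length: int,
    truth_svs: Sequence[tuple],
    insert_median: float,
    insert_sd: float,
    n_pairs: int,
    seed: int,
    chrom: str = "chr1",
    library_id: str = "lib1",
    min_mapped_distance: int = 500,
) -> pd.DataFrame:
    """Mate-pair table with FR expected orientation and SV-perturbed pairs.

    Concordant inserts are Normal(insert_median, insert_sd). Fragments
    spanning a truth DEL map with the insert inflated by the deleted
    length; truth INS deflates spanning inserts; truth INV flips the strand
    of the end falling inside the inverted segment; truth DUP adds everted
    pairs across the tandem-duplication junction.
    """
    if insert_median <= 0:
        raise ValueError("insert_median must be positive")
    rng = np.random.default_rng(seed)
    d = np.maximum(150, rng.normal(insert_median, insert_sd, size=n_pairs))
    pos1 = rng.integers(0, max(1, genome_length - int(insert_median * 3)), size=n_pairs)
    pos2 = pos1 + d.astype(int)
    strand1 = np.full(n_pairs, "+")
    strand2 = np.full(n_pairs, "-")

    keep = np.ones(n_pairs, dtype=bool)
    for svtype, chrom_s, s, e, _strain in truth_svs:
        if svtype == "DEL":
            # no real sequence inside a homozygous deletion
            keep &= ~((pos1 >= s) & (pos1 < e))
            cross = (pos1 < s) & (pos2 >= s)
            pos2 = np.where(cross, pos2 + (e - s), pos2)
        elif svtype == "INS":
            # a spanning fragment only maps on both sides when it protrudes
            # well beyond the inserted sequence
            ilen = e - s
            cross = (pos1 < s) & (pos2 >= s)
            pos2 = np.where(cross, pos2 - ilen, pos2)
            keep &= ~(cross & (pos2 - pos1 < min_mapped_distance))
        elif svtype == "INV":
            in1 = (pos1 > s) & (pos1 < e)
            in2 = (pos2 > s) & (pos2 < e)
            new1 = np.where(in1, s + e - pos1, pos1)
            new2 = np.where(in2, s + e - pos2, pos2)
            strand1 = np.where(in1, np.where(strand1 == "+", "-", "+"), strand1)
            strand2 = np.where(in2, np.where(strand2 == "+", "-", "+"), strand2)
            pos1, pos2 = new1, new2

    pos1, pos2 = pos1[keep], pos2[keep]
    strand1, strand2 = strand1[keep], strand2[keep]

    extra = []
    for svtype, chrom_s, s, e, _strain in truth_svs:
        if svtype != "DUP":
            continue
        lam = n_pairs * insert_median / genome_length
        n_cross = rng.poisson(lam)
        for _ in range(n_cross):
            dd = max(200.0, rng.normal(insert_median, insert_sd))
            u = rng.uniform(0, dd)
            left_read = e - u          # '+' read in first copy
            right_read = s + (dd - u)  # '-' read mapped back to segment start
            extra.append((int(left_read), "+", int(right_read), "-"))
    if extra:
        ep1 = np.array([x[0] for x in extra])
        es1 = np.array([x[1] for x in extra])
        ep2 = np.array([x[2] for x in extra])
        es2 = np.array([x[3] for x in extra])
        pos1 = np.concatenate([pos1, ep1])
        pos2 = np.concatenate([pos2, ep2])
        strand1 = np.concatenate([strand1, es1])
        strand2 = np.concatenate([strand2, es2])

    # normalize so pos1 <= pos2
    swap = pos1 > pos2
    p1 = np.where(swap, pos2, pos1)
    p2 = np.where(swap, pos1, pos2)
    s1 = np.where(swap, strand2, strand1)
    s2 = np.where(swap, strand1, strand2)
    return pd.DataFrame(
        {
            "chrom1": chrom,
            "pos1": p1.astype(int),
            "strand1": s1,
            "chrom2": chrom,
            "pos2": p2.astype(int),
            "strand2": s2,
            "library_id": library_id,
            "n_hits": 1,
        }
    )


# --------------------------------------------------------------- RNA-seq


def sample_names(strains: Sequence[str], n_replicates: int) -> list[str]:
    return [f"{s}_rep{j + 1}" for s in strains for j in range(n_replicates)]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2.

    dispersion == 0 is the deterministic limit: counts equal the rounded
    means exactly (useful as an oracle for scaling laws).
    """
    if dispersion == 0:
        return np.round(mu).astype(int)
    lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    return rng.poisson(lam)


def simulate_rnaseq(
    gene_models: Sequence[GeneModel],
    de_truth: Sequence[tuple],
    splice_truth: Sequence[tuple],
    ase_truth: Sequence[tuple],
    n_replicates: int = 3,
    libsize: float = 1_000_000,
    dispersion: float = 0.05,
    seed: int = 0,
    strains: Sequence[str] = ("strain1", "strain2"),
    junction_depth: float = 20.0,
    ase_depth: float = 30.0,
):
    """(gene counts, junction counts, allele counts) for 2 strains.

    Gene counts are negative binomial around strain means whose ratio is
    the truth fold change (fold = strain1/strain2); columns are
    ``<strain>_rep<j>``. Junction counts cover annotated adjacent-exon
    junctions plus truth exon-skip junctions. Allele counts give binomial
    ref/alt reads at the truth ASE sites.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per strain for a t-test")
    rng = np.random.default_rng(seed)
    genes = [g.gene_id for g in gene_models]
    n_genes = len(genes)
    base = rng.lognormal(mean=4.0, sigma=1.2, size=n_genes)
    fold = pd.Series(1.0, index=genes, dtype=float)
    for gid, f in de_truth:
        fold.loc[gid] = f
    # fold > 1 is realized as up-regulation in strain1, fold < 1 as
    # up-regulation in strain2; the truth ratio strain1/strain2 is `fold`
    # either way, and sequencing-depth composition stays symmetric
    f_arr = fold.to_numpy()
    mean1 = base * np.maximum(f_arr, 1.0)
    mean2 = base * np.maximum(1.0 / f_arr, 1.0)
    mean1 *= libsize / mean1.sum()
    mean2 *= libsize / mean2.sum()
    cols = {}
    for strain, mu in zip(strains, (mean1, mean2)):
        for j in range(n_replicates):
            cols[f"{strain}_rep{j + 1}"] = _nb_draw(rng, mu, dispersion)
    gene_counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))

    # junction counts over annotated adjacent junctions (+ skip junctions)
    skip_by_gene = {}
    for gid, k, strain in splice_truth:
        skip_by_gene.setdefault(gid, []).append((k, strain))
    rows = []
    samples = sample_names(strains, n_replicates)
    for g in gene_models:
        n_ex = len(g.exons)
        skips = skip_by_gene.get(g.gene_id, [])
        skipped = {(k, strain) for k, strain in skips}
        junctions = [(i, i + 1) for i in range(n_ex - 1)]
        for k, _strain in skips:
            if 0 < k < n_ex - 1:
                junctions.append((k - 1, k + 1))
        for di, ai in sorted(set(junctions)):
            row = {"gene_id": g.gene_id, "donor_idx": di, "acceptor_idx": ai}
            for sample in samples:
                strain = sample.rsplit("_rep", 1)[0]
                is_skip_junction = ai - di == 2 and ((di + 1, strain) in skipped)
                touches_skipped = any(
                    k in (di, ai) for k, s in skips if s == strain
                )
                if is_skip_junction:
                    mu = junction_depth
                elif ai - di > 1 or touches_skipped:
                    mu = 0.0
                else:
                    mu = junction_depth
                row[sample] = int(rng.poisson(mu))
            rows.append(row)
    junction_counts = pd.DataFrame(
        rows, columns=["gene_id", "donor_idx", "acceptor_idx"] + samples
    )

    ase_rows = []
    for chrom, pos, frac in ase_truth:
        cov = rng.poisson(ase_depth)
        alt = rng.binomial(cov, frac)
        ase_rows.append(
            {
                "chrom": chrom,
                "pos": pos + 1,
                "ref_count": int(cov - alt),
                "alt_count": int(alt),
            }
        )
    allele_counts = pd.DataFrame(
        ase_rows, columns=["chrom", "pos", "ref_count", "alt_count"]
    )
    return gene_counts, junction_counts, allele_counts


# ---------------------------------------------------------- whole study


def simulate_study(outdir, seed: int, config: dict | None = None) -> TruthSet:
    """Generate a small complete study (genome + all stage inputs) on disk.

    Used by the ``varxome simulate`` command; file formats are the plain
    text ones consumed by the other subcommands.
    """
    import json
    import os

    from . import io as vio

    cfg = {
        "genome_length": 200_000,
        "n_genes": 4,
        "depth_mean": 30,
        "error_rate": 0.01,
        "bin_size": 250,
        "mean_per_bin": 20,
        "insert_median": 2000,
        "insert_sd": 200,
        "n_pairs": 2000,  # ~20x physical coverage at the default sizes
        "n_replicates": 3,
        "libsize": 300_000.0,
        "dispersion": 0.05,
    }
    cfg.update(config or {})
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    genome, genes, repeats = make_genome(
        cfg["genome_length"], cfg["n_genes"], seed=seed
    )
    L = len(genome)
    truth = TruthSet()
    for i in range(20):
        pos = int(rng.integers(0, L))
        ref = genome[pos]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        strain = ["strain1", "strain2"][i % 2]
        truth.variants.append(("chr1", pos, ref, alt, strain, "hom"))
    truth.cnvs.append(("chr1", 20_000, 30_000, 2.0, "strain2"))
    truth.svs.append(("DEL", "chr1", 120_000, 130_000, "strain2"))
    truth.de_genes.append((genes[0].gene_id, 8.0))
    if len(genes[1].exons) >= 3:
        truth.splice_events.append((genes[1].gene_id, 1, "strain2"))
    truth.ase_sites.append(("chr1", genes[0].exons[0][0] + 5, 0.5))

    vio.write_fasta(f"{outdir}/genome.fa", {"chr1": genome})
    vio.write_gff3(f"{outdir}/genes.gff3", genes)
    vio.write_bed(f"{outdir}/repeats.bed", repeats_to_bed(repeats))
    sites = simulate_site_summaries(
        genome, truth.variants, cfg["depth_mean"], cfg["error_rate"], seed
    )
    for strain, df in sites.items():
        vio.write_tsv(f"{outdir}/sites_{strain}.tsv", df)
    cov = simulate_coverage(
        L, truth.cnvs, cfg["bin_size"], cfg["mean_per_bin"], seed
    )
    vio.write_tsv(f"{outdir}/coverage.tsv", cov)
    pairs = simulate_matepairs(
        L, truth.svs, cfg["insert_median"], cfg["insert_sd"], cfg["n_pairs"], seed
    )
    vio.write_tsv(f"{outdir}/matepairs_case.tsv", pairs)
    ctrl = simulate_matepairs(
        L, [], cfg["insert_median"], cfg["insert_sd"], cfg["n_pairs"], seed + 1
    )
    vio.write_tsv(f"{outdir}/matepairs_control.tsv", ctrl)
    gc, jc, ac = simulate_rnaseq(
        genes,
        truth.de_genes,
        truth.splice_events,
        truth.ase_sites,
        n_replicates=cfg["n_replicates"],
        libsize=cfg["libsize"],
        dispersion=cfg["dispersion"],
        seed=seed,
    )
    vio.write_tsv(f"{outdir}/gene_counts.tsv", gc.reset_index())
    vio.write_tsv(f"{outdir}/junction_counts.tsv", jc)
    vio.write_tsv(f"{outdir}/allele_counts.tsv", ac)
    with open(f"{outdir}/truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=1)
    return truth


def repeats_to_bed(repeats):
    return [(c, s, e, fam) for c, s, e, fam in repeats]
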