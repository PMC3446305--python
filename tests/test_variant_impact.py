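"""Consequence classification against a translate-and-compare oracle,
SV-gene overlap, predictive values, upstream density, ASE and intronic
repeat deletions."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import varxome
from varxome import variant_impact as vi, synthetic_data as sd
from varxome.small_variants import VariantCall, variant_type


def _v(pos, ref, alt, chrom="chr1"):
    return VariantCall(chrom, pos, ref, alt, variant_type(ref, alt), "hom", 95.0, 9)


def _cons(variant, genes, genome):
    out = vi.classify_small_variant(variant, genes, genome)
    return sorted((c.gene_id, c.consequence) for c in out)


class TestClassifier:
    def test_codon_oracle_on_random_cds_snvs(self, small_genome):
        """Every CDS SNV class agrees with re-translating the mutated CDS."""
        genome, genes, _ = small_genome
        comp = str.maketrans("ACGT", "TGCA")
        rng = np.random.default_rng(5)
        for g in genes:
            pos_list = vi._cds_positions(g)
            ref_cds = "".join(genome[p] for p in pos_list)
            if g.strand == "-":
                ref_cds = ref_cds.translate(comp)
            ref_prot = str(Seq(ref_cds).translate())
            for idx in rng.choice(len(pos_list), size=40, replace=False):
                p0 = pos_list[idx]
                ref = genome[p0]
                alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
                got = dict(_cons(_v(p0 + 1, ref, alt), [g], genome))[g.gene_id]
                # oracle: mutate the genome, re-extract, re-translate
                mut = genome[:p0] + alt + genome[p0 + 1 :]
                alt_cds = "".join(mut[p] for p in pos_list)
                if g.strand == "-":
                    alt_cds = alt_cds.translate(comp)
                alt_prot = str(Seq(alt_cds).translate())
                i = idx // 3
                if ref_prot[i] == alt_prot[i]:
                    expected = "synonymous"
                elif alt_prot[i] == "*":
                    expected = "stop_gain"
                elif ref_prot[i] == "*":
                    expected = "stop_loss"
                else:
                    expected = "missense"
                assert got == expected, (g.gene_id, p0, ref, alt)

    def test_stop_gain_example(self):
        # hand-built single-exon gene: ATG CAA TAA, CAA -> TAA by C>T
        genome = "X" * 100 + "AAATGCAATAAGGG" + "X" * 100
        genome = genome.replace("X", "T")
        g = sd.GeneModel("g1", "chr1", 100, 114, "+", ((100, 114),), 102, 111)
        got = dict(_cons(_v(106, "C", "T"), [g], genome))
        assert got["g1"] == "stop_gain"

    @pytest.mark.parametrize(
        "ref_len,alt_len,expected",
        [(2, 1, "frameshift"), (4, 1, "inframe_indel"), (1, 3, "frameshift"),
         (1, 4, "inframe_indel")],
    )
    def test_indel_mod3_rule(self, small_genome, ref_len, alt_len, expected):
        genome, genes, _ = small_genome
        g = genes[0]
        pos_list = vi._cds_positions(g)
        p0 = sorted(pos_list)[4]
        ref = genome[p0 : p0 + ref_len]
        alt = genome[p0] + "A" * (alt_len - 1)
        got = dict(_cons(_v(p0, ref, alt), [g], genome))  # anchored: pos is p0 1-based -> first changed base p0
        assert got[g.gene_id] == expected

    def test_essential_splice_positions(self, small_genome):
        genome, genes, _ = small_genome
        g = genes[0]
        intron = g.introns()[0]
        for off, expected in [
            (0, "essential_splice"), (1, "essential_splice"), (2, "intronic"),
        ]:
            p0 = intron[0] + off
            got = dict(_cons(_v(p0 + 1, genome[p0], "A" if genome[p0] != "A" else "C"),
                             [g], genome))
            assert got[g.gene_id] == expected
        p0 = intron[1] - 1
        got = dict(_cons(_v(p0 + 1, genome[p0], "A" if genome[p0] != "A" else "C"),
                         [g], genome))
        assert got[g.gene_id] == "essential_splice"

    def test_utr_upstream_intergenic(self, small_genome):
        genome, genes, _ = small_genome
        g = next(x for x in genes if x.strand == "+")
        utr5, utr3 = g.utr_intervals()
        p5, p3 = utr5[0][0], utr3[-1][1] - 1
        assert dict(_cons(_v(p5 + 1, genome[p5], "A" if genome[p5] != "A" else "C"),
                          [g], genome))[g.gene_id] == "utr5"
        assert dict(_cons(_v(p3 + 1, genome[p3], "A" if genome[p3] != "A" else "C"),
                          [g], genome))[g.gene_id] == "utr3"
        up = g.start - 100
        assert dict(_cons(_v(up + 1, genome[up], "C"), [g], genome))[g.gene_id] == "upstream5kb"
        far = 5  # < 5 kb exists before the first gene? place outside any annotation
        cons = vi.classify_small_variant(_v(far, genome[far - 1], "C"), [g], genome)
        assert [c.consequence for c in cons] == ["intergenic"]

    def test_severity_is_total_and_unique(self, small_genome):
        genome, genes, _ = small_genome
        rng = np.random.default_rng(3)
        for pos in rng.integers(1, len(genome), size=200):
            ref = genome[pos - 1]
            alt = "A" if ref != "A" else "G"
            cons = vi.classify_small_variant(_v(int(pos), ref, alt), genes, genome)
            per_gene = [(c.gene_id, c.consequence) for c in cons]
            assert len(per_gene) == len(set(g for g, _ in per_gene))
            assert all(c.consequence in vi.SEVERITY_ORDER for c in cons)


class TestSvOverlap:
    def _gene(self):
        return sd.GeneModel("g1", "chr1", 10_000, 14_000, "+",
                            ((10_000, 11_000), (13_000, 14_000)), 10_200, 13_800)

    @pytest.mark.parametrize(
        "sv,relation",
        [
            (("DUP", "chr1", 9000, 15_000), "full_dup"),
            (("DUP", "chr1", 10_500, 15_000), "partial_dup"),
            (("DEL", "chr1", 9000, 15_000), "full_del"),
            (("DEL", "chr1", 11_200, 12_800), "partial_del"),  # intron only
            (("INV", "chr1", 9000, 15_000), "other"),
        ],
    )
    def test_relations(self, sv, relation):
        got = vi.overlap_svs([sv], [self._gene()])
        assert len(got) == 1 and got[0].relation == relation

    def test_no_overlap_no_record(self):
        assert vi.overlap_svs([("DEL", "chr1", 0, 5000)], [self._gene()]) == []

    def test_matches_intervaltree_oracle(self, rng):
        from intervaltree import IntervalTree

        genes = [
            sd.GeneModel(f"g{i}", "chr1", s, s + 2000, "+",
                         ((s, s + 800), (s + 1200, s + 2000)), s + 100, s + 1900)
            for i, s in enumerate(range(0, 100_000, 5000))
        ]
        svs = []
        for _ in range(40):
            s = int(rng.integers(0, 98_000))
            svs.append((rng.choice(["DUP", "DEL"]), "chr1", s, s + int(rng.integers(500, 8000))))
        got = {(o.sv_id, o.gene_id) for o in vi.overlap_svs(svs, genes)}
        tree = IntervalTree()
        for g in genes:
            tree.addi(g.start, g.end, g.gene_id)
        expected = set()
        for t, c, s, e in svs:
            for iv in tree.overlap(s, e):
                expected.add((f"{t}:{c}:{s}-{e}", iv.data))
        assert got == expected


class TestPredictiveValue:
    def test_printed_style_fractions(self):
        assert vi.predictive_fraction(5, 7) == pytest.approx(5 / 7)
        assert vi.predictive_fraction(19, 193) == pytest.approx(19 / 193)
        assert vi.predictive_fraction(3, 0) is None

    def test_table_counts_and_null(self):
        cons = [
            vi.Consequence("v1", "g1", "stop_gain"),
            vi.Consequence("v2", "g2", "stop_gain"),
            vi.Consequence("v3", "g3", "missense"),
            vi.Consequence("v4", None, "intergenic"),
        ]
        ovl = [vi.SvGeneOverlap("sv1", "g4", "full_dup")]
        expressed = {"g1", "g2", "g4"}
        de = {"g1", "g4"}
        table = vi.predictive_value(cons, ovl, expressed, de).set_index("variant_class")
        assert table.loc["stop_gain", "n_expressed"] == 2
        assert table.loc["stop_gain", "n_de"] == 1
        assert table.loc["stop_gain", "fraction"] == pytest.approx(0.5)
        assert table.loc["full_dup", "fraction"] == pytest.approx(1.0)
        assert np.isnan(table.loc["missense", "fraction"])  # g3 not expressed
        assert table.loc["stop_variant", "n_expressed"] == 2

    def test_invariant_to_duplicates_and_order(self):
        cons = [vi.Consequence("v1", "g1", "missense")]
        expressed, de = {"g1"}, {"g1"}
        a = vi.predictive_value(cons, [], expressed, de)
        b = vi.predictive_value(cons * 3, [], expressed, de)
        pd.testing.assert_frame_equal(a, b)


class TestUpstreamDensity:
    def _genes(self, n):
        return [
            sd.GeneModel(f"g{i}", "chr1", 10_000 + i * 20_000, 12_000 + i * 20_000,
                         "+", ((10_000 + i * 20_000, 12_000 + i * 20_000),),
                         10_100 + i * 20_000, 11_900 + i * 20_000)
            for i in range(n)
        ]

    def test_zero_variants_zero_counts(self):
        res = vi.upstream_density([], self._genes(4), {"g0", "g1"})
        assert (res.per_gene[["n_snv", "n_indel"]] == 0).all().all()

    def test_equal_groups_large_p(self, rng):
        genes = self._genes(40)
        variants = []
        for g in genes:
            us, ue = g.upstream_interval(5000)
            for p in rng.integers(us, ue, size=5):
                variants.append(_v(int(p) + 1, "A", "C"))
        res = vi.upstream_density(variants, genes, {g.gene_id for g in genes[:20]})
        assert res.p_snv > 0.5

    def test_enrichment_detected(self):
        """Poisson(8) upstream SNVs in DE genes vs Poisson(6) elsewhere is
        detected at alpha = 0.001 with 500 genes per group."""
        rng = np.random.default_rng(7)
        genes = [
            sd.GeneModel(f"g{i}", "chr1", 10_000 + i * 12_000, 11_000 + i * 12_000,
                         "+", ((10_000 + i * 12_000, 11_000 + i * 12_000),),
                         10_100 + i * 12_000, 10_900 + i * 12_000)
            for i in range(1000)
        ]
        de_set = {g.gene_id for g in genes[:500]}
        variants = []
        for g in genes:
            lam = 8 if g.gene_id in de_set else 6
            us, ue = g.upstream_interval(5000)
            for p in rng.integers(us, ue, size=rng.poisson(lam)):
                variants.append(_v(int(p) + 1, "A", "C"))
        res = vi.upstream_density(variants, genes, de_set)
        assert res.mean_snv_de > res.mean_snv_other
        assert res.p_snv < 0.001

    def test_strand_aware_window(self):
        g = sd.GeneModel("g1", "chr1", 10_000, 12_000, "-", ((10_000, 12_000),),
                         10_100, 11_900)
        inside = _v(12_500, "A", "C")   # downstream of start for '-' = upstream
        outside = _v(9_500, "A", "C")
        res = vi.upstream_density([inside, outside], [g], set())
        assert res.per_gene.loc[0, "n_snv"] == 1


class TestAse:
    @pytest.mark.parametrize(
        "ref_n,alt_n,call",
        [(10, 8, "biallelic"), (20, 0, "monoallelic"), (4, 2, "uninformative"),
         (30, 2, "monoallelic")],  # minor frac 2/32 < 0.1
    )
    def test_thresholds(self, ref_n, alt_n, call):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "ref_count": [ref_n], "alt_count": [alt_n]}
        )
        assert vi.allele_specific_expression(df)["call"].iloc[0] == call

    def test_swap_antisymmetry(self, rng):
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(50),
                "ref_count": rng.integers(0, 30, 50),
                "alt_count": rng.integers(0, 30, 50),
            }
        )
        a = vi.allele_specific_expression(df)["call"]
        swapped = df.rename(columns={"ref_count": "alt_count", "alt_count": "ref_count"})
        b = vi.allele_specific_expression(swapped)["call"]
        assert (a == b).all()

    def test_truth_half_fraction_called_biallelic(self):
        """Binomial(30, 0.5) sites are almost always called biallelic."""
        truth = [("chr1", 100 + i, 0.5) for i in range(400)]
        _, _, ac = sd.simulate_rnaseq(
            [sd.GeneModel("g1", "chr1", 0, 1000, "+", ((0, 1000),), 10, 990)],
            [], [], truth, seed=5, ase_depth=30,
        )
        calls = vi.allele_specific_expression(ac)
        frac = (calls["call"] == "biallelic").mean()
        assert frac >= 0.95


class TestIntronicRepeatDeletions:
    def _gene(self):
        return sd.GeneModel("g1", "chr1", 10_000, 30_000, "+",
                            ((10_000, 11_000), (25_000, 30_000)), 10_100, 29_900)

    def test_flagged_example(self):
        dels = [("chr1", 15_000, 18_000)]
        repeats = [("chr1", 15_200, 17_700, "LINE")]
        res = vi.intronic_repeat_deletions(dels, repeats, [self._gene()])
        row = res.iloc[0]
        assert row["repeat_bp"] == 2500
        assert row["intronic"] and row["flagged"]

    def test_exon_overlap_not_intronic(self):
        dels = [("chr1", 10_500, 18_000)]
        repeats = [("chr1", 10_500, 17_000, "LINE")]
        res = vi.intronic_repeat_deletions(dels, repeats, [self._gene()])
        assert not res.iloc[0]["intronic"] and not res.iloc[0]["flagged"]

    def test_repeat_bp_matches_sweepline_oracle(self, rng):
        repeats = []
        for _ in range(30):
            s = int(rng.integers(0, 50_000))
            repeats.append(("chr1", s, s + int(rng.integers(100, 3000)), "LTR"))
        dels = []
        for _ in range(10):
            s = int(rng.integers(0, 48_000))
            dels.append(("chr1", s, s + int(rng.integers(500, 5000))))
        res = vi.intronic_repeat_deletions(dels, repeats, [self._gene()])
        for (chrom, s, e), row in zip(dels, res.itertuples(index=False)):
            covered = np.zeros(e - s, dtype=bool)
            for _, rs, re_, _ in repeats:
                lo, hi = max(s, rs), min(e, re_)
                if lo < hi:
                    covered[lo - s : hi - s] = True
            assert row.repeat_bp == covered.sum()
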