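"""Differential expression between two inbred strains (3 animals each).

Reads are counted per gene over CDS exons on the annotated strand,
normalized to the per-sample total of coding-mapped reads (mean-total
scaling, so count magnitudes are preserved), and a gene is expressed when
its strain-mean normalized count exceeds 10 in at least one strain.
Differential expression requires a more than two-fold difference of strain
means with P < 0.05 from a two-sided equal-variance t-test (computed on
log2(normalized + 1)). The false discovery rate is estimated by label
swapping: the DE rule is re-applied under every balanced relabeling of the
samples and the mean number of genes passing under the null relabelings is
divided by the observed DE count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

EXPRESSED_THRESHOLD = 10.0
FOLD_THRESHOLD = 2.0
P_THRESHOLD = 0.05


@dataclass
class DeTable:
    table: pd.DataFrame  # gene_id, mean_<strain>..., fold_change, p_value, expressed, de
    strains: tuple[str, str]


@dataclass
class SwapFdr:
    expected_false: float
    observed_de: int
    fdr: float | None
    per_swap_counts: list[int]


# ------------------------------------------------------------- counting


def count_genes(
    placements: pd.DataFrame, gene_models: Sequence, samples: Sequence[str]
) -> pd.DataFrame:
    """Raw count matrix: a read increments a gene iff its position lies in
    a CDS exon of the gene on the annotated strand.

    `placements` columns: (sample, chrom, pos, strand); pos 0-based.
    Reads on unknown chromosomes or outside any CDS are left unassigned.
    """
    trees: dict[str, IntervalTree] = {}
    for g in gene_models:
        t = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.cds_intervals():
            t.addi(s, e, (g.gene_id, g.strand))
    genes = [g.gene_id for g in gene_models]
    mat = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"), columns=list(samples))
    for row in placements.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.at(row.pos):
            gid, strand = iv.data
            if strand == row.strand:
                mat.loc[gid, row.sample] += 1
    return mat


# --------------------------------------------------------- normalization


def normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample by (mean coding total over samples) / (its total)."""
    totals = raw.sum(axis=0)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"samples with zero coding-mapped totals: {bad}")
    return raw * (totals.mean() / totals)


def strain_of_columns(columns: Sequence[str]) -> pd.Series:
    """Default sample sheet: columns named `<strain>_rep<j>`."""
    return pd.Series(
        {c: c.rsplit("_rep", 1)[0] for c in columns}, name="strain"
    )


# ------------------------------------------------------------------ tests


def flag_expressed(
    norm: pd.DataFrame,
    labels: Mapping[str, str],
    threshold: float = EXPRESSED_THRESHOLD,
) -> pd.Series:
    """Expressed iff strain-mean normalized count > threshold in >= 1 strain."""
    strains = pd.Series(labels)
    means = norm.T.groupby(strains).mean().T
    return (means > threshold).any(axis=1)


def _t_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided pooled-variance t-test per row, on log2(x + 1)."""
    import warnings

    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    with warnings.catch_warnings():
        # constant rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(la, lb, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate rows: zero variance in both groups
    var0 = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    eq = np.isclose(la.mean(axis=1), lb.mean(axis=1))
    p[var0 & eq] = 1.0
    p[var0 & ~eq] = 0.0
    return p


def test_de(
    norm: pd.DataFrame,
    labels: Mapping[str, str],
    fold_threshold: float = FOLD_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    expressed_threshold: float = EXPRESSED_THRESHOLD,
) -> DeTable:
    """Per-gene strain means, fold change (ratio of strain means of
    normalized counts), t-test P-value and the expressed/DE flags."""
    strains = sorted(set(labels.values()))
    if len(strains) != 2:
        raise ValueError("exactly two strains required")
    cols1 = [c for c in norm.columns if labels[c] == strains[0]]
    cols2 = [c for c in norm.columns if labels[c] == strains[1]]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("need >= 2 samples per strain")
    a = norm[cols1].to_numpy(dtype=float)
    b = norm[cols2].to_numpy(dtype=float)
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(m2 > 0, m1 / m2, np.inf)
        fold = np.where((m1 == 0) & (m2 == 0), 1.0, fold)
    p = _t_pvalues(a, b)
    expressed = (m1 > expressed_threshold) | (m2 > expressed_threshold)
    big_fold = (fold > fold_threshold) | (fold < 1.0 / fold_threshold)
    de = expressed & big_fold & (p < p_threshold)
    table = pd.DataFrame(
        {
            f"mean_{strains[0]}": m1,
            f"mean_{strains[1]}": m2,
            "fold_change": fold,
            "p_value": p,
            "expressed": expressed,
            "de": de,
        },
        index=norm.index,
    )
    return DeTable(table=table, strains=(strains[0], strains[1]))


# -------------------------------------------------------------- swap FDR


def fdr_from_counts(expected_false: float, observed_de: int) -> float | None:
    """Swap-FDR ratio: mean null-positive count over observed DE count."""
    if observed_de <= 0:
        return None
    return expected_false / observed_de


def swap_fdr(
    norm: pd.DataFrame,
    labels: Mapping[str, str],
    ordered: bool = False,
    **test_kwargs,
) -> SwapFdr:
    """Re-run the DE rule under every balanced relabeling of the samples.

    For 3 vs 3 there are 10 unordered balanced partitions; the true one is
    excluded, leaving 9 null relabelings (the test and the |fold| rule are
    label-symmetric, so unordered partitions are the default; `ordered`
    doubles the enumeration). Returns the mean null-positive count and its
    ratio to the observed DE count.
    """
    cols = list(norm.columns)
    strains = sorted(set(labels.values()))
    observed = int(test_de(norm, labels, **test_kwargs).table["de"].sum())
    group_size = sum(1 for c in cols if labels[c] == strains[0])
    true_group = frozenset(c for c in cols if labels[c] == strains[0])
    counts = []
    seen = set()
    for combo in combinations(cols, group_size):
        g = frozenset(combo)
        comp = frozenset(c for c in cols if c not in g)
        if len(comp) != len(cols) - group_size:
            continue
        key = frozenset((g, comp))
        if not ordered:
            if key in seen:
                continue
            seen.add(key)
        if g == true_group or comp == true_group:
            continue
        swap_labels = {c: (strains[0] if c in g else strains[1]) for c in cols}
        res = test_de(norm, swap_labels, **test_kwargs)
        counts.append(int(res.table["de"].sum()))
    expected_false = float(np.mean(counts)) if counts else 0.0
    return SwapFdr(
        expected_false=expected_false,
        observed_de=observed,
        fdr=fdr_from_counts(expected_false, observed),
        per_swap_counts=counts,
    )
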