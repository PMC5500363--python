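"""Chromosome-dosage analysis of a two-strain expression count matrix.

Normalizes raw counts with median-of-ratios size factors, computes per-gene
log2 fold changes (evolved over parent), summarizes the mean fold change per
chromosome against the complement of all other chromosomes (the signature of
an aneuploid chromosome: a trisomic chromosome in a diploid shifts its genes
by about log2(1.5) ~ 0.585), and bins significant genes by direction and a
two-fold cutoff.

Differential-expression testing itself (dispersion estimation, Wald/NB
tests) is deliberately not part of this module; significance flags computed
by a dedicated DE tool (FDR < 0.05) can be supplied to the binning step, and
every summary is also available descriptively over all genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scipy.stats import gmean

__all__ = [
    "size_factors",
    "normalize",
    "log2_fold_change",
    "chromosome_dosage_summary",
    "bin_fold_changes",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    For each gene with nonzero counts in every sample, a sample's ratio is
    its count over the gene's geometric mean across samples; the sample's
    factor is the median of those ratios. Requires at least one all-nonzero
    gene.
    """
    full = counts.loc[(counts > 0).all(axis=1)]
    if len(full) == 0:
        raise ValueError("no gene with nonzero counts in all samples")
    geo = gmean(full.to_numpy(dtype=float), axis=1)
    factors = full.div(geo, axis=0).median(axis=0)
    factors.name = "size_factor"
    return factors


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts divided by their sample's size factor."""
    return counts.div(size_factors(counts), axis=1)


def log2_fold_change(
    counts: pd.DataFrame,
    parent_samples: list[str],
    evolved_samples: list[str],
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-gene log2 fold change of normalized means, evolved over parent.

    FC = log2((mean normalized evolved + pc) / (mean normalized parent + pc)).
    The pseudocount stabilizes low counts and makes a gene absent from both
    strains score exactly 0.
    """
    for s in [*parent_samples, *evolved_samples]:
        if s not in counts.columns:
            raise ValueError(f"sample {s!r} not in count matrix")
    norm = normalize(counts)
    mean_p = norm[parent_samples].mean(axis=1)
    mean_e = norm[evolved_samples].mean(axis=1)
    fc = np.log2((mean_e + pseudocount) / (mean_p + pseudocount))
    fc.name = "log2_fc"
    return fc


def chromosome_dosage_summary(
    fc: pd.Series, chromosomes: pd.Series, significant: pd.Series | None = None
) -> pd.DataFrame:
    """Mean log2 fold change per chromosome vs the complement of the genome.

    ``chromosomes`` maps each gene in ``fc`` to its chromosome. When a
    significance mask is given, means restricted to significant genes are
    reported alongside the all-gene means (both views, since a dosage shift
    is visible either way).

    Returns one row per chromosome: ``chrom, n_genes, mean_fc,
    complement_mean_fc`` (+ ``mean_fc_significant, n_significant`` when a
    mask is supplied).
    """
    chromosomes = chromosomes.reindex(fc.index)
    if chromosomes.isna().any():
        missing = list(fc.index[chromosomes.isna()][:3])
        raise ValueError(f"genes without chromosome assignment, e.g. {missing}")
    rows = []
    for chrom in chromosomes.unique():
        on = chromosomes == chrom
        row = {
            "chrom": chrom,
            "n_genes": int(on.sum()),
            "mean_fc": float(fc[on].mean()),
            "complement_mean_fc": float(fc[~on].mean()),
        }
        if significant is not None:
            sig = significant.reindex(fc.index).fillna(False).astype(bool)
            row["n_significant"] = int((on & sig).sum())
            row["mean_fc_significant"] = (
                float(fc[on & sig].mean()) if (on & sig).any() else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("chrom")


def bin_fold_changes(
    fc: pd.Series,
    significant: pd.Series | None = None,
    chromosomes: pd.Series | None = None,
    exclude_chromosomes: tuple[str, ...] = (),
) -> pd.Series:
    """Count significant genes by direction and two-fold magnitude.

    Genes on excluded chromosomes (e.g. an aneuploid one whose fold changes
    reflect dosage, not regulation) are dropped first; among the remaining
    significant genes, up = FC > 0 and down = FC < 0, and "two-fold or
    greater" is inclusive: |log2 FC| >= 1.

    Returns counts indexed ``up_ge2, up_lt2, down_ge2, down_lt2``.
    """
    if significant is None:
        significant = pd.Series(True, index=fc.index)
    if len(significant) != len(fc):
        raise ValueError("significance flags do not match fold-change vector length")
    significant = significant.reindex(fc.index).fillna(False).astype(bool)
    keep = significant.copy()
    if exclude_chromosomes:
        if chromosomes is None:
            raise ValueError("exclude_chromosomes requires a gene-to-chromosome map")
        chromosomes = chromosomes.reindex(fc.index)
        keep &= ~chromosomes.isin(exclude_chromosomes)
    sub = fc[keep]
    return pd.Series(
        {
            "up_ge2": int(((sub > 0) & (sub >= 1)).sum()),
            "up_lt2": int(((sub > 0) & (sub < 1)).sum()),
            "down_ge2": int(((sub < 0) & (sub <= -1)).sum()),
            "down_lt2": int(((sub < 0) & (sub > -1)).sum()),
        }
    )
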