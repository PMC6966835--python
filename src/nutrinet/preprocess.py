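"""Count-matrix IO, TMM normalisation, CPM, expression filtering and outlier capping.

The preprocessing contract mirrors common RNA-seq practice for two-group
contrasts: between-sample scaling with trimmed-mean-of-M-values (TMM)
factors, counts-per-million on effective library sizes, an expressed-gene
filter of CPM > 1 in at least half of the samples (long intergenic
non-coding RNAs are exempt because they are systematically low-expressed),
and per-gene capping of influential outlier values to the 10th/90th
percentiles when they fall outside 1.5 interquartile ranges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MatrixFormatError


@dataclass
class NormalizationFactors:
    """Per-sample library sizes and TMM scaling factors (geometric mean 1)."""

    library_size: pd.Series
    tmm_factor: pd.Series

    @property
    def effective_library_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor


def read_count_matrix(counts_path, biotype_path, groups_path) -> ExpressionMatrix:
    """Read and validate a counts TSV plus biotype and group annotation TSVs.

    The counts file carries a ``gene_id`` first column and one column per
    sample; the biotype file maps gene_id -> {mRNA, miRNA, lincRNA}; the
    groups file maps sample_id -> group label.  Any inconsistency (duplicate
    ids, negative counts, unannotated genes or samples) raises
    :class:`MatrixFormatError` naming the offending record.
    """
    counts = pd.read_csv(counts_path, sep="\t")
    if counts.columns[0] != "gene_id":
        raise MatrixFormatError(
            f"counts file must start with a 'gene_id' column, got {counts.columns[0]!r}"
        )
    counts = counts.set_index("gene_id")
    bio = pd.read_csv(biotype_path, sep="\t")
    if bio["gene_id"].duplicated().any():
        dup = bio["gene_id"][bio["gene_id"].duplicated()].iloc[0]
        raise MatrixFormatError(f"duplicate gene id in biotype table: {dup!r}")
    biotype = bio.set_index("gene_id")["biotype"]
    grp = pd.read_csv(groups_path, sep="\t")
    if grp["sample_id"].duplicated().any():
        dup = grp["sample_id"][grp["sample_id"].duplicated()].iloc[0]
        raise MatrixFormatError(f"duplicate sample id in groups table: {dup!r}")
    group = grp.set_index("sample_id")["group"]
    return ExpressionMatrix(counts=counts, biotype=biotype, group=group)


def _trimmed_kept(values: np.ndarray, trim: float) -> np.ndarray:
    """Boolean mask keeping ranks in [floor(trim*n), n - floor(trim*n))."""
    n = len(values)
    lo = int(math.floor(trim * n))
    hi = n - lo
    order = np.argsort(values, kind="stable")
    keep = np.zeros(n, dtype=bool)
    keep[order[lo:hi]] = True
    return keep


def tmm_factors(
    matrix: ExpressionMatrix,
    reference_sample: str | None = None,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    For each sample versus the reference, gene-wise log2 expression ratios
    (M) and average log2 abundances (A) are computed on library-scaled
    counts over genes with positive counts in both samples; genes in the
    outer 30% of M ranks or outer 5% of A ranks are trimmed; the factor is
    2 to the precision-weighted (inverse asymptotic variance of M) mean of
    the surviving M values.  Factors are rescaled so their geometric mean
    is exactly 1.

    The default reference is the sample whose 75th count-proportion
    percentile is closest to the across-sample mean of those percentiles.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        s = matrix.sample_ids[int(np.argmin(lib))]
        raise ValueError(f"sample {s!r} has zero library size")
    if matrix.n_samples < 2:
        raise ValueError("TMM needs at least two samples")

    props = counts / lib
    if reference_sample is None:
        uq = np.quantile(props, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(matrix.sample_ids).index(reference_sample)

    yr = counts[:, ref_idx]
    nr = lib[ref_idx]
    log_factors = np.zeros(matrix.n_samples)
    for s in range(matrix.n_samples):
        if s == ref_idx:
            continue
        ys, ns = counts[:, s], lib[s]
        pos = (ys > 0) & (yr > 0)
        if pos.sum() == 0:
            continue
        ps, pr = ys[pos] / ns, yr[pos] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        keep = _trimmed_kept(m, logratio_trim) & _trimmed_kept(a, abundance_trim)
        if keep.sum() == 0:
            continue
        # inverse of the delta-method variance of M for count data
        var = (ns - ys[pos]) / (ns * ys[pos]) + (nr - yr[pos]) / (nr * yr[pos])
        w = np.where(var[keep] > 0, 1.0 / np.maximum(var[keep], 1e-12), 1e12)
        log_factors[s] = np.sum(w * m[keep]) / np.sum(w)
    log_factors -= log_factors.mean()  # geometric mean 1
    return NormalizationFactors(
        library_size=pd.Series(lib, index=matrix.sample_ids),
        tmm_factor=pd.Series(2.0 ** log_factors, index=matrix.sample_ids),
    )


def cpm(matrix: ExpressionMatrix, factors: NormalizationFactors) -> pd.DataFrame:
    """Counts per million on TMM-effective library sizes."""
    eff = factors.effective_library_size.reindex(matrix.sample_ids)
    if (eff <= 0).any():
        s = eff.index[int(np.argmin(eff.to_numpy()))]
        raise ValueError(f"zero effective library size for sample {s!r}")
    return matrix.counts / eff * 1e6


def filter_expressed(
    cpm_matrix: pd.DataFrame,
    biotype: pd.Series,
    min_cpm: float = 1.0,
    min_fraction: float = 0.5,
) -> pd.Index:
    """Genes retained for differential analysis.

    mRNA and miRNA genes are kept iff CPM > ``min_cpm`` in at least
    ceil(min_fraction * n_samples) samples; lincRNAs are kept
    unconditionally (an expression filter would discard most of them).
    """
    if cpm_matrix.shape[0] == 0 or cpm_matrix.shape[1] == 0:
        raise ValueError("empty expression matrix")
    n_needed = math.ceil(min_fraction * cpm_matrix.shape[1])
    n_pass = (cpm_matrix > min_cpm).sum(axis=1)
    bio = biotype.reindex(cpm_matrix.index)
    keep = (n_pass >= n_needed) | (bio == "lincRNA")
    return cpm_matrix.index[keep]


def cap_outliers(values: np.ndarray) -> np.ndarray:
    """Cap influential per-gene outliers to the 10th/90th percentiles.

    Values outside the Tukey fences Q1 - 1.5*IQR .. Q3 + 1.5*IQR are
    replaced by the 10th/90th percentile of the *within-fence* values
    (linear, type-7 quantiles throughout); taking the percentiles over the
    non-outlying values keeps the operation idempotent, which a
    whole-vector percentile would not be.  Vectors shorter than 4 are
    returned unchanged with a warning, and a zero IQR disables capping
    (any rule would collapse the vector).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("cap_outliers expects a 1-D per-gene vector")
    if x.size < 4:
        warnings.warn("vector shorter than 4: outlier capping skipped")
        return x.copy()
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        return x.copy()
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = (x >= lo_fence) & (x <= hi_fence)
    p10, p90 = np.quantile(x[inside], [0.10, 0.90])
    out = x.copy()
    out[x > hi_fence] = p90
    out[x < lo_fence] = p10
    return out


def cap_outliers_frame(cpm_matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`cap_outliers` gene-wise across all samples of a contrast."""
    capped = np.apply_along_axis(cap_outliers, 1, cpm_matrix.to_numpy(dtype=float))
    return pd.DataFrame(capped, index=cpm_matrix.index, columns=cpm_matrix.columns)
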