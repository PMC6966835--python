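"""Validated containers for count matrices with biotype and group metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_BIOTYPES = ("mRNA", "miRNA", "lincRNA")


class MatrixFormatError(ValueError):
    """Raised when an input count matrix or its metadata is malformed."""


@dataclass
class ExpressionMatrix:
    """Gene x sample integer counts plus per-gene biotype and per-sample group.

    The spine of the pipeline: every downstream stage (normalisation,
    differential testing, network inference) consumes this container.

    Parameters
    ----------
    counts : pd.DataFrame
        Non-negative integer counts, index = gene ids, columns = sample ids.
    biotype : pd.Series
        Per-gene label, one of ``mRNA``, ``miRNA``, ``lincRNA``.
    group : pd.Series
        Per-sample group label (e.g. fasted vs fed contrast arms).
    """

    counts: pd.DataFrame
    biotype: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise MatrixFormatError(f"duplicate gene id: {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise MatrixFormatError(f"duplicate sample id: {dup!r}")
        vals = c.to_numpy()
        if not np.isfinite(vals).all():
            raise MatrixFormatError("counts contain non-finite values")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise MatrixFormatError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        missing = c.index.difference(self.biotype.index)
        if len(missing):
            raise MatrixFormatError(f"gene without biotype annotation: {missing[0]!r}")
        self.biotype = self.biotype.reindex(c.index)
        bad = ~self.biotype.isin(VALID_BIOTYPES)
        if bad.any():
            g = self.biotype.index[bad][0]
            raise MatrixFormatError(
                f"unknown biotype {self.biotype[g]!r} for gene {g!r}"
            )
        missing = c.columns.difference(self.group.index)
        if len(missing):
            raise MatrixFormatError(f"sample without group assignment: {missing[0]!r}")
        self.group = self.group.reindex(c.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_of(self, group_label: str) -> list[str]:
        """Sample ids belonging to one group, in matrix column order."""
        return [s for s in self.counts.columns if self.group[s] == group_label]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts[list(sample_ids)],
            biotype=self.biotype.copy(),
            group=self.group.loc[list(sample_ids)].copy(),
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts.loc[list(gene_ids)],
            biotype=self.biotype.loc[list(gene_ids)].copy(),
            group=self.group.copy(),
        )
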