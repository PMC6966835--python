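#!/usr/bin/env python
"""Normalise, cap and filter the synthetic count matrix.

Reports TMM factor spread, how many genes survive the CPM > 1 in >= 50%
of samples rule per biotype (lincRNAs are exempt), and writes the capped
CPM matrix used by the correlation-based stages.
"""

from pathlib import Path

import pandas as pd

from nutrinet.preprocess import (cap_outliers_frame, cpm, filter_expressed,
                                 read_count_matrix, tmm_factors)

IN = Path("results/synthetic")
OUT = Path("results/tables")


def main() -> None:
    matrix = read_count_matrix(IN / "counts.tsv", IN / "biotypes.tsv",
                               IN / "groups.tsv")
    factors = tmm_factors(matrix)
    print(f"TMM factors: {factors.tmm_factor.min():.3f} .. "
          f"{factors.tmm_factor.max():.3f} (geometric mean 1)")
    capped = cap_outliers_frame(cpm(matrix, factors))
    kept = filter_expressed(capped, matrix.biotype)
    OUT.mkdir(parents=True, exist_ok=True)
    capped.loc[kept].rename_axis("gene_id").to_csv(OUT / "capped_cpm.tsv", sep="\t")
    summary = pd.DataFrame({
        "annotated": matrix.biotype.value_counts(),
        "expressed": matrix.biotype.loc[kept].value_counts(),
    }).fillna(0).astype(int)
    summary.rename_axis("biotype").to_csv(OUT / "preprocess_summary.tsv", sep="\t")
    print(summary)
    print(f"retained {len(kept)}/{matrix.n_genes} genes -> {OUT}/capped_cpm.tsv")


if __name__ == "__main__":
    main()
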