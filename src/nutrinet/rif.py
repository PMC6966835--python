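"""Regulatory impact factor (RIF) scoring of candidate regulator miRNAs.

For a two-condition contrast with n_de differentially expressed genes,
each regulator i is scored from the DE genes' condition means e1_j, e2_j
(log2 CPM) and its within-condition correlations r1_ij, r2_ij with them:

    PIF_j  = (e1_j^2 - e2_j^2) / 2          phenotype impact factor
    DW_ij  = r1_ij - r2_ij                  differential wiring
    RIF1_i = mean_j PIF_j * DW_ij^2
    RIF2_i = mean_j [(e1_j r1_ij)^2 - (e2_j r2_ij)^2]

RIF1 favours regulators whose wiring to abundant, strongly shifted DE
genes changes most; RIF2 favours regulators whose ability to predict DE
gene abundance changes sign or strength between conditions.  Reversing
the contrast negates both scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pcit import pearson_matrix


@dataclass
class ConditionProfile:
    """Per-condition inputs for RIF scoring.

    e1, e2: per-DE-gene mean expression (log2 CPM) in conditions 1 and 2;
    r1, r2: regulator x DE-gene correlation matrices per condition.
    """

    de_gene_ids: list
    regulator_ids: list
    e1: np.ndarray
    e2: np.ndarray
    r1: np.ndarray
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.e1 = np.asarray(self.e1, dtype=float)
        self.e2 = np.asarray(self.e2, dtype=float)
        self.r1 = np.atleast_2d(np.asarray(self.r1, dtype=float))
        self.r2 = np.atleast_2d(np.asarray(self.r2, dtype=float))
        n_reg, n_de = self.r1.shape
        if self.r2.shape != (n_reg, n_de):
            raise ValueError("r1 and r2 shapes differ")
        if len(self.e1) != n_de or len(self.e2) != n_de:
            raise ValueError("expression vectors do not match the DE gene count")
        if not (np.isfinite(self.e1).all() and np.isfinite(self.e2).all()):
            raise ValueError("non-finite expression values")
        for r in (self.r1, self.r2):
            if (np.abs(r) > 1 + 1e-9).any():
                raise ValueError("correlations must lie in [-1, 1]")

    def reversed(self) -> "ConditionProfile":
        """The same profile with conditions 1 and 2 swapped."""
        return ConditionProfile(
            self.de_gene_ids, self.regulator_ids,
            self.e2.copy(), self.e1.copy(), self.r2.copy(), self.r1.copy(),
        )


def pif(e1_j: float, e2_j: float) -> float:
    """Phenotype impact factor of one DE gene: (e1^2 - e2^2) / 2."""
    return 0.5 * (e1_j ** 2 - e2_j ** 2)


def differential_wiring(r1_ij: float, r2_ij: float) -> float:
    """Change in regulator-gene correlation between conditions."""
    return r1_ij - r2_ij


def rif1(profile: ConditionProfile) -> np.ndarray:
    """RIF1 raw score per regulator: mean over DE genes of PIF * DW^2."""
    if len(profile.e1) == 0:
        raise ValueError("RIF needs at least one DE gene")
    pif_j = 0.5 * (profile.e1 ** 2 - profile.e2 ** 2)
    dw = profile.r1 - profile.r2
    return (dw ** 2 * pif_j[None, :]).mean(axis=1)


def rif2(profile: ConditionProfile) -> np.ndarray:
    """RIF2 raw score: mean over DE genes of (e1 r1)^2 - (e2 r2)^2."""
    if len(profile.e1) == 0:
        raise ValueError("RIF needs at least one DE gene")
    t1 = (profile.e1[None, :] * profile.r1) ** 2
    t2 = (profile.e2[None, :] * profile.r2) ** 2
    return (t1 - t2).mean(axis=1)


def standardize_scores(raw) -> np.ndarray:
    """(x - mean) / sample SD; order-preserving z-scores."""
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise ValueError("standardisation needs at least two scores")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant score vector cannot be standardised")
    return (x - x.mean()) / sd


def build_profile(
    capped_cpm: pd.DataFrame,
    samples1: list,
    samples2: list,
    regulator_ids,
    de_gene_ids,
    prior: float = 0.25,
) -> ConditionProfile:
    """Condition profile from capped CPM: within-condition means and correlations.

    Expression enters on the log2(CPM + prior) scale; correlations are
    Pearson, computed separately over each condition's samples.
    """
    regulator_ids = list(regulator_ids)
    de_gene_ids = list(de_gene_ids)
    log1 = np.log2(capped_cpm.loc[de_gene_ids, samples1] + prior)
    log2_ = np.log2(capped_cpm.loc[de_gene_ids, samples2] + prior)
    e1 = log1.mean(axis=1).to_numpy()
    e2 = log2_.mean(axis=1).to_numpy()
    both = regulator_ids + de_gene_ids
    r1_full = pearson_matrix(np.log2(capped_cpm.loc[both, samples1] + prior))
    r2_full = pearson_matrix(np.log2(capped_cpm.loc[both, samples2] + prior))
    r1 = r1_full.loc[regulator_ids, de_gene_ids].to_numpy()
    r2 = r2_full.loc[regulator_ids, de_gene_ids].to_numpy()
    return ConditionProfile(de_gene_ids, regulator_ids, e1, e2, r1, r2)


def rif_table(profile: ConditionProfile) -> pd.DataFrame:
    """RIF1/RIF2 raw and standardised scores with dense ranks."""
    raw1 = rif1(profile)
    raw2 = rif2(profile)
    tab = pd.DataFrame(
        {"rif1_raw": raw1, "rif2_raw": raw2},
        index=pd.Index(profile.regulator_ids, name="mirna_id"),
    )
    if len(tab) > 1 and raw1.std(ddof=1) > 0 and raw2.std(ddof=1) > 0:
        tab["rif1_z"] = standardize_scores(raw1)
        tab["rif2_z"] = standardize_scores(raw2)
    else:
        tab["rif1_z"] = np.nan
        tab["rif2_z"] = np.nan
    tab["rif1_rank"] = tab["rif1_raw"].rank(ascending=False, method="first").astype(int)
    tab["rif2_rank"] = tab["rif2_raw"].rank(ascending=False, method="first").astype(int)
    return tab
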