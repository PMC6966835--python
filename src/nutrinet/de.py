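"""Two-group negative-binomial differential expression.

The model follows the classic count-based DE recipe for small-replicate
RNA-seq: per-gene negative binomial with variance mu + phi*mu^2, a common
dispersion maximising the summed conditional log-likelihood on
library-equalised pseudo-counts, empirical-Bayes (weighted-likelihood)
shrinkage of gene-wise dispersions toward the common value, and an exact
conditional test of the group-1 sum given the total.  This is a
self-contained re-implementation of that machinery, validated by
statistical properties (type-I error, FDR control, effect recovery)
rather than numeric identity with any external tool.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binom, nbinom

_PHI_GRID = np.exp(np.linspace(np.log(1e-6), np.log(20.0), 400))


def equalize_counts(counts: np.ndarray, eff_lib: np.ndarray) -> np.ndarray:
    """Scale counts to the geometric-mean effective library size and round.

    Equal pseudo-library sizes make the conditional exact test (which
    assumes exchangeable per-sample means within a group) valid with
    unequal sequencing depths.
    """
    eff_lib = np.asarray(eff_lib, dtype=float)
    geo = np.exp(np.mean(np.log(eff_lib)))
    return np.rint(np.asarray(counts, dtype=float) * (geo / eff_lib))


def _cond_loglik_grid(y: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Conditional NB log-likelihood (terms in phi only) per gene x phi.

    For one group with counts ``y`` (genes x samples) under an equal-mean
    NB model, the likelihood conditional on the gene's total is, up to
    phi-free terms,

        sum_i lgamma(y_i + r) + lgamma(n r) - lgamma(z + n r) - n lgamma(r)

    with r = 1/phi and z the gene total.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = y.shape[1]
    z = y.sum(axis=1)
    r = 1.0 / phi  # (k,)
    # genes x samples x k is too big for long grids; loop over the grid
    out = np.empty((y.shape[0], len(phi)))
    for j, rj in enumerate(r):
        out[:, j] = (
            gammaln(y + rj).sum(axis=1)
            + gammaln(n * rj)
            - gammaln(z + n * rj)
            - n * gammaln(rj)
        )
    return out


def _groupwise_cond_loglik(counts: np.ndarray, group_idx: list[np.ndarray],
                           phi: np.ndarray) -> np.ndarray:
    ll = np.zeros((counts.shape[0], len(phi)))
    for idx in group_idx:
        ll += _cond_loglik_grid(counts[:, idx], phi)
    return ll


def _refine_max(phi_grid: np.ndarray, ll: np.ndarray) -> float:
    """Parabolic refinement of the grid argmax on the log-phi axis."""
    j = int(np.argmax(ll))
    if j == 0 or j == len(phi_grid) - 1:
        return float(phi_grid[j])
    x = np.log(phi_grid[j - 1:j + 2])
    y = ll[j - 1:j + 2]
    if y[0] - 2 * y[1] + y[2] >= 0:
        return float(phi_grid[j])
    # 3-point parabola vertex on the log-phi axis
    num = (x[1] - x[0]) ** 2 * (y[1] - y[2]) - (x[1] - x[2]) ** 2 * (y[1] - y[0])
    den = (x[1] - x[0]) * (y[1] - y[2]) - (x[1] - x[2]) * (y[1] - y[0])
    xv = x[1] - 0.5 * num / den
    return float(np.exp(np.clip(xv, x[0], x[2])))


def estimate_dispersions(
    matrix_counts: pd.DataFrame,
    groups: pd.Series,
    eff_lib: pd.Series | None = None,
    prior_weight: float = 10.0,
) -> tuple[float, pd.Series]:
    """Common and tagwise NB dispersions for a two-group contrast.

    The common dispersion maximises the conditional log-likelihood summed
    over genes and groups on library-equalised pseudo-counts; tagwise
    dispersions maximise each gene's conditional likelihood plus
    ``prior_weight`` times the across-gene average (empirical-Bayes
    shrinkage toward the common value; weight 0 returns the raw gene-wise
    maxima).
    """
    groups = groups.reindex(matrix_counts.columns)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    gidx = [np.flatnonzero((groups == g).to_numpy()) for g in labels]
    if min(len(i) for i in gidx) < 2:
        raise ValueError("each group needs at least two samples")
    counts = matrix_counts.to_numpy(dtype=float)
    if eff_lib is None:
        eff_lib = pd.Series(counts.sum(axis=0), index=matrix_counts.columns)
    eq = equalize_counts(counts, eff_lib.reindex(matrix_counts.columns).to_numpy())

    ll = _groupwise_cond_loglik(eq, gidx, _PHI_GRID)
    informative = eq.sum(axis=1) > 0
    total = ll[informative].sum(axis=0)
    common = _refine_max(_PHI_GRID, total)

    mean_ll = total / max(int(informative.sum()), 1)
    tag_obj = ll + prior_weight * mean_ll
    tagwise = np.array([
        _refine_max(_PHI_GRID, tag_obj[g]) if informative[g] else common
        for g in range(eq.shape[0])
    ])
    return common, pd.Series(tagwise, index=matrix_counts.index, name="dispersion")


def _nb_logpmf(k: np.ndarray, mean: float, size: float) -> np.ndarray:
    p = size / (size + mean)
    return nbinom.logpmf(k, size, p)


def nb_exact_test(
    gene_counts: np.ndarray,
    groups: np.ndarray,
    dispersion: float,
    eff_lib: np.ndarray | None = None,
    prior_count: float = 0.125,
    label_order: tuple | None = None,
) -> tuple[float, float, float, float]:
    """Exact conditional NB test for one gene between two groups.

    Returns ``(log2fc, pvalue, log2cpm_group1, log2cpm_group2)`` where the
    fold change is group 2 over group 1 (labels in sorted order unless
    ``label_order`` is given).  The two-sided p-value sums the conditional
    probabilities, given the total pseudo-count, of all group-1 sums at
    most as probable as the observed one; in the dispersion -> 0 limit
    this is the exact Poisson-conditional (binomial) test.
    """
    y = np.asarray(gene_counts, dtype=float)
    groups = np.asarray(groups)
    labels = np.sort(pd.unique(pd.Series(groups))) if label_order is None \
        else np.asarray(label_order)
    if len(labels) != 2:
        raise ValueError("exact test requires exactly two groups")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if eff_lib is None:
        eff_lib = np.full(y.shape, max(y.sum(), 1.0))
    eq = equalize_counts(y, np.asarray(eff_lib, dtype=float))
    geo = float(np.exp(np.mean(np.log(np.asarray(eff_lib, dtype=float)))))

    i1 = groups == labels[0]
    i2 = groups == labels[1]
    n1, n2 = int(i1.sum()), int(i2.sum())
    s1, s2 = float(eq[i1].sum()), float(eq[i2].sum())
    t = int(round(s1 + s2))

    m1 = s1 / n1 + prior_count
    m2 = s2 / n2 + prior_count
    log2fc = math.log2(m2 / m1)
    cpm_scale = 1e6 / geo
    log2cpm1 = math.log2((s1 / n1 + prior_count) * cpm_scale)
    log2cpm2 = math.log2((s2 / n2 + prior_count) * cpm_scale)

    if t == 0:
        return 0.0, 1.0, log2cpm1, log2cpm2

    mu = t / (n1 + n2)
    if dispersion < 1e-12:
        # Poisson limit: S1 | total ~ Binomial(t, n1/(n1+n2))
        support, logp = _binned_support(t, n1 * mu, math.sqrt(n1 * mu * n2 / (n1 + n2)))
        logp = binom.logpmf(support, t, n1 / (n1 + n2))
    else:
        sd = math.sqrt(n1 * (mu + dispersion * mu * mu))
        support, _ = _binned_support(t, n1 * mu, sd)
        logp = (
            _nb_logpmf(support, n1 * mu, n1 / dispersion)
            + _nb_logpmf(t - support, n2 * mu, n2 / dispersion)
        )
        logp -= logsumexp(logp)
    s1i = int(round(s1))
    if s1i < support[0] or s1i > support[-1]:
        # observation beyond a 40-sd window around the conditional mean:
        # the two-sided tail mass is far below double precision
        return log2fc, 0.0, log2cpm1, log2cpm2
    obs_logp = float(logp[s1i - int(support[0])])
    keep = logp <= obs_logp + 1e-10
    pvalue = float(min(np.exp(logsumexp(logp[keep])), 1.0))
    return log2fc, pvalue, log2cpm1, log2cpm2


def _binned_support(t: int, mean: float, sd: float) -> tuple[np.ndarray, None]:
    """Integer support for the conditional sum, windowed for large totals."""
    if t <= 20000:
        return np.arange(t + 1), None
    half = max(40.0 * sd, 50.0)
    lo = max(int(mean - half), 0)
    hi = min(int(mean + half), t)
    return np.arange(lo, hi + 1), None


def adjust_pvalues(pvalues, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg or Benjamini-Yekutieli step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be adjusted; drop them first")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    if method == "BY":
        ranked *= np.sum(1.0 / np.arange(1, m + 1))
    elif method != "BH":
        raise ValueError(f"unknown correction method {method!r}")
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def contrast_table(
    counts: pd.DataFrame,
    groups: pd.Series,
    group1: str,
    group2: str,
    eff_lib: pd.Series | None = None,
    prior_weight: float = 10.0,
    use_tagwise: bool = True,
) -> pd.DataFrame:
    """Full DE table (log2FC, p, BH q, per-group log2CPM) for one contrast."""
    samples = [s for s in counts.columns if groups[s] == group1]
    samples += [s for s in counts.columns if groups[s] == group2]
    sub = counts[samples]
    grp = groups.loc[samples]
    if eff_lib is not None:
        eff_lib = eff_lib.loc[samples]
        el = eff_lib.to_numpy(dtype=float)
    else:
        el = sub.sum(axis=0).to_numpy(dtype=float)
    # order groups so that log2fc is group2 vs group1
    garr = np.where(grp.to_numpy() == group1, 0, 1)
    common, tagwise = estimate_dispersions(sub, grp, eff_lib=pd.Series(el, index=samples),
                                           prior_weight=prior_weight)
    disp = tagwise if use_tagwise else pd.Series(common, index=sub.index)
    rows = []
    arr = sub.to_numpy(dtype=float)
    for g in range(arr.shape[0]):
        lfc, p, c1, c2 = nb_exact_test(arr[g], garr, float(disp.iloc[g]), eff_lib=el)
        rows.append((lfc, p, c1, c2))
    tab = pd.DataFrame(
        rows, index=sub.index,
        columns=["log2fc", "pvalue", "log2cpm_group1", "log2cpm_group2"],
    )
    tab["qvalue"] = adjust_pvalues(tab["pvalue"].to_numpy(), "BH")
    tab["dispersion"] = disp.to_numpy()
    return tab


def classify_de(
    table: pd.DataFrame, fc_threshold: float = 1.5, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Flag genes as DE at a linear fold-change and q-value threshold."""
    out = table.copy()
    out["de_flag"] = (out["qvalue"] < q_threshold) & (
        2.0 ** out["log2fc"].abs() > fc_threshold
    )
    return out


def de_proportion(n_de: int, n_expressed: int) -> float:
    """Percentage of expressed genes called DE, truncated to 2 decimals."""
    if n_expressed <= 0:
        raise ValueError("n_expressed must be positive")
    if n_de > n_expressed:
        raise ValueError("n_de cannot exceed n_expressed")
    return math.floor(100.0 * n_de / n_expressed * 100.0) / 100.0


def mean_abs_fold_change(log2fc_list) -> float:
    """Arithmetic mean of linear absolute fold changes, 2^|log2FC|."""
    x = np.asarray(list(log2fc_list), dtype=float)
    if x.size == 0:
        raise ValueError("empty fold-change list")
    return float(np.mean(2.0 ** np.abs(x)))
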