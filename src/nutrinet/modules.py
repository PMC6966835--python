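"""Signed weighted co-expression modules and module-phenotype association.

The workflow mirrors weighted gene co-expression network analysis on a
signed network: soft-thresholded adjacency a_ij = ((1 + r_ij)/2)^beta with
beta = 16, topological overlap similarity, average-linkage clustering of
1 - TOM with a static height cut, a minimum module size of 30, iterative
merging of modules whose eigengenes correlate above 0.75 (dissimilarity
below 0.25), module eigengenes as first principal components, Pearson
module-trait correlation with Student asymptotic p-values, per-gene trait
significance, and scaled Kleinberg hub centrality within modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

UNASSIGNED = "unassigned"


def signed_adjacency(expr: pd.DataFrame, beta: float = 16.0) -> pd.DataFrame:
    """Signed soft-threshold adjacency a_ij = ((1 + r_ij) / 2)^beta.

    Anticorrelated genes get near-zero adjacency rather than high
    adjacency, preserving the sign of co-regulation; beta = 16 is the
    conventional signed-network power for ~20 samples.
    """
    from .pcit import pearson_matrix

    r = pearson_matrix(expr).to_numpy()
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: shared-neighbourhood similarity of a network.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k_i the connectivity excluding the diagonal; TOM_ii = 1.
    """
    a = adjacency.to_numpy(dtype=float).copy()
    if ((a < 0) | (a > 1)).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    # the u == i and u == j terms of the product sum vanish since a_ii = 0
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def module_eigengene(expr: pd.DataFrame, members) -> pd.Series:
    """First principal component of the standardised member-gene profiles.

    Unit variance across samples, sign-oriented so the mean correlation
    with member genes is non-negative; constant genes are dropped with a
    warning.
    """
    sub = expr.loc[list(members)].to_numpy(dtype=float)
    if sub.shape[0] < 2:
        raise ValueError("module eigengene needs at least 2 member genes")
    sd = sub.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} constant gene(s) dropped from eigengene")
        sub = sub[sd > 0]
        sd = sd[sd > 0]
        if sub.shape[0] < 2:
            raise ValueError("too few non-constant genes for an eigengene")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    me = me / me.std(ddof=1)
    member_cor = np.array([np.corrcoef(z[g], me)[0, 1] for g in range(z.shape[0])])
    if member_cor.mean() < 0:
        me = -me
    return pd.Series(me, index=expr.columns, name="eigengene")


def detect_modules(
    dissimilarity: pd.DataFrame,
    expr: pd.DataFrame | None = None,
    min_module_size: int = 30,
    merge_height: float = 0.25,
    cut_height: float | None = None,
) -> pd.Series:
    """Module labels from average-linkage clustering of 1 - TOM.

    The tree is cut statically; when ``cut_height`` is not given it is
    placed in the widest gap of the upper half of the merge heights,
    which separates tight co-expression joins from the background joins
    of unstructured genes.  Clusters smaller than ``min_module_size``
    become ``unassigned``; when expression is given, modules whose
    eigengene dissimilarity 1 - cor falls below ``merge_height`` are
    merged iteratively, closest pair first.  Labels are ``M1``, ``M2``,
    ... in decreasing size order.
    """
    d = dissimilarity.to_numpy(dtype=float)
    genes = dissimilarity.index
    if len(genes) < min_module_size:
        return pd.Series(UNASSIGNED, index=genes, name="module")
    condensed = squareform((d + d.T) / 2.0, checks=False)
    tree = linkage(condensed, method="average")
    if cut_height is None:
        cut_height = _gap_cut_height(tree[:, 2])
    raw = fcluster(tree, t=cut_height, criterion="distance")

    labels = pd.Series(raw, index=genes).astype(object)
    sizes = labels.value_counts()
    labels[labels.isin(sizes[sizes < min_module_size].index)] = UNASSIGNED

    if expr is not None:
        labels = _merge_close_modules(labels, expr, merge_height)

    # stable final names by decreasing module size
    final = pd.Series(UNASSIGNED, index=genes, name="module", dtype=object)
    kept = [m for m in labels.value_counts().index if m != UNASSIGNED]
    for i, m in enumerate(kept, start=1):
        final[labels == m] = f"M{i}"
    return final


def _gap_cut_height(heights: np.ndarray, lower_quantile: float = 0.5) -> float:
    """Midpoint of the widest gap among the upper merge heights."""
    hs = np.sort(np.asarray(heights, dtype=float))
    seg = hs[int(len(hs) * lower_quantile):]
    if len(seg) < 2:
        return float(hs[-1])
    gaps = np.diff(seg)
    i = int(np.argmax(gaps))
    return float((seg[i] + seg[i + 1]) / 2.0)


def _merge_close_modules(labels: pd.Series, expr: pd.DataFrame,
                         merge_height: float) -> pd.Series:
    labels = labels.copy()
    while True:
        mods = [m for m in labels.unique() if m != UNASSIGNED]
        if len(mods) < 2:
            return labels
        mes = {m: module_eigengene(expr, labels.index[labels == m]) for m in mods}
        best, best_diss = None, None
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                diss = 1.0 - float(np.corrcoef(mes[a], mes[b])[0, 1])
                if best_diss is None or diss < best_diss:
                    best, best_diss = (a, b), diss
        if best_diss is None or best_diss >= merge_height:
            return labels
        a, b = best
        labels[labels == b] = a


def trait_association(x, trait) -> tuple[float, float]:
    """Pearson r and Student asymptotic two-sided p-value.

    p is computed from t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of
    freedom; pairs with missing values are dropped (pairwise-complete).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(trait, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("trait association needs at least 4 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in trait association input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) >= 1.0:
        return r, 0.0
    tstat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * float(t_dist.sf(abs(tstat), df=n - 2))
    return r, min(p, 1.0)


def kleinberg_hub_scores(adjacency: pd.DataFrame) -> pd.Series:
    """Scaled Kleinberg hub centrality of a weighted undirected network.

    For a symmetric adjacency the hub and authority vectors coincide with
    the principal eigenvector; scores are scaled so the maximum is 1.
    """
    a = adjacency.to_numpy(dtype=float)
    if a.shape[0] < 2:
        raise ValueError("hub centrality needs at least 2 nodes")
    a = (a + a.T) / 2.0
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    if off.max() == 0:
        return pd.Series(0.0, index=adjacency.index, name="hub")
    vals, vecs = np.linalg.eigh(a)
    v = np.abs(vecs[:, int(np.argmax(vals))])
    v = v / v.max()
    return pd.Series(v, index=adjacency.index, name="hub")


@dataclass
class ModuleSet:
    """Bundle of module detection and trait-association outputs."""

    labels: pd.Series
    eigengenes: pd.DataFrame          # module x sample
    module_trait_r: pd.DataFrame      # module x trait
    module_trait_p: pd.DataFrame
    gene_significance_r: pd.DataFrame  # gene x trait
    gene_significance_p: pd.DataFrame
    kleinberg_hub: pd.Series           # per gene, max 1 within each module
    dropped_mirna_only: list = field(default_factory=list)


def module_trait_analysis(
    log_expr: pd.DataFrame,
    biotype: pd.Series,
    phenotypes: pd.DataFrame,
    beta: float = 16.0,
    min_module_size: int = 30,
    merge_height: float = 0.25,
    cut_height: float | None = None,
) -> ModuleSet:
    """End-to-end module detection plus phenotype association.

    ``log_expr`` is gene x sample log2 expression (capped CPM);
    ``phenotypes`` is sample x trait.  miRNA-only modules are excluded
    from trait association; hub centrality runs on the signed adjacency
    restricted to each module's members.
    """
    adj = signed_adjacency(log_expr, beta=beta)
    tom = tom_similarity(adj)
    labels = detect_modules(
        1.0 - tom, expr=log_expr,
        min_module_size=min_module_size, merge_height=merge_height,
        cut_height=cut_height,
    )
    mods = [m for m in labels.unique() if m != UNASSIGNED]
    mirna_only = [
        m for m in mods
        if (biotype.reindex(labels.index[labels == m]) == "miRNA").all()
    ]
    scored = [m for m in mods if m not in mirna_only]

    mes = pd.DataFrame(
        {m: module_eigengene(log_expr, labels.index[labels == m]) for m in scored}
    ).T
    phen = phenotypes.reindex(log_expr.columns)
    mt_r = pd.DataFrame(index=scored, columns=phen.columns, dtype=float)
    mt_p = pd.DataFrame(index=scored, columns=phen.columns, dtype=float)
    for m in scored:
        for tr in phen.columns:
            r, p = trait_association(mes.loc[m], phen[tr])
            mt_r.at[m, tr], mt_p.at[m, tr] = r, p

    gs_r = pd.DataFrame(index=log_expr.index, columns=phen.columns, dtype=float)
    gs_p = pd.DataFrame(index=log_expr.index, columns=phen.columns, dtype=float)
    for tr in phen.columns:
        y = phen[tr].to_numpy(dtype=float)
        for g in log_expr.index:
            try:
                r, p = trait_association(log_expr.loc[g].to_numpy(), y)
            except ValueError:
                r, p = np.nan, np.nan
            gs_r.at[g, tr], gs_p.at[g, tr] = r, p

    hub = pd.Series(np.nan, index=log_expr.index, name="hub")
    for m in mods:
        members = labels.index[labels == m]
        if len(members) >= 2:
            hub.loc[members] = kleinberg_hub_scores(adj.loc[members, members])
    return ModuleSet(labels, mes, mt_r, mt_p, gs_r, gs_p, hub, mirna_only)
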