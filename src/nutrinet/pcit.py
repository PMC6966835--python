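"""PCIT co-expression edge significance, typed edge extraction and hub scores.

PCIT (partial correlation with information theory) keeps a correlation
edge x-y only if no third gene z "explains it away": for every trio the
three first-order partial correlations are computed, a trio tolerance
epsilon is the mean of the three partial/direct ratios, and the x-y edge
is invalidated by z when |r_xy| <= |eps * r_xz| and |r_xy| <= |eps * r_yz|.
An edge is significant iff no trio invalidates it.

Retained edges are then typed by the study's biological rules: candidate
miRNA->mRNA interactions must be strongly negative (r < -0.5, a repressor
assumption) while mRNA-mRNA co-expression must satisfy |r| > 0.7.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

_CLAMP = 1.0 - 1e-12


def pearson_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between rows (genes) across columns (samples).

    Constant rows get zero off-diagonal correlation with a warning rather
    than NaN, so degenerate genes cannot poison downstream trio logic.
    """
    x = expr.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("correlation needs at least 3 samples")
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene(s): correlations set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(x)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def pcit_mask(corr: pd.DataFrame) -> pd.DataFrame:
    """Boolean matrix of PCIT-significant edges.

    Vectorised over the conditioning gene z: for fixed z all three trio
    partials are 2-D functions of (x, y).  Trios in which any of the three
    direct correlations is exactly zero contribute no invalidation (a zero
    edge cannot explain others away).  Off-diagonal |r| = 1 is clamped to
    1 - 1e-12 before partials.
    """
    r = corr.to_numpy(dtype=float).copy()
    n = r.shape[0]
    if n == 0:
        raise ValueError("empty correlation matrix")
    if not np.allclose(r, r.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    off = ~np.eye(n, dtype=bool)
    clip_needed = np.abs(r[off]) >= 1.0
    if clip_needed.any():
        warnings.warn("off-diagonal |r| = 1 clamped before partial correlations")
    r[off] = np.clip(r[off], -_CLAMP, _CLAMP)
    np.fill_diagonal(r, 1.0)

    invalid = np.zeros((n, n), dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(n):
            rz = r[:, z]                       # r_xz as a vector
            rx = rz[:, None]                   # r_xz broadcast over y
            ry = rz[None, :]                   # r_yz broadcast over x
            sx = np.sqrt(1.0 - rx * rx)
            sy = np.sqrt(1.0 - ry * ry)
            sxy = np.sqrt(1.0 - r * r)
            a = (r - rx * ry) / (sx * sy)      # r_xy.z
            b = (rx - r * ry) / (sxy * sy)     # r_xz.y
            c = (ry - r * rx) / (sxy * sx)     # r_yz.x
            eps = (a / r + b / rx + c / ry) / 3.0
            cond = (np.abs(r) <= np.abs(eps * rx)) & (np.abs(r) <= np.abs(eps * ry))
            # trios with a zero direct correlation never invalidate
            cond &= (r != 0) & (rx != 0) & (ry != 0)
            cond &= np.isfinite(eps)
            cond[z, :] = False
            cond[:, z] = False
            np.fill_diagonal(cond, False)
            invalid |= cond
    mask = ~invalid
    np.fill_diagonal(mask, False)
    return pd.DataFrame(mask, index=corr.index, columns=corr.columns)


def extract_edges(
    corr: pd.DataFrame,
    mask: pd.DataFrame,
    mirna_ids,
    de_mrna_ids,
    mirna_r_max: float = -0.5,
    mrna_abs_r_min: float = 0.7,
    apply_mask_to_mirna: bool = True,
) -> pd.DataFrame:
    """Typed edge list from a correlation matrix and PCIT mask.

    miRNA->mRNA edges require PCIT significance (toggleable) and
    r < ``mirna_r_max``; mRNA-mRNA edges (both differentially expressed)
    require PCIT significance and |r| > ``mrna_abs_r_min``.
    """
    mirna_ids = list(mirna_ids)
    de_mrna_ids = list(de_mrna_ids)
    if set(mirna_ids) & set(de_mrna_ids):
        raise ValueError("miRNA and mRNA node sets must be disjoint")
    unknown = (set(mirna_ids) | set(de_mrna_ids)) - set(corr.index)
    if unknown:
        raise KeyError(f"node id not in correlation matrix: {sorted(unknown)[0]!r}")

    rows = []
    for mi in mirna_ids:
        for mr in de_mrna_ids:
            r = corr.at[mi, mr]
            sig = bool(mask.at[mi, mr]) if apply_mask_to_mirna else True
            if sig and r < mirna_r_max:
                rows.append((mi, mr, float(r), "miRNA->mRNA", True))
    for i, a in enumerate(de_mrna_ids):
        for b in de_mrna_ids[i + 1:]:
            r = corr.at[a, b]
            if bool(mask.at[a, b]) and abs(r) > mrna_abs_r_min:
                rows.append((a, b, float(r), "mRNA-mRNA", bool(mask.at[a, b])))
    edges = pd.DataFrame(
        rows, columns=["source", "target", "r", "edge_type", "pcit_significant"]
    )
    edges["seed_validated"] = pd.NA
    return edges


def hub_scores(edges: pd.DataFrame, node_ids=None) -> pd.DataFrame:
    """Connectivity hub score K_i = x_i / mean degree for the mRNA-mRNA net.

    ``x_i`` is the number of significant mRNA-mRNA connections of gene i
    and the denominator is the average connectivity over the scored genes,
    so K averages to exactly 1.  ``node_ids`` widens the scored set (e.g.
    all DE mRNAs, including those with no retained edge).
    """
    mm = edges[edges["edge_type"] == "mRNA-mRNA"]
    if len(mm) == 0:
        raise ValueError("empty mRNA-mRNA network")
    degree: dict[str, int] = {}
    if node_ids is not None:
        degree = {g: 0 for g in node_ids}
    for _, e in mm.iterrows():
        degree[e["source"]] = degree.get(e["source"], 0) + 1
        degree[e["target"]] = degree.get(e["target"], 0) + 1
    ids = list(degree)
    x = np.array([degree[g] for g in ids], dtype=float)
    k = x / x.mean()
    return pd.DataFrame({"gene_id": ids, "x_i": x.astype(int), "K_i": k}).set_index("gene_id")
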