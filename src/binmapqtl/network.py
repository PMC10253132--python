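"""Weighted coexpression network: soft-threshold adjacency, topological
overlap, module detection and eigengenes.

The adjacency is the unsigned soft-threshold a_ij = |cor_ij|^beta (beta = 8
by default).  Modules come from average-linkage hierarchical clustering of
the topological-overlap dissimilarity with a static tree cut; modules whose
eigengenes correlate above 1 - mergeCutHeight are merged.  Edges with
weight > 0.2 are retained for candidate screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

UNASSIGNED = -1


def soft_adjacency(cor: np.ndarray, beta: float = 8.0) -> np.ndarray:
    """Unsigned soft-threshold adjacency |cor|^beta with zero diagonal."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    cor = np.asarray(cor, dtype=float)
    if np.any(np.abs(cor) > 1 + 1e-8):
        raise ValueError("correlations must lie in [-1, 1]")
    adj = np.abs(np.clip(cor, -1, 1)) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    Requires a symmetric adjacency with zero diagonal; the result is
    symmetric with unit diagonal and entries in [0, 1].
    """
    A = np.asarray(adjacency, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        A = A.copy()
        np.fill_diagonal(A, 0.0)
    shared = A @ A
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _eigengene(expr: np.ndarray) -> np.ndarray:
    """First PC across samples of standardized gene profiles; sign fixed so
    the eigengene correlates positively with the module mean profile."""
    X = np.asarray(expr, dtype=float)
    sd = X.std(axis=1, keepdims=True)
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    if np.corrcoef(eig, Z.mean(axis=0))[0, 1] < 0:
        eig = -eig
    return eig


@dataclass
class CoexpressionNetwork:
    genes: np.ndarray
    correlation: np.ndarray
    adjacency: np.ndarray
    tom: np.ndarray
    modules: np.ndarray                     # per-gene module label; -1 unassigned
    eigengenes: pd.DataFrame | None = None  # modules x samples


def detect_modules(tom: np.ndarray, expr: np.ndarray,
                   min_module_size: int = 100, merge_cut_height: float = 0.25,
                   cut_height: float = 0.95):
    """Static-cut module detection on the TOM dissimilarity.

    Average-linkage clustering of 1 - TOM is cut at ``cut_height``;
    clusters below ``min_module_size`` are left unassigned; modules whose
    eigengene correlation is >= 1 - merge_cut_height are merged (repeatedly,
    closest pair first).  Returns (labels, eigengene matrix) where the
    eigengene matrix is (n_modules, n_samples) in label order.
    """
    n = tom.shape[0]
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size: all unassigned")
        return np.full(n, UNASSIGNED), np.empty((0, expr.shape[1]))
    dis = 1.0 - tom
    np.fill_diagonal(dis, 0.0)
    Z = linkage(squareform(dis, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = np.full(n, UNASSIGNED)
    next_label = 0
    for c in np.unique(raw):
        members = raw == c
        if members.sum() >= min_module_size:
            labels[members] = next_label
            next_label += 1
    # iterative eigengene merging
    while True:
        mods = [m for m in np.unique(labels) if m != UNASSIGNED]
        if len(mods) < 2:
            break
        eigs = {m: _eigengene(expr[labels == m]) for m in mods}
        best, best_cor = None, 1.0 - merge_cut_height
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                c = np.corrcoef(eigs[a], eigs[b])[0, 1]
                if c >= best_cor:
                    best, best_cor = (a, b), c
        if best is None:
            break
        labels[labels == best[1]] = best[0]
    # relabel compactly by size
    mods = [m for m in np.unique(labels) if m != UNASSIGNED]
    mods.sort(key=lambda m: -(labels == m).sum())
    relabel = np.full(n, UNASSIGNED)
    for k, m in enumerate(mods):
        relabel[labels == m] = k
    eig_rows = [_eigengene(expr[relabel == k]) for k in range(len(mods))]
    return relabel, np.asarray(eig_rows)


def build_network(expr: pd.DataFrame, beta: float = 8.0,
                  min_module_size: int = 100, merge_cut_height: float = 0.25,
                  cut_height: float = 0.95, log_transform: bool = True) -> CoexpressionNetwork:
    """Full pipeline: correlations -> adjacency -> TOM -> modules.

    ``expr`` is genes x samples on the abundance (FPKM-like) scale; values
    are log2(x + 1)-transformed before correlation unless ``log_transform``
    is disabled.
    """
    X = expr.to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    cor = np.corrcoef(X)
    cor = np.nan_to_num(cor, nan=0.0)
    adj = soft_adjacency(cor, beta)
    tom = topological_overlap(adj)
    labels, eigs = detect_modules(tom, X, min_module_size, merge_cut_height, cut_height)
    eig_df = pd.DataFrame(eigs, columns=expr.columns,
                          index=[f"ME{k}" for k in range(eigs.shape[0])]) \
        if eigs.size else None
    return CoexpressionNetwork(genes=np.asarray(expr.index), correlation=cor,
                               adjacency=adj, tom=tom, modules=labels,
                               eigengenes=eig_df)


def module_trait_correlation(eigengenes: pd.DataFrame,
                             sample_groups: pd.Series | dict) -> pd.DataFrame:
    """Spearman correlation of each eigengene with each sample indicator.

    ``sample_groups`` maps sample name -> condition label (e.g.
    "ZS11_25daf"); each condition becomes a 0/1 indicator.  Returns a tidy
    frame (module, condition, rho, p); constant eigengenes are flagged with
    NaN correlations.
    """
    groups = pd.Series(sample_groups)
    if eigengenes.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    groups = groups.reindex(eigengenes.columns)
    rows = []
    for me, eig in eigengenes.iterrows():
        constant = np.isclose(eig.std(), 0.0)
        for cond in pd.unique(groups.dropna()):
            ind = (groups == cond).astype(float).to_numpy()
            if constant or ind.std() == 0:
                rho, p = np.nan, np.nan
            else:
                res = spearmanr(eig.to_numpy(), ind)
                rho, p = float(res.statistic), float(res.pvalue)
            rows.append((me, cond, rho, p))
    return pd.DataFrame(rows, columns=["module", "condition", "rho", "p"])


def retain_edges(adjacency: np.ndarray, genes, floor: float = 0.2) -> pd.DataFrame:
    """Undirected edges with weight strictly greater than ``floor``."""
    A = np.asarray(adjacency)
    genes = np.asarray(genes)
    iu = np.triu_indices_from(A, k=1)
    keep = A[iu] > floor
    return pd.DataFrame({
        "gene1": genes[iu[0][keep]],
        "gene2": genes[iu[1][keep]],
        "weight": A[iu][keep],
    }).reset_index(drop=True)
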