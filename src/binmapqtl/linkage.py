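"""Genetic-map construction from F2 bin markers.

Pairwise recombination fractions are estimated by maximum likelihood for a
codominant F2 intercross (EM over the double-heterozygote phase ambiguity),
markers are grouped by linkage (LOD/r thresholds on a marker graph),
ordered by minimum-spanning-tree seriation with a 2-opt polish, and
adjacent distances are converted to centimorgans with the Kosambi mapping
function d = 25 ln((1+2r)/(1-2r)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import minimum_spanning_tree, connected_components, breadth_first_order
from scipy.stats import spearmanr

from .variants import AA, AB, BB, MISSING


# ---------------------------------------------------------------------------
# Kosambi map function


def kosambi_cm(r):
    """Map distance in cM from recombination fraction: 25 ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d):
    """Recombination fraction from cM distance: 0.5 tanh(d/50)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def haldane_inverse(d):
    """Recombination fraction under the no-interference (Haldane) map."""
    d = np.asarray(d, dtype=float)
    r = 0.5 * (1.0 - np.exp(-d / 50.0))
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# recombination-fraction estimation

# cell order: 3*g1 + g2 with genotype codes 0=aa, 1=ab, 2=bb
_REC_GAMETES = np.array([0, 1, 2, 1, np.nan, 1, 2, 1, 0])  # nan = double het (0 or 2)


def _cell_probs(r):
    """F2 two-locus genotype probabilities, cells ordered 3*g1+g2."""
    r = np.asarray(r, dtype=float)
    p = 1.0 - r
    out = np.empty(r.shape + (9,))
    out[..., 0] = out[..., 8] = p * p / 4.0
    out[..., 2] = out[..., 6] = r * r / 4.0
    for k in (1, 3, 5, 7):
        out[..., k] = p * r / 2.0
    out[..., 4] = (p * p + r * r) / 2.0
    return out


@dataclass
class RFEstimate:
    r: float
    lod: float
    n_informative: int


def _em_r(cells: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Batched EM for r given cell counts shaped (..., 9)."""
    cells = np.asarray(cells, dtype=float)
    n_pairs = cells.sum(axis=-1)
    fixed_rec = np.nansum(cells * _REC_GAMETES, axis=-1)
    n_dh = cells[..., 4]
    r = np.full(n_pairs.shape, 0.25)
    with np.errstate(invalid="ignore", divide="ignore"):
        for _ in range(max_iter):
            p = 1.0 - r
            e_dh = 2.0 * r * r / (p * p + r * r)      # E[rec gametes | double het]
            r_new = (fixed_rec + n_dh * e_dh) / (2.0 * n_pairs)
            r_new = np.clip(r_new, 1e-12, 0.5)
            if np.all(np.abs(r_new - r) < tol):
                r = r_new
                break
            r = r_new
    return r


def _loglik(cells: np.ndarray, r) -> np.ndarray:
    probs = _cell_probs(np.asarray(r))
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(cells > 0, cells * np.log(np.maximum(probs, 1e-300)), 0.0)
    return ll.sum(axis=-1)


def pair_counts(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """9-cell count vector for one marker pair (missing excluded)."""
    ok = (ga != MISSING) & (gb != MISSING)
    idx = 3 * ga[ok].astype(int) + gb[ok].astype(int)
    return np.bincount(idx, minlength=9).astype(float)


def estimate_rf(ga: np.ndarray, gb: np.ndarray) -> RFEstimate:
    """ML recombination fraction between two F2 marker columns.

    LOD is the base-10 log likelihood ratio against free recombination
    (r = 0.5), computed on the shared informative individuals.
    """
    cells = pair_counts(np.asarray(ga), np.asarray(gb))
    n = int(cells.sum())
    if n < 2:
        raise ValueError("need at least 2 shared informative individuals")
    r = float(_em_r(cells))
    lod = float((_loglik(cells, r) - _loglik(cells, 0.5)) / np.log(10.0))
    return RFEstimate(r=min(r, 0.5), lod=max(lod, 0.0), n_informative=n)


def rf_matrix(genotypes: np.ndarray):
    """Pairwise r-hat and LOD for all marker pairs (markers x individuals).

    Counts for every pair are accumulated with indicator-matrix products,
    and the EM runs batched, so the cost is a few dense matmuls.
    """
    G = np.asarray(genotypes)
    m = G.shape[0]
    ind = [(G == g).astype(float) for g in (AA, AB, BB)]
    cells = np.empty((m, m, 9))
    for a in range(3):
        for b in range(3):
            cells[:, :, 3 * a + b] = ind[a] @ ind[b].T
    r = _em_r(cells)
    lod = (_loglik(cells, r) - _loglik(cells, 0.5)) / np.log(10.0)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, 0.0)
    return np.minimum(r, 0.5), np.maximum(lod, 0.0), cells.sum(axis=-1).astype(int)


# ---------------------------------------------------------------------------
# grouping and ordering


def group_markers(r: np.ndarray, lod: np.ndarray, lod_threshold: float = 6.0,
                  r_threshold: float = 0.35) -> list[np.ndarray]:
    """Linkage groups = connected components of the marker graph with edges
    where LOD >= lod_threshold and r-hat <= r_threshold."""
    adj = (lod >= lod_threshold) & (r <= r_threshold)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(sparse.csr_matrix(adj), directed=False)
    return [np.flatnonzero(labels == k) for k in range(n_comp)]


def _adjacent_sum(order: np.ndarray, dist: np.ndarray) -> float:
    return float(dist[order[:-1], order[1:]].sum())


def _two_opt(order: np.ndarray, dist: np.ndarray, max_passes: int = 10) -> np.ndarray:
    """2-opt polish on the sum of adjacent distances (segment reversals)."""
    order = order.copy()
    n = len(order)
    for _ in range(max_passes):
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                left = dist[order[i - 1], order[j]] if i > 0 else 0.0
                right = dist[order[i], order[j + 1]] if j < n - 1 else 0.0
                old_l = dist[order[i - 1], order[i]] if i > 0 else 0.0
                old_r = dist[order[j], order[j + 1]] if j < n - 1 else 0.0
                if left + right < old_l + old_r - 1e-12:
                    order[i:j + 1] = order[i:j + 1][::-1]
                    improved = True
        if not improved:
            break
    return order


def order_markers(dist: np.ndarray, physical_start: np.ndarray | None = None) -> np.ndarray:
    """Seriate markers by MST traversal plus 2-opt on adjacent distances.

    ``dist`` is a symmetric distance matrix for one linkage group.  The
    returned order is canonically oriented: ascending physical start when
    anchors are supplied (reversal-invariant otherwise).
    """
    n = dist.shape[0]
    if n <= 2:
        order = np.arange(n)
    else:
        mst = minimum_spanning_tree(sparse.csr_matrix(dist)).tocsr()
        sym = mst + mst.T
        # diameter heuristic: BFS from node 0, then from the farthest node
        far, _ = breadth_first_order(sym, 0, directed=False)
        start = far[-1]
        order, _ = breadth_first_order(sym, start, directed=False)
        order = _two_opt(np.asarray(order), dist)
    if physical_start is not None and n > 1:
        rho = spearmanr(np.arange(n), np.asarray(physical_start)[order]).statistic
        if rho is not None and not np.isnan(rho) and rho < 0:
            order = order[::-1]
    return order


# ---------------------------------------------------------------------------
# map assembly and summaries


@dataclass
class MapGroup:
    name: str
    markers: np.ndarray        # indices into the bin matrix, in map order
    cm: np.ndarray             # cumulative Kosambi positions
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray

    @property
    def length(self) -> float:
        return float(self.cm[-1]) if len(self.cm) else 0.0


@dataclass
class GeneticMap:
    groups: list[MapGroup]

    def group(self, name: str) -> MapGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for k, m in enumerate(g.markers):
                rows.append((g.name, int(m), g.cm[k], g.chrom[k], int(g.start[k]),
                             int(g.end[k])))
        return pd.DataFrame(rows, columns=["group", "marker", "cm", "chrom",
                                           "start", "end"])


def build_map(bins, lod_threshold: float = 6.0, r_threshold: float = 0.35,
              max_r_for_distance: float = 0.49) -> GeneticMap:
    """Estimate, group, order and position bin markers into a GeneticMap."""
    r, lod, _ = rf_matrix(bins.genotypes)
    groups = group_markers(r, lod, lod_threshold, r_threshold)
    out = []
    for gi, members in enumerate(sorted(groups, key=lambda m: str(bins.chrom[m[0]]))):
        dist = kosambi_cm(np.minimum(r[np.ix_(members, members)], max_r_for_distance))
        order = order_markers(dist, physical_start=bins.start[members])
        ordered = members[order]
        adj_r = np.minimum(r[ordered[:-1], ordered[1:]], max_r_for_distance)
        cm = np.concatenate([[0.0], np.cumsum(kosambi_cm(adj_r))])
        name = str(bins.chrom[ordered[0]])
        out.append(MapGroup(name=name, markers=ordered, cm=cm,
                            chrom=bins.chrom[ordered], start=bins.start[ordered],
                            end=bins.end[ordered]))
    return GeneticMap(out)


def interval_summary(lengths, counts, names=None) -> pd.DataFrame:
    """Map-summary arithmetic from per-group (length cM, marker count).

    Per group: mean interval = length / (count - 1) (0 for singleton groups).
    The whole-map row sums lengths and counts and reports two averaging
    conventions: the unweighted mean of per-group mean intervals
    (``mean_interval``) and total length / (markers - groups)
    (``mean_interval_global``).
    """
    lengths = np.asarray(lengths, dtype=float)
    counts = np.asarray(counts, dtype=int)
    names = list(names) if names is not None else [f"LG{i+1}" for i in range(len(lengths))]
    with np.errstate(divide="ignore"):
        mean_iv = np.where(counts > 1, lengths / np.maximum(counts - 1, 1), 0.0)
    df = pd.DataFrame({"group": names, "length_cm": lengths, "n_markers": counts,
                       "mean_interval": mean_iv,
                       "singleton": counts <= 1})
    whole = pd.DataFrame({
        "group": ["Whole"], "length_cm": [lengths.sum()], "n_markers": [counts.sum()],
        "mean_interval": [float(np.mean(mean_iv))],
        "singleton": [False],
    })
    df = pd.concat([df, whole], ignore_index=True)
    denom = counts.sum() - len(lengths)
    df.attrs["mean_interval_global"] = float(lengths.sum() / denom) if denom > 0 else 0.0
    return df


def map_summary(gmap: GeneticMap) -> pd.DataFrame:
    """Per-group length, marker count, mean and max marker interval."""
    names, lengths, counts, max_iv = [], [], [], []
    for g in gmap.groups:
        names.append(g.name)
        lengths.append(g.length)
        counts.append(len(g.markers))
        d = np.diff(g.cm)
        max_iv.append(float(d.max()) if len(d) else 0.0)
    df = interval_summary(lengths, counts, names)
    max_iv.append(float(np.mean(max_iv)) if max_iv else 0.0)
    df["max_interval"] = max_iv
    return df


def collinearity(gmap: GeneticMap, suppression_max_cm: float = 2.0,
                 suppression_min_bp: float = 10e6) -> pd.DataFrame:
    """Genetic-vs-physical order diagnostics per group.

    Reports the Spearman correlation between map rank and physical start,
    the count of locally discordant adjacent pairs, and recombination-
    suppressed spans (physical span above ``suppression_min_bp`` within
    less than ``suppression_max_cm`` of map distance).
    """
    rows = []
    for g in gmap.groups:
        n = len(g.markers)
        if n < 2:
            rows.append((g.name, np.nan, 0, 0))
            continue
        rho = spearmanr(np.arange(n), g.start).statistic
        discordant = int(np.sum(np.diff(g.start.astype(float)) < 0))
        n_suppressed = 0
        j = 0
        flagged_until = -1
        for i in range(n):
            j = max(j, i)
            while j + 1 < n and g.cm[j + 1] - g.cm[i] < suppression_max_cm:
                j += 1
            if abs(float(g.start[j]) - float(g.start[i])) > suppression_min_bp and j > flagged_until:
                n_suppressed += 1
                flagged_until = j
        rows.append((g.name, float(rho), discordant, n_suppressed))
    return pd.DataFrame(rows, columns=["group", "spearman_rho", "n_discordant_adjacent",
                                       "n_suppressed_spans"])
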