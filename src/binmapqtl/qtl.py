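"""Composite interval mapping over an F2 bin map.

The scan walks each linkage group on a fixed-cM grid, computes conditional
QTL-genotype probabilities from the flanking markers (Markov chain with
recombination fractions from the inverse map function), and fits the
Haley-Knott regression of the phenotype on the expected additive and
dominance codes plus background marker cofactors outside an exclusion
window.  LOD = (n/2) log10(RSS_reduced / RSS_full).  Genome-wide
significance comes from a permutation test on the maximum LOD.

All heavy paths are vectorized: positions are solved as batched
normal-equation systems and permutations share the per-position designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage import kosambi_inverse, GeneticMap
from .variants import AA, AB, BB, MISSING

_PRIOR = np.array([0.25, 0.5, 0.25])


@dataclass
class CIMConfig:
    step_cm: float = 0.5
    n_cofactors: int = 5
    window_cm: float = 10.0
    n_permutations: int = 1000
    alpha: float = 0.05

    def __post_init__(self):
        if self.step_cm <= 0 or self.window_cm < 0:
            raise ValueError("step must be > 0 and window >= 0")
        if self.n_permutations < 100:
            raise ValueError("use at least 100 permutations")


@dataclass
class GroupMarkers:
    """Ordered markers of one linkage group, ready for scanning."""

    name: str
    cm: np.ndarray                      # (n_markers,) non-decreasing
    genotypes: np.ndarray               # (n_markers, n_ind) codes 0/1/2/-1
    start_bp: np.ndarray | None = None  # physical anchors (optional)
    end_bp: np.ndarray | None = None

    def __post_init__(self):
        self.cm = np.asarray(self.cm, dtype=float)
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("marker positions must be non-decreasing")


def markers_from_map(gmap: GeneticMap, bins) -> list[GroupMarkers]:
    """Assemble scan input from a GeneticMap and its BinGenotypeMatrix."""
    out = []
    for g in gmap.groups:
        out.append(GroupMarkers(g.name, g.cm, bins.genotypes[g.markers],
                                start_bp=g.start, end_bp=g.end))
    return out


def markers_from_truth(sim_map, diplotypes: np.ndarray) -> list[GroupMarkers]:
    """Scan input directly from simulated true genotypes (no noise stages)."""
    out, offset = [], 0
    for g in sim_map.groups:
        sl = slice(offset, offset + g.n_sites)
        out.append(GroupMarkers(g.name, g.cm, diplotypes[sl],
                                start_bp=g.bp, end_bp=g.bp))
        offset += g.n_sites
    return out


# ---------------------------------------------------------------------------
# conditional genotype probabilities


def _transition(r):
    """F2 genotype transition matrix between two loci at recombination r."""
    r = np.asarray(r, dtype=float)
    p = 1.0 - r
    T = np.empty(r.shape + (3, 3))
    T[..., 0, 0] = p * p;       T[..., 0, 1] = 2 * p * r;          T[..., 0, 2] = r * r
    T[..., 1, 0] = p * r;       T[..., 1, 1] = p * p + r * r;      T[..., 1, 2] = p * r
    T[..., 2, 0] = r * r;       T[..., 2, 1] = 2 * p * r;          T[..., 2, 2] = p * p
    return T


def genotype_probs(left_geno, right_geno, d_left_cm, d_right_cm,
                   map_function=kosambi_inverse):
    """(p_aa, p_ab, p_bb) at a position between two flanking markers.

    ``left_geno``/``right_geno`` are genotype codes (arrays allowed;
    missing = -1); distances are in cM.  With both flanks missing the
    1:2:1 prior is returned; at zero distance to a typed marker the
    probabilities collapse onto its genotype.
    """
    if d_left_cm < 0 or d_right_cm < 0:
        raise ValueError("position must lie between the flanking markers")
    C = _position_tensor(map_function(d_left_cm), map_function(d_right_cm))
    lg = np.atleast_1d(np.asarray(left_geno, dtype=int)).copy()
    rg = np.atleast_1d(np.asarray(right_geno, dtype=int)).copy()
    lg[lg == MISSING] = 3
    rg[rg == MISSING] = 3
    probs = C[lg, rg]
    return probs[0] if np.isscalar(left_geno) or np.asarray(left_geno).ndim == 0 else probs


def _position_tensor(r_left: float, r_right: float) -> np.ndarray:
    """C[mL, mR, q] = P(Q=q | left marker mL, right marker mR); index 3 = missing."""
    TL = np.vstack([_transition(np.array(r_left)), _PRIOR[None, :]])      # (4, 3)
    TR = np.hstack([_transition(np.array(r_right)), np.ones((3, 1))])     # (3, 4)
    C = TL[:, None, :] * TR.T[None, :, :]
    denom = C.sum(axis=-1, keepdims=True)
    # flank combinations impossible at the given distances (e.g. aa|bb at
    # zero recombination) get the prior; they never occur in valid data
    return np.where(denom > 0, C / np.where(denom > 0, denom, 1.0), _PRIOR)


@dataclass
class _GroupGrid:
    name: str
    pos: np.ndarray       # scan positions (cM)
    li: np.ndarray        # left flanking marker index per position
    ri: np.ndarray        # right flanking marker index
    C: np.ndarray         # (P, 4, 4, 3) conditional tensors


def _prepare_grid(group: GroupMarkers, step: float,
                  map_function=kosambi_inverse) -> _GroupGrid:
    cm = group.cm
    pos = np.arange(0.0, cm[-1] + step / 2, step)
    pos = np.minimum(pos, cm[-1])
    ri = np.searchsorted(cm, pos, side="left")
    ri = np.clip(ri, 0, len(cm) - 1)
    li = np.where(cm[ri] > pos, np.maximum(ri - 1, 0), ri)
    rl = map_function(np.maximum(pos - cm[li], 0.0))
    rr = map_function(np.maximum(cm[ri] - pos, 0.0))
    P = len(pos)
    C = np.empty((P, 4, 4, 3))
    for p in range(P):
        C[p] = _position_tensor(rl[p], rr[p])
    return _GroupGrid(group.name, pos, li, ri, C)


def _grid_probs(grid: _GroupGrid, genotypes: np.ndarray) -> np.ndarray:
    """Conditional probabilities (P, n, 3) for one group's marker matrix."""
    G = genotypes.astype(int).copy()
    G[G == MISSING] = 3
    GL = G[grid.li]   # (P, n)
    GR = G[grid.ri]
    P = len(grid.pos)
    return grid.C[np.arange(P)[:, None], GL, GR]


# ---------------------------------------------------------------------------
# regression machinery


def _batched_ols(X: np.ndarray, Y: np.ndarray):
    """RSS of per-position OLS fits.

    X is (P, n, m); Y is (n,) or (n, B).  Returns (rss, beta) with rss
    shaped (P,) or (P, B) and beta (P, m) or (P, m, B).
    """
    y2d = Y[:, None] if Y.ndim == 1 else Y
    XtX = np.einsum("pnm,pnk->pmk", X, X, optimize=True)
    XtY = np.einsum("pnm,nb->pmb", X, y2d, optimize=True)
    m = X.shape[2]
    XtX = XtX + 1e-10 * np.eye(m)
    beta = np.linalg.solve(XtX, XtY)
    yty = (y2d ** 2).sum(axis=0)
    rss = yty[None, :] - np.einsum("pmb,pmb->pb", beta, XtY, optimize=True)
    rss = np.maximum(rss, 1e-300)
    if Y.ndim == 1:
        return rss[:, 0], beta[:, :, 0]
    return rss, beta


def _additive_codes(genotypes: np.ndarray) -> np.ndarray:
    """Mean-imputed additive codes (-1/0/+1) for cofactor regression."""
    G = genotypes.astype(float)
    x = G - 1.0
    x[G == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=1, keepdims=True)
    return np.where(np.isnan(x), np.broadcast_to(col_mean, x.shape), x)


def select_cofactors(markers: list[GroupMarkers], y: np.ndarray, k: int):
    """Greedy forward selection of k background markers by RSS reduction.

    Returns (global marker indices, additive code matrix (k, n)).  The
    global index enumerates markers group by group in scan order.
    Deterministic given its inputs.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    Z = np.vstack([_additive_codes(g.genotypes) for g in markers])
    if k > Z.shape[0]:
        raise ValueError("k exceeds the number of markers")
    if k == 0:
        return np.empty(0, dtype=int), np.empty((0, Z.shape[1]))
    codes = Z.copy()
    n = Z.shape[1]
    yr = y - y.mean()
    Zr = Z - Z.mean(axis=1, keepdims=True)
    chosen = []
    for _ in range(k):
        ss = (Zr ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(ss > 1e-12, (Zr @ yr) ** 2 / ss, -np.inf)
        score[chosen] = -np.inf
        j = int(np.argmax(score))
        if not np.isfinite(score[j]):
            break
        chosen.append(j)
        z = Zr[j] / np.sqrt(ss[j])
        yr = yr - (yr @ z) * z
        Zr = Zr - np.outer(Zr @ z, z)
    idx = np.asarray(chosen, dtype=int)
    return idx, codes[idx]


def _marker_positions(markers: list[GroupMarkers]):
    """Global marker index -> (group index, cM)."""
    gidx, cms = [], []
    for gi, g in enumerate(markers):
        gidx.extend([gi] * len(g.cm))
        cms.extend(g.cm.tolist())
    return np.asarray(gidx), np.asarray(cms)


@dataclass
class ScanResult:
    table: pd.DataFrame        # group, cm, lod, add, dom, r2_single, r2_partial
    n: int
    trait: str = "trait"
    cofactors: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def peak_row(self) -> pd.Series:
        return self.table.loc[self.table["lod"].idxmax()]


def cim_scan(markers: list[GroupMarkers], phenotype, config: CIMConfig | None = None,
             trait: str = "trait", cofactor_idx=None, cofactor_codes=None,
             grids: list[_GroupGrid] | None = None,
             map_function=kosambi_inverse) -> ScanResult:
    """Composite interval mapping scan of one numeric phenotype.

    With ``n_cofactors = 0`` this is plain Haley-Knott interval mapping.
    Cofactors may be passed explicitly (as returned by
    :func:`select_cofactors`); otherwise they are selected here.
    """
    config = config or CIMConfig()
    y = np.asarray(phenotype, dtype=float)
    if y.ndim != 1 or not np.all(np.isfinite(y)):
        raise ValueError("phenotype must be a finite numeric vector")
    n = len(y)
    if cofactor_idx is None:
        cofactor_idx, cofactor_codes = select_cofactors(markers, y, config.n_cofactors)
    cof_group, cof_cm = (None, None)
    if len(cofactor_idx):
        all_gidx, all_cm = _marker_positions(markers)
        cof_group, cof_cm = all_gidx[cofactor_idx], all_cm[cofactor_idx]
    if grids is None:
        grids = [_prepare_grid(g, config.step_cm, map_function) for g in markers]

    yc = y - y.mean()
    rss_null = float(yc @ yc)
    frames = []
    for gi, (g, grid) in enumerate(zip(markers, grids)):
        probs = _grid_probs(grid, g.genotypes)           # (P, n, 3)
        xa = probs[:, :, 2] - probs[:, :, 0]
        xd = probs[:, :, 1]
        P = len(grid.pos)
        ones = np.ones((P, n, 1))
        Xq = np.stack([xa, xd], axis=2)                  # (P, n, 2)

        # single-QTL model (for R^2 reporting) — no cofactors
        X1 = np.concatenate([ones, Xq], axis=2)
        rss1, beta1 = _batched_ols(X1, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_single = np.nan_to_num(1.0 - rss1 / rss_null, nan=0.0, neginf=0.0)

        if len(cofactor_idx) == 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                lod = np.nan_to_num((n / 2.0) * np.log10(rss_null / rss1),
                                    nan=0.0, posinf=0.0)
            r2_partial = r2_single
            add, dom = beta1[:, 1], beta1[:, 2]
        else:
            lod = np.empty(P)
            r2_partial = np.empty(P)
            add = np.empty(P)
            dom = np.empty(P)
            # positions sharing the same excluded-cofactor set form blocks
            excl = (cof_group == gi)[None, :] & \
                   (np.abs(grid.pos[:, None] - cof_cm[None, :]) < config.window_cm)
            keys = np.packbits(excl, axis=1) if excl.shape[1] else np.zeros((P, 1), np.uint8)
            _, inv = np.unique(keys, axis=0, return_inverse=True)
            for b in np.unique(inv):
                sel = inv == b
                keep = ~excl[np.flatnonzero(sel)[0]]
                Xc = np.concatenate([np.ones((n, 1)), cofactor_codes[keep].T], axis=1)
                nb = int(sel.sum())
                Xc_b = np.broadcast_to(Xc, (nb, n, Xc.shape[1]))
                rss_red, _ = _batched_ols(Xc_b[:1], y)
                rss_red = float(rss_red[0])
                Xf = np.concatenate([Xc_b, Xq[sel]], axis=2)
                rss_full, beta = _batched_ols(Xf, y)
                lod[sel] = (n / 2.0) * np.log10(rss_red / rss_full)
                r2_partial[sel] = 1.0 - rss_full / rss_red
                add[sel] = beta[:, -2]
                dom[sel] = beta[:, -1]
        frames.append(pd.DataFrame({
            "group": g.name, "cm": grid.pos, "lod": np.maximum(lod, 0.0),
            "add": add, "dom": dom,
            "r2_single": np.clip(r2_single, 0.0, 1.0),
            "r2_partial": np.clip(r2_partial, 0.0, 1.0),
        }))
    table = pd.concat(frames, ignore_index=True)
    return ScanResult(table=table, n=n, trait=trait, cofactors=cofactor_idx)


def permutation_threshold(markers: list[GroupMarkers], phenotype,
                          config: CIMConfig | None = None, seed=0,
                          grids=None, map_function=kosambi_inverse):
    """Genome-wide LOD threshold from a permutation test.

    The phenotype is shuffled across individuals; the maximum LOD of each
    permuted scan is recorded and the (1 - alpha) quantile returned.  With
    cofactors the full procedure (cofactor selection included) is re-run
    per permutation; without cofactors all permutations are solved in one
    batched pass.  Returns (threshold, max_lod_distribution).
    """
    config = config or CIMConfig()
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    B = config.n_permutations
    if grids is None:
        grids = [_prepare_grid(g, config.step_cm, map_function) for g in markers]
    if config.n_cofactors == 0:
        perm = np.argsort(rng.random((B, n)), axis=1)
        Y = y[perm].T                                     # (n, B)
        Yc = Y - Y.mean(axis=0)
        rss_null = (Yc ** 2).sum(axis=0)                  # (B,)
        max_lod = np.zeros(B)
        for g, grid in zip(markers, grids):
            probs = _grid_probs(grid, g.genotypes)
            xa = probs[:, :, 2] - probs[:, :, 0]
            xd = probs[:, :, 1]
            P = len(grid.pos)
            X = np.concatenate([np.ones((P, n, 1)),
                                np.stack([xa, xd], axis=2)], axis=2)
            rss, _ = _batched_ols(X, Y)                   # (P, B)
            with np.errstate(divide="ignore", invalid="ignore"):
                lod = np.nan_to_num((n / 2.0) * np.log10(rss_null[None, :] / rss),
                                    nan=0.0, posinf=0.0)
            max_lod = np.maximum(max_lod, lod.max(axis=0))
    else:
        max_lod = np.empty(B)
        for b in range(B):
            yp = rng.permutation(y)
            res = cim_scan(markers, yp, config, grids=grids, map_function=map_function)
            max_lod[b] = res.max_lod()
    threshold = float(np.quantile(max_lod, 1.0 - config.alpha))
    return threshold, max_lod


# ---------------------------------------------------------------------------
# peaks


@dataclass
class QTLPeak:
    trait: str
    group: str
    pos_cm: float
    lod: float
    r2_percent: float          # single-QTL convention, in %
    r2_partial_percent: float
    add: float
    dom: float
    ci_lo_cm: float
    ci_hi_cm: float
    phys_lo_bp: int | None = None
    phys_hi_bp: int | None = None


def call_peaks(result: ScanResult, threshold: float,
               markers: list[GroupMarkers] | None = None,
               min_separation_cm: float = 10.0) -> list[QTLPeak]:
    """Peaks above threshold with 1-LOD support intervals.

    Peaks are greedy maxima above the threshold, at least
    ``min_separation_cm`` apart within a group and separated from already
    accepted peaks by a valley dropping at least 1 LOD below the smaller
    peak (linked shoulders of one QTL are absorbed).  The support interval
    spans the outermost grid positions around the peak with LOD >= peak -
    1; the physical interval is the bp range of the markers whose anchors
    fall inside (or flank) the cM interval.
    """
    peaks: list[QTLPeak] = []
    anchors = {g.name: g for g in markers} if markers else {}
    for name, sub in result.table.groupby("group", sort=False):
        sub = sub.reset_index(drop=True)
        lod = sub["lod"].to_numpy()
        pos = sub["cm"].to_numpy()
        taken = np.zeros(len(sub), dtype=bool)
        accepted_idx: list[int] = []
        while True:
            cand = np.where(taken, -np.inf, lod)
            i = int(np.argmax(cand))
            if cand[i] < threshold:
                break
            # require a 1-LOD valley between this candidate and every
            # accepted peak of the group
            separated = True
            for j in accepted_idx:
                a, b = sorted((i, j))
                if lod[a:b + 1].min() > lod[i] - 1.0:
                    separated = False
                    break
            if not separated:
                taken[i] = True
                continue
            accepted_idx.append(i)
            lo = i
            while lo > 0 and lod[lo - 1] >= lod[i] - 1.0:
                lo -= 1
            hi = i
            while hi < len(lod) - 1 and lod[hi + 1] >= lod[i] - 1.0:
                hi += 1
            phys_lo = phys_hi = None
            if name in anchors and anchors[name].start_bp is not None:
                g = anchors[name]
                inside = (g.cm >= pos[lo]) & (g.cm <= pos[hi])
                if not inside.any():
                    nearest = int(np.argmin(np.abs(g.cm - pos[i])))
                    inside[nearest] = True
                phys_lo = int(np.min(g.start_bp[inside]))
                phys_hi = int(np.max(g.end_bp[inside]))
            peaks.append(QTLPeak(
                trait=result.trait, group=name, pos_cm=float(pos[i]),
                lod=float(lod[i]),
                r2_percent=float(sub["r2_single"][i] * 100.0),
                r2_partial_percent=float(sub["r2_partial"][i] * 100.0),
                add=float(sub["add"][i]), dom=float(sub["dom"][i]),
                ci_lo_cm=float(pos[lo]), ci_hi_cm=float(pos[hi]),
                phys_lo_bp=phys_lo, phys_hi_bp=phys_hi,
            ))
            taken |= np.abs(pos - pos[i]) < min_separation_cm
    peaks.sort(key=lambda p: -p.lod)
    return peaks


def peaks_to_frame(peaks: list[QTLPeak]) -> pd.DataFrame:
    cols = ["trait", "group", "pos_cm", "lod", "r2_percent", "r2_partial_percent",
            "add", "dom", "ci_lo_cm", "ci_hi_cm", "phys_lo_bp", "phys_hi_bp"]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in peaks], columns=cols)
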