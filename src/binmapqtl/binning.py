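"""Sliding-window genotyping and recombination-bin construction.

Low-coverage F2 calls systematically under-call heterozygotes (a het site
looks homozygous whenever only one allele is sampled).  Window genotyping
fixes this: each window of 15 consecutive sites is called homozygous for a
parent when 11 or more of its informative sites carry that parent's allele,
heterozygous otherwise.  Chromosome segments between the population-wide
recombination breakpoints are merged into bin markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import AA, AB, BB, MISSING

DEFAULT_WINDOW = 15
DEFAULT_HOMO = 11
UNKNOWN = 3   # window with too little information


@dataclass
class BinGenotypeMatrix:
    """Recombination-bin markers x individuals, coded aa/ab/bb/missing."""

    chrom: np.ndarray          # (n_bins,)
    start: np.ndarray          # (n_bins,) bp, 1-based inclusive
    end: np.ndarray            # (n_bins,) bp, 1-based inclusive
    genotypes: np.ndarray      # (n_bins, n_ind) int8; UNKNOWN mapped to MISSING
    samples: list[str]

    def __post_init__(self):
        if np.any(self.start > self.end):
            raise ValueError("bin start must be <= end")

    @property
    def n_bins(self) -> int:
        return len(self.start)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})
        geno = pd.DataFrame(self.genotypes, columns=self.samples)
        return pd.concat([df, geno.replace(MISSING, pd.NA)], axis=1)


def window_counts(calls: np.ndarray, window: int = DEFAULT_WINDOW, step: int = 1):
    """Sliding counts of aa/ab/bb/missing calls per window.

    ``calls`` is (n_ind, n_sites).  Windows start at multiples of ``step``
    and span up to ``window`` sites; terminal windows may be shorter.
    Returns (counts, starts, lengths) with counts shaped
    (4, n_ind, n_windows) in the order aa, ab, bb, missing.
    """
    calls = np.atleast_2d(calls)
    n_ind, n_sites = calls.shape
    if n_sites == 0:
        raise ValueError("empty window track")
    # windows stay full-width whenever the chromosome allows it; a shorter
    # pro-rated tail window appears only when the step skips past the last
    # full-window start (e.g. non-overlapping step-15 mode)
    starts = np.arange(0, max(n_sites - window, 0) + 1, step)
    if starts[-1] + window < n_sites:
        starts = np.append(starts, starts[-1] + step)
    ends = np.minimum(starts + window, n_sites)
    out = np.empty((4, n_ind, len(starts)), dtype=np.int32)
    for k, code in enumerate((AA, AB, BB, MISSING)):
        cum = np.zeros((n_ind, n_sites + 1), dtype=np.int32)
        np.cumsum(calls == code, axis=1, out=cum[:, 1:])
        out[k] = cum[:, ends] - cum[:, starts]
    return out, starts, ends - starts


def call_window(counts_aa, counts_ab, counts_bb, counts_missing,
                window: int = DEFAULT_WINDOW, homo_threshold: int = DEFAULT_HOMO,
                max_missing_frac: float = 2.0 / 3.0):
    """Window genotype from site-call counts (vectorized over any shape).

    A window is homozygous for a parent when that parent's allele count
    reaches the pro-rated threshold ceil(homo_threshold/window x informative
    sites); otherwise heterozygous.  Windows with more than
    ``max_missing_frac`` of their sites missing are unknown.
    """
    ca = np.asarray(counts_aa, dtype=np.int64)
    cb = np.asarray(counts_bb, dtype=np.int64)
    ch = np.asarray(counts_ab, dtype=np.int64)
    cm = np.asarray(counts_missing, dtype=np.int64)
    size = ca + cb + ch + cm
    if np.any(size == 0):
        raise ValueError("empty window")
    informative = size - cm
    thr = np.ceil(homo_threshold / window * informative).astype(np.int64)
    thr = np.maximum(thr, 1)
    geno = np.full(ca.shape, AB, dtype=np.int8)
    geno[ca >= thr] = AA
    geno[cb >= thr] = BB
    geno[(cm > max_missing_frac * size) | (informative == 0)] = UNKNOWN
    return geno


def slide_windows(calls: np.ndarray, positions_bp: np.ndarray,
                  window: int = DEFAULT_WINDOW, homo_threshold: int = DEFAULT_HOMO,
                  step: int = 1, smooth: bool = True):
    """Window-genotype track(s) for one chromosome.

    ``calls`` is (n_ind, n_sites) (a single individual's vector is also
    accepted); sites must be sorted by ``positions_bp``.  Returns
    (window_geno, starts, site_geno): the per-window genotypes, window start
    indices, and a per-site genotype track obtained by assigning each
    window's call to its centre site (used for breakpoint detection and
    bin merging).
    """
    calls = np.atleast_2d(calls)
    positions_bp = np.asarray(positions_bp)
    if np.any(np.diff(positions_bp) < 0):
        raise ValueError("sites must be sorted by position")
    counts, starts, lengths = window_counts(calls, window, step)
    geno = call_window(counts[0], counts[1], counts[2], counts[3],
                       window=window, homo_threshold=homo_threshold)
    if smooth:
        geno = _absorb_singletons(geno)
    centers = starts + lengths // 2
    site_geno = _windows_to_sites(geno, centers, calls.shape[1])
    return geno, starts, site_geno


def _absorb_singletons(geno: np.ndarray) -> np.ndarray:
    """Remove isolated single-window states flanked by one identical state."""
    g = geno.copy()
    if g.shape[1] < 3:
        return g
    mid = (g[:, 2:] == g[:, :-2]) & (g[:, 1:-1] != g[:, :-2])
    g[:, 1:-1] = np.where(mid, g[:, :-2], g[:, 1:-1])
    return g


def _windows_to_sites(window_geno: np.ndarray, centers: np.ndarray,
                      n_sites: int) -> np.ndarray:
    """Per-site genotype = call of the window whose centre is nearest."""
    site_idx = np.arange(n_sites)
    nearest = np.searchsorted(centers, site_idx)
    nearest = np.clip(nearest, 0, len(centers) - 1)
    left = np.clip(nearest - 1, 0, len(centers) - 1)
    use_left = (np.abs(centers[left] - site_idx) <= np.abs(centers[nearest] - site_idx))
    pick = np.where(use_left, left, nearest)
    return window_geno[:, pick]


def detect_breakpoints(site_geno: np.ndarray, positions_bp: np.ndarray,
                       pad_sites: int = DEFAULT_WINDOW - DEFAULT_HOMO) -> list[list[tuple]]:
    """Breakpoints per individual from a per-site genotype track.

    Returns, per individual, a list of (left_bp, right_bp, from_geno,
    to_geno) for each transition between distinct known states; unknown
    stretches are bridged (a transition across unknowns spans them).

    The reported interval is widened by ``pad_sites`` on each side: the
    homozygosity threshold is asymmetric (a window needs 11/15 sites to be
    called homozygous but only 5 heterozygous-consistent sites to be called
    het), so the raw transition site is offset by up to window - threshold
    sites from the true crossover.
    """
    site_geno = np.atleast_2d(site_geno)
    n_sites = site_geno.shape[1]
    out = []
    for row in site_geno:
        known = np.flatnonzero(row != UNKNOWN)
        bps = []
        for a, b in zip(known[:-1], known[1:]):
            if row[a] != row[b]:
                lo = max(int(a) - pad_sites, 0)
                hi = min(int(b) + pad_sites, n_sites - 1)
                bps.append((int(positions_bp[lo]), int(positions_bp[hi]),
                            int(row[a]), int(row[b])))
        out.append(bps)
    return out


def merge_bins(site_geno: np.ndarray, positions_bp: np.ndarray, chrom: str,
               samples: list[str]) -> BinGenotypeMatrix:
    """Partition a chromosome at the union of all individuals' breakpoints.

    Within a bin every individual's (window-derived) genotype is constant;
    adjacent bins differ for at least one individual.  Unknown window calls
    become missing bin genotypes.
    """
    site_geno = np.atleast_2d(site_geno)
    n_ind, n_sites = site_geno.shape
    changes = np.any(site_geno[:, 1:] != site_geno[:, :-1], axis=0)
    cut_after = np.flatnonzero(changes)
    starts_idx = np.concatenate([[0], cut_after + 1])
    ends_idx = np.concatenate([cut_after, [n_sites - 1]])
    geno = site_geno[:, starts_idx].T.astype(np.int8).copy()
    geno[geno == UNKNOWN] = MISSING
    return BinGenotypeMatrix(
        chrom=np.full(len(starts_idx), chrom),
        start=positions_bp[starts_idx].astype(np.int64),
        end=positions_bp[ends_idx].astype(np.int64),
        genotypes=geno,
        samples=list(samples),
    )


def build_bin_matrix(vm, window: int = DEFAULT_WINDOW,
                     homo_threshold: int = DEFAULT_HOMO, step: int = 1,
                     smooth: bool = True) -> BinGenotypeMatrix:
    """Window-genotype every chromosome of a filtered VariantMatrix and
    merge population-wide consistent segments into bin markers."""
    chroms, starts, ends, genos = [], [], [], []
    for c in dict.fromkeys(vm.chrom.tolist()):
        mask = vm.chrom == c
        pos = vm.pos[mask]
        order = np.argsort(pos, kind="stable")
        calls = vm.calls[mask][order].T     # (n_ind, n_sites)
        _, _, site_geno = slide_windows(calls, pos[order], window=window,
                                        homo_threshold=homo_threshold,
                                        step=step, smooth=smooth)
        bm = merge_bins(site_geno, pos[order], c, vm.samples)
        chroms.append(bm.chrom); starts.append(bm.start)
        ends.append(bm.end); genos.append(bm.genotypes)
    return BinGenotypeMatrix(np.concatenate(chroms), np.concatenate(starts),
                             np.concatenate(ends), np.vstack(genos),
                             list(vm.samples))
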