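"""Marker-retention filters for the F2 mapping population.

Sites are kept when (in this order) they are aa x bb polymorphisms between
the parents with adequate parental depth, enough F2 individuals are called
at adequate depth, the minor allele frequency among F2 calls exceeds the
floor, and the genotype counts are consistent with 1:2:1 segregation by a
chi-square test.  Defaults: parent depth >= 2, F2 depth >= 3, MAF > 0.30,
call rate >= 0.5, chi-square p >= 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .variants import VariantMatrix, AA, AB, BB, MISSING


@dataclass
class FilterCriteria:
    min_parent_depth: int = 2
    min_f2_depth: int = 3
    maf_floor: float = 0.30
    max_missing: float = 0.5
    segregation_p_floor: float = 0.001
    expected_ratio: tuple[float, float, float] = (1.0, 2.0, 1.0)
    per_allele_depth: bool = False   # strict reading: each observed allele covered

    def __post_init__(self):
        if not (0 <= self.maf_floor <= 0.5 and 0 <= self.max_missing <= 1
                and 0 <= self.segregation_p_floor <= 1):
            raise ValueError("filter thresholds out of range")


@dataclass
class FilterReport:
    n_input: int
    dropped: dict = field(default_factory=dict)   # rule -> count
    site_table: pd.DataFrame | None = None

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.dropped.values())


def _depth_ok(allele_depths: np.ndarray, floor: int, per_allele: bool) -> np.ndarray:
    """allele_depths (..., 2) -> bool: meets the depth rule."""
    if per_allele:
        observed = allele_depths > 0
        ok = np.all((allele_depths >= floor) | ~observed, axis=-1)
        return ok & observed.any(axis=-1)
    return allele_depths.sum(axis=-1) >= floor


def select_parental_polymorphisms(vm: VariantMatrix,
                                  criteria: FilterCriteria | None = None) -> np.ndarray:
    """Mask of sites with opposite homozygous parental calls at depth."""
    criteria = criteria or FilterCriteria()
    if vm.parent_calls.shape[1] != 2:
        raise ValueError("both parent columns are required")
    p1, p2 = vm.parent_calls[:, 0], vm.parent_calls[:, 1]
    opposite = ((p1 == AA) & (p2 == BB)) | ((p1 == BB) & (p2 == AA))
    d1 = _depth_ok(vm.parent_depths[:, 0], criteria.min_parent_depth, criteria.per_allele_depth)
    d2 = _depth_ok(vm.parent_depths[:, 1], criteria.min_parent_depth, criteria.per_allele_depth)
    return opposite & d1 & d2


def apply_depth_and_missing(vm: VariantMatrix,
                            criteria: FilterCriteria | None = None):
    """Mask low-depth F2 calls as missing; return (masked calls, site mask).

    A site survives when at least ``1 - max_missing`` of the F2 individuals
    remain called after depth masking.
    """
    criteria = criteria or FilterCriteria()
    ok = _depth_ok(vm.allele_depths, criteria.min_f2_depth, criteria.per_allele_depth)
    calls = np.where(ok, vm.calls, MISSING).astype(np.int8)
    call_rate = (calls != MISSING).mean(axis=1)
    return calls, call_rate >= (1.0 - criteria.max_missing)


def minor_allele_frequency(calls: np.ndarray) -> np.ndarray:
    """MAF per site from F2 genotype calls.

    p = (2 n_aa + n_ab) / (2 n_called); MAF = min(p, 1 - p).  Raises on a
    site with no calls.
    """
    arr = np.asarray(calls)
    one_site = arr.ndim == 1
    calls2d = np.atleast_2d(arr)
    n_aa = (calls2d == AA).sum(axis=1)
    n_ab = (calls2d == AB).sum(axis=1)
    n_called = (calls2d != MISSING).sum(axis=1)
    if np.any(n_called == 0):
        raise ValueError("MAF undefined: site with all calls missing")
    p = (2 * n_aa + n_ab) / (2 * n_called)
    maf = np.minimum(p, 1.0 - p)
    return float(maf[0]) if one_site else maf


def segregation_chi2(counts, ratio=(1.0, 2.0, 1.0)):
    """Chi-square test of (n_aa, n_ab, n_bb) against an expected ratio.

    Returns (chi2, p) with p from the asymptotic df-2 upper tail.  Accepts a
    single count triple or an (n_sites, 3) array.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    total = counts.sum(axis=1)
    if np.any(total == 0):
        raise ValueError("segregation test undefined for zero total count")
    ratio = np.asarray(ratio, dtype=float)
    expected = total[:, None] * ratio / ratio.sum()
    chi2 = ((counts - expected) ** 2 / expected).sum(axis=1)
    p = stats.chi2.sf(chi2, df=2)
    if chi2.shape[0] == 1:
        return float(chi2[0]), float(p[0])
    return chi2, p


def genotype_counts(calls: np.ndarray) -> np.ndarray:
    calls = np.atleast_2d(calls)
    return np.stack([(calls == g).sum(axis=1) for g in (AA, AB, BB)], axis=1)


def run_filter(vm: VariantMatrix, criteria: FilterCriteria | None = None):
    """Apply all rules in order; returns (filtered VariantMatrix, FilterReport).

    Order: parental polymorphism -> F2 depth/missing -> MAF -> segregation.
    Each site is charged to the first rule that drops it, so the drop counts
    plus the retained count equal the input site count.
    """
    criteria = criteria or FilterCriteria()
    n = vm.n_sites
    poly = select_parental_polymorphisms(vm, criteria)
    masked_calls, depth_ok = apply_depth_and_missing(vm, criteria)

    alive = poly.copy()
    dropped = {"polymorphism": int((~poly).sum())}
    drop_depth = alive & ~depth_ok
    dropped["depth_missing"] = int(drop_depth.sum())
    alive &= depth_ok

    maf = np.full(n, np.nan)
    called_any = (masked_calls != MISSING).any(axis=1)
    maf[called_any] = minor_allele_frequency(masked_calls[called_any])
    maf_ok = called_any & (maf > criteria.maf_floor)
    dropped["maf"] = int((alive & ~maf_ok).sum())
    alive &= maf_ok

    counts = genotype_counts(masked_calls)
    chi2 = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    nz = counts.sum(axis=1) > 0
    chi2[nz], pval[nz] = segregation_chi2(counts[nz], criteria.expected_ratio)
    seg_ok = nz & (pval >= criteria.segregation_p_floor)
    dropped["segregation"] = int((alive & ~seg_ok).sum())
    alive &= seg_ok

    out = vm.subset(alive)
    out.calls = masked_calls[alive]
    table = pd.DataFrame({
        "chrom": vm.chrom, "pos": vm.pos,
        "n_aa": counts[:, 0], "n_ab": counts[:, 1], "n_bb": counts[:, 2],
        "maf": maf, "chi2": chi2, "p": pval, "retained": alive,
    })
    report = FilterReport(n_input=n, dropped=dropped, site_table=table)
    assert report.n_retained == int(alive.sum())
    return out, report
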