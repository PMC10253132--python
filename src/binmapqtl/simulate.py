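"""Synthetic F2 populations with known ground truth.

Everything downstream of read alignment is exercised against simulated data:
an F2 intercross between two inbred lines (aa x bb at every informative
site), low-coverage genotype calls derived from sampled allele depths,
seed-color phenotypes driven by planted QTLs, and a structured expression
matrix for the coexpression stages.  Every stochastic operation takes an
explicit seed (or a ``numpy.random.Generator``) and the truth needed to
verify downstream inference is returned alongside the data.

The default map geometry follows the published 19-group Brassica napus
linkage map used as the study template: group lengths and marker counts
totalling 1618.329 cM over 4148 sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import json
import numpy as np
import pandas as pd

from .linkage import kosambi_inverse

# genotype codes used throughout the package
AA, AB, BB, MISSING = 0, 1, 2, -1
GENO_LABELS = {AA: "aa", AB: "ab", BB: "bb", MISSING: "missing"}

# Published template geometry: (group, length cM, marker count, physical Mb).
# Physical lengths are plausible chromosome sizes for the ZS11 assembly;
# only their order and rough scale matter for the synthetic genome.
DEFAULT_GROUPS: list[tuple[str, float, int, float]] = [
    ("A01", 84.693, 226, 33.0),
    ("A02", 71.058, 195, 32.0),
    ("A03", 89.030, 295, 37.0),
    ("A04", 65.910, 168, 25.0),
    ("A05", 100.404, 228, 34.0),
    ("A06", 90.317, 258, 31.0),
    ("A07", 72.777, 180, 29.0),
    ("A08", 90.235, 149, 24.0),
    ("A09", 93.434, 276, 63.0),
    ("A10", 60.582, 194, 26.0),
    ("C01", 80.946, 236, 45.0),
    ("C02", 82.514, 175, 52.0),
    ("C03", 111.315, 303, 75.0),
    ("C04", 99.501, 224, 63.0),
    ("C05", 98.286, 241, 65.0),
    ("C06", 90.109, 183, 52.0),
    ("C07", 77.757, 207, 57.0),
    ("C08", 77.850, 199, 48.0),
    ("C09", 81.611, 211, 56.0),
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimGroup:
    name: str
    length_cm: float
    cm: np.ndarray       # site positions in cM, strictly increasing
    bp: np.ndarray       # site positions in bp, strictly increasing (collinear)
    physical_bp: int

    def __post_init__(self):
        self.cm = np.asarray(self.cm, dtype=float)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        if self.length_cm < 0:
            raise ValueError("group length must be >= 0")
        if len(self.cm) != len(self.bp):
            raise ValueError("cM and bp position vectors differ in length")
        if len(self.cm) and (np.any(np.diff(self.cm) < 0) or np.any(np.diff(self.bp) <= 0)):
            raise ValueError("site positions must be increasing and collinear")

    @property
    def n_sites(self) -> int:
        return len(self.cm)


@dataclass
class SimMap:
    """Synthetic genome geometry: linkage groups with collinear cM/bp sites."""

    groups: list[SimGroup]

    def __post_init__(self):
        if not self.groups:
            raise ValueError("SimMap needs at least one group")

    @property
    def n_sites(self) -> int:
        return sum(g.n_sites for g in self.groups)

    @property
    def total_cm(self) -> float:
        return sum(g.length_cm for g in self.groups)

    def group(self, name: str) -> SimGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


def default_map(n_sites: int | None = None, groups: Sequence[tuple] | None = None) -> SimMap:
    """Build the default 19-group template map.

    Sites are evenly spaced in cM within each group with collinear physical
    positions.  ``n_sites`` rescales the per-group counts proportionally
    (useful to thin the map for quick experiments) while keeping lengths.
    """
    template = list(groups) if groups is not None else list(DEFAULT_GROUPS)
    total = sum(t[2] for t in template)
    out = []
    for name, length, count, mb in template:
        k = count if n_sites is None else max(2, int(round(count * n_sites / total)))
        cm = np.linspace(0.0, length, k)
        phys = int(mb * 1e6)
        bp = np.linspace(1, phys, k).round().astype(np.int64)
        bp = np.maximum.accumulate(bp)
        # enforce strict increase in bp
        bp = bp + np.arange(k)
        out.append(SimGroup(name, length, cm, bp, phys + k))
    return SimMap(out)


@dataclass
class TruthQTL:
    """A planted QTL: additive effect toward the bb (yellow) allele."""

    group: str
    pos_cm: float
    h2: float                 # marginal variance share in (0, 1)
    dominance_ratio: float = 0.0   # d/a in [-1, 1]

    def __post_init__(self):
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if abs(self.dominance_ratio) > 1:
            raise ValueError("d/a must lie in [-1, 1]")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic population."""

    n_individuals: int = 196
    mean_depth: float = 4.8
    error_rate: float = 0.005
    missing_rate: float = 0.02
    residual_sd: float = 1.0
    visual_threshold: float = 67.0   # R value splitting black-ish from yellow-ish seeds
    r_location: float = 85.0         # centre of the R distribution
    r_scale: float = 30.0            # sd of the latent colour value on the R scale
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("need at least two individuals")
        if self.mean_depth <= 0:
            raise ValueError("depth must be positive")
        for r in (self.error_rate, self.missing_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must be in [0, 1)")


@dataclass
class TruthTracks:
    """Ground truth retained for verifying downstream inference."""

    crossovers: list[list[dict]]          # per individual: [{group, gamete, pos_cm}, ...]
    diplotypes: np.ndarray                # (n_sites, n_ind) codes 0/1/2
    genetic_values: np.ndarray | None = None


# ---------------------------------------------------------------------------
# meiosis


def _crossover_positions(length_cm: float, rng: np.random.Generator,
                         interference_shape: float | None) -> np.ndarray:
    """Crossover positions (cM) on one gamete for one chromosome.

    Default is the Haldane process: Poisson count with mean length/100
    Morgans, uniform positions, no interference.  With
    ``interference_shape`` set (e.g. 2.63) a stationary gamma-renewal
    process with unit mean rate per Morgan is used instead, which mimics
    positive crossover interference.
    """
    L = length_cm / 100.0  # Morgans
    if L <= 0:
        return np.empty(0)
    if interference_shape is None:
        k = rng.poisson(L)
        return np.sort(rng.uniform(0.0, length_cm, size=k))
    nu = interference_shape
    # stationary renewal: first waiting time from the equilibrium distribution
    pos = []
    t = _equilibrium_gamma(nu, rng)
    while t < L:
        pos.append(t * 100.0)
        t += rng.gamma(nu, 1.0 / nu)
    return np.asarray(pos)


def _equilibrium_gamma(nu: float, rng: np.random.Generator) -> float:
    # equilibrium forward-recurrence time of a gamma(nu, 1/nu) renewal
    # process: uniform fraction of a length-biased interval, and the
    # length-biased gamma(nu) is gamma(nu + 1) with the same scale
    return rng.uniform() * rng.gamma(nu + 1.0, 1.0 / nu)


def simulate_meiosis(sim_map: SimMap, n_gametes: int, seed=0,
                     interference_shape: float | None = None):
    """Simulate gamete haplotypes from an F1 (one chromosome set per group).

    Returns ``(haplotypes, crossovers)`` where ``haplotypes`` is a
    (n_sites, n_gametes) 0/1 array (0 = parent-1 allele) and ``crossovers``
    lists, per gamete, per group, the crossover positions in cM.
    """
    rng = _rng(seed)
    hap_blocks = []
    xovers = [dict() for _ in range(n_gametes)]
    for g in sim_map.groups:
        block = np.empty((g.n_sites, n_gametes), dtype=np.int8)
        for j in range(n_gametes):
            pos = _crossover_positions(g.length_cm, rng, interference_shape)
            start = rng.integers(0, 2)
            # allele switches at each crossover
            n_before = np.searchsorted(pos, g.cm, side="right")
            block[:, j] = (start + n_before) % 2
            xovers[j][g.name] = pos
        hap_blocks.append(block)
    return np.vstack(hap_blocks) if hap_blocks else np.empty((0, n_gametes), dtype=np.int8), xovers


def simulate_f2(sim_map: SimMap, n: int, seed=0,
                interference_shape: float | None = None) -> TruthTracks:
    """Simulate an F2 population: each individual is two independent gametes.

    Diplotype codes: 0 = aa (parent-1 homozygote), 1 = ab, 2 = bb.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    h1, x1 = simulate_meiosis(sim_map, n, rng, interference_shape)
    h2, x2 = simulate_meiosis(sim_map, n, rng, interference_shape)
    diplo = (h1 + h2).astype(np.int8)
    crossovers = []
    for i in range(n):
        rec = []
        for gamete, xo in ((0, x1[i]), (1, x2[i])):
            for gname, pos in xo.items():
                rec.extend({"group": gname, "gamete": gamete, "pos_cm": float(p)} for p in pos)
        crossovers.append(rec)
    return TruthTracks(crossovers=crossovers, diplotypes=diplo)


# ---------------------------------------------------------------------------
# variant calls


def simulate_variant_calls(diplotypes: np.ndarray, mean_depth: float = 4.8,
                           error_rate: float = 0.005, missing_rate: float = 0.02,
                           seed=0):
    """Low-coverage genotype calls from sampled allele depths.

    Per site and individual the total depth is Poisson(``mean_depth``); each
    read carries the a or b allele according to the true diplotype, flipped
    with probability ``error_rate``.  The call is aa/bb when only one allele
    is observed, ab when both are, missing at zero depth or (independently)
    with probability ``missing_rate``.

    Returns ``(calls, allele_depths)`` with calls coded 0/1/2/-1 and
    allele_depths shaped (n_sites, n_ind, 2) = (a reads, b reads).
    """
    if mean_depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(seed)
    n_sites, n_ind = diplotypes.shape
    depth = rng.poisson(mean_depth, size=(n_sites, n_ind))
    p_b = np.choose(diplotypes, [error_rate, 0.5, 1.0 - error_rate])
    b_reads = rng.binomial(depth, p_b)
    a_reads = depth - b_reads
    calls = np.full((n_sites, n_ind), MISSING, dtype=np.int8)
    calls[(a_reads > 0) & (b_reads == 0)] = AA
    calls[(a_reads > 0) & (b_reads > 0)] = AB
    calls[(a_reads == 0) & (b_reads > 0)] = BB
    if missing_rate > 0:
        drop = rng.uniform(size=calls.shape) < missing_rate
        calls[drop] = MISSING
        a_reads = np.where(drop, 0, a_reads)
        b_reads = np.where(drop, 0, b_reads)
    return calls, np.stack([a_reads, b_reads], axis=-1)


# ---------------------------------------------------------------------------
# phenotypes


_TRAITS = ["R", "G", "B", "l", "a", "b"]

# affine maps latent -> trait: trait = intercept + slope * latent + noise_sd * eps
# slopes for a and b are negative (darker seeds score higher on a/b chroma axes);
# noise sds keep |pairwise correlations| >= 0.9.
_TRAIT_TRANSFORMS = {
    "G": (60.0, 0.85, 0.25),
    "B": (45.0, 0.70, 0.25),
    "l": (35.0, 0.30, 0.10),
    "a": (12.0, -0.08, 0.03),
    "b": (20.0, -0.15, 0.05),
}


def _qtl_genotype(sim_map: SimMap, truth: TruthTracks, qtl: TruthQTL) -> np.ndarray:
    """Genotype code at the QTL = genotype at the nearest simulated site."""
    g = sim_map.group(qtl.group)
    offset = 0
    for gg in sim_map.groups:
        if gg.name == qtl.group:
            break
        offset += gg.n_sites
    idx = int(np.argmin(np.abs(g.cm - qtl.pos_cm)))
    return truth.diplotypes[offset + idx]


def simulate_phenotypes(sim_map: SimMap, truth: TruthTracks,
                        qtls: Sequence[TruthQTL], config: SimConfig,
                        seed=None) -> pd.DataFrame:
    """Seed-color phenotypes R,G,B,l,a,b plus a binary visual score.

    The latent colour value is a sum of QTL genetic values and a Gaussian
    residual, scaled so each QTL's marginal variance share equals its h2
    (additive variance a^2/2 + dominance variance d^2/4 under 1:2:1
    frequencies).  R is an affine map of the latent value; the remaining
    traits are affine functions of the latent value with small independent
    noise; visual = 1 when R exceeds the configured threshold (yellow-ish).
    """
    total_h2 = sum(q.h2 for q in qtls)
    if total_h2 >= 1:
        raise ValueError("sum of QTL variance shares must be < 1")
    rng = _rng(config.seed if seed is None else seed)
    n = truth.diplotypes.shape[1]
    latent = np.zeros(n)
    genetic = np.zeros(n)
    for q in qtls:
        geno = _qtl_genotype(sim_map, truth, q)
        x = geno.astype(float) - 1.0            # -1, 0, +1 (bb = yellow = +1)
        z = (geno == AB).astype(float)
        dr = q.dominance_ratio
        var_unit = 0.5 + (dr ** 2) / 4.0        # Var(a*x + a*dr*z) per unit a
        a_eff = np.sqrt(q.h2 / var_unit)
        g_val = a_eff * x + a_eff * dr * (z - 0.5)
        latent += g_val
        genetic += g_val
    latent = latent + rng.normal(0.0, np.sqrt(max(1.0 - total_h2, 1e-12)), size=n)
    R = config.r_location + config.r_scale * latent
    data = {"R": R}
    latent_R = R
    for t, (b0, b1, sd) in _TRAIT_TRANSFORMS.items():
        data[t] = b0 + b1 * latent_R + rng.normal(0.0, sd * config.r_scale, size=n)
    df = pd.DataFrame(data, index=[f"F2_{i + 1:03d}" for i in range(n)])
    df["visual"] = (df["R"] > config.visual_threshold).astype(int)
    df.index.name = "id"
    truth.genetic_values = config.r_location + config.r_scale * genetic
    return df[_TRAITS + ["visual"]]


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionDesign:
    """2 genotypes x 3 stages x n replicates, log2-FPKM scale."""

    genotypes: tuple[str, str] = ("ZS11", "HAZ")   # black, yellow
    stages: tuple[int, ...] = (15, 25, 35)
    n_reps: int = 3

    def columns(self) -> list[str]:
        return [f"{g}_{s}daf_r{r + 1}" for g in self.genotypes for s in self.stages
                for r in range(self.n_reps)]


def simulate_expression(n_genes: int, module_sizes: Sequence[int],
                        n_flavonoid: int = 20, flavonoid_log2fc: float = -2.0,
                        design: ExpressionDesign | None = None,
                        factor_sd: float = 2.0, noise_sd: float = 0.25,
                        seed=0):
    """Expression matrix with planted module structure and DE truth.

    Genes within a module share a latent stage program (orthogonal between
    modules, sd ``factor_sd`` on the log2 scale, identical for the two
    genotypes); per-gene replicate noise has sd ``noise_sd``, giving
    within-replicate correlations above 0.96 at the defaults.  The first
    ``n_flavonoid`` genes of module 0 are the designated flavonoid set:
    shifted by ``flavonoid_log2fc`` in the yellow genotype at the second
    and third stages — they are the exact differential-expression truth.

    Returns ``(fpkm_df, truth)``; truth carries module labels and the
    flavonoid gene ids.
    """
    if len(module_sizes) < 2 or min(module_sizes) < 3:
        raise ValueError("need >= 2 modules of >= 3 genes")
    design = design or ExpressionDesign()
    if len(design.genotypes) < 2:
        raise ValueError("need two genotype conditions")
    rng = _rng(seed)
    cols = design.columns()
    n_samples = len(cols)
    sizes = list(module_sizes)
    n_mod_genes = sum(sizes)
    if n_genes < n_mod_genes:
        raise ValueError("n_genes smaller than the sum of module sizes")

    # per-module stage profile (a developmental program), shared by the two
    # genotypes and by replicates: genotype differences enter only through
    # the planted flavonoid shifts, so the DE truth is exactly that set
    n_stages = len(design.stages)
    stage_of_sample = np.tile(np.repeat(np.arange(n_stages), design.n_reps),
                              len(design.genotypes))
    # orthogonal stage programs keep planted modules distinguishable; with
    # more modules than stages the extra profiles are random redraws kept
    # only loosely separated (|cor| <= 0.8)
    q, _ = np.linalg.qr(rng.normal(size=(n_stages, n_stages)))
    profiles = []
    for m in range(len(sizes)):
        if m < n_stages:
            p = q[:, m] * factor_sd * np.sqrt(n_stages)
        else:
            for _ in range(100):
                p = rng.normal(0.0, factor_sd, size=n_stages)
                cors = [abs(np.corrcoef(p, e)[0, 1]) for e in profiles]
                if max(cors) <= 0.8:
                    break
        profiles.append(p)
    log2 = np.empty((n_genes, n_samples))
    labels = np.full(n_genes, -1, dtype=int)
    row = 0
    for m, size in enumerate(sizes):
        factor = profiles[m][stage_of_sample]
        base = rng.normal(5.0, 2.0, size=size)
        loading = np.ones(size)
        log2[row:row + size] = (base[:, None] + loading[:, None] * factor[None, :]
                                + rng.normal(0.0, noise_sd, size=(size, n_samples)))
        labels[row:row + size] = m
        row += size
    if row < n_genes:   # background genes: independent noise
        log2[row:] = rng.normal(5.0, 2.0, size=(n_genes - row, 1)) \
            + rng.normal(0.0, 1.0, size=(n_genes - row, n_samples))

    gene_ids = np.array([f"gene{i + 1:05d}" for i in range(n_genes)])
    flav = gene_ids[:n_flavonoid]
    yellow = design.genotypes[1]
    late = {design.stages[1], design.stages[2]}
    shift_cols = [j for j, c in enumerate(cols)
                  if c.startswith(yellow) and int(c.split("_")[1][:-3]) in late]
    log2[:n_flavonoid][:, shift_cols] += flavonoid_log2fc

    fpkm = pd.DataFrame(np.power(2.0, log2), index=gene_ids, columns=cols)
    fpkm.index.name = "gene"
    truth = {
        "module_labels": labels,
        "flavonoid_genes": list(flav),
        "flavonoid_log2fc": flavonoid_log2fc,
        "shifted_columns": [cols[j] for j in shift_cols],
    }
    return fpkm, truth


# ---------------------------------------------------------------------------
# fixtures


def write_fixtures(outdir, sim_map: SimMap | None = None,
                   config: SimConfig | None = None,
                   qtls: Sequence[TruthQTL] | None = None,
                   n_sites: int | None = 400, seed: int = 0):
    """Write a complete desk-scale fixture set: VCF, phenotypes, GFF3,
    expression matrix and a truth JSON.  Returns the paths dict."""
    from pathlib import Path
    from .variants import VariantMatrix, write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_map = sim_map or default_map(n_sites=n_sites)
    config = config or SimConfig(seed=seed)
    if qtls is None:
        qtls = [TruthQTL("A09", 81.91, 0.2095, dominance_ratio=0.5),
                TruthQTL("C03", 0.31, 0.0625)]
    rng = np.random.default_rng(seed)
    truth = simulate_f2(sim_map, config.n_individuals, rng)
    calls, ad = simulate_variant_calls(truth.diplotypes, config.mean_depth,
                                       config.error_rate, config.missing_rate, rng)
    pheno = simulate_phenotypes(sim_map, truth, qtls, config, seed=rng)
    samples = list(pheno.index)
    vm = VariantMatrix.from_simulation(sim_map, calls, ad, samples,
                                       parent_depth=int(round(config.mean_depth * 2)))
    paths = {
        "vcf": outdir / "population.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "gff3": outdir / "genes.gff3",
        "expression": outdir / "expression.tsv",
        "flavonoid": outdir / "flavonoid_genes.txt",
        "truth": outdir / "truth.json",
    }
    write_vcf(vm, paths["vcf"])
    pheno.to_csv(paths["phenotypes"], sep="\t")
    _write_toy_gff3(sim_map, paths["gff3"])
    expr, etruth = simulate_expression(300, [60, 60, 60], seed=seed)
    expr.to_csv(paths["expression"], sep="\t")
    paths["flavonoid"].write_text("\n".join(etruth["flavonoid_genes"]) + "\n")
    truth_doc = {
        "seed": seed,
        "qtls": [asdict(q) for q in qtls],
        "config": asdict(config),
        "crossovers": truth.crossovers,
        "expression_truth": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                             for k, v in etruth.items()},
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1))
    return paths


def _write_toy_gff3(sim_map: SimMap, path, genes_per_group: int = 40):
    lines = ["##gff-version 3"]
    for g in sim_map.groups:
        span = max(int(g.physical_bp), genes_per_group * 3000)
        starts = np.linspace(1, span - 2000, genes_per_group).astype(int)
        for i, s in enumerate(starts):
            gid = f"{g.name}g{i + 1:04d}"
            lines.append("\t".join([g.name, "sim", "gene", str(s), str(s + 1500),
                                    ".", "+", ".", f"ID={gid};Name={gid}"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
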