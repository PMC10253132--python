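"""Genotype-call container and VCF v4.2 input/output.

A :class:`VariantMatrix` holds biallelic calls for the two parents and the
F2 individuals with per-allele read depths — the raw material for marker
filtering and window genotyping.  VCF files are written as plain text
(GT and AD fields) and read back with cyvcf2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AA, AB, BB, MISSING = 0, 1, 2, -1

_GT_STRINGS = {AA: "0/0", AB: "0/1", BB: "1/1", MISSING: "./."}


@dataclass
class VariantMatrix:
    chrom: np.ndarray            # (n_sites,) str
    pos: np.ndarray              # (n_sites,) int, 1-based
    calls: np.ndarray            # (n_sites, n_ind) int8 codes
    allele_depths: np.ndarray    # (n_sites, n_ind, 2) int
    parent_calls: np.ndarray     # (n_sites, 2) int8
    parent_depths: np.ndarray    # (n_sites, 2, 2) int
    samples: list[str]
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if np.any(self.pos < 1):
            raise ValueError("positions are 1-based, must be >= 1")
        if self.ref is None:
            self.ref = np.full(self.n_sites, "A")
        if self.alt is None:
            self.alt = np.full(self.n_sites, "T")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    def subset(self, mask) -> "VariantMatrix":
        mask = np.asarray(mask)
        return VariantMatrix(self.chrom[mask], self.pos[mask], self.calls[mask],
                             self.allele_depths[mask], self.parent_calls[mask],
                             self.parent_depths[mask], list(self.samples),
                             self.ref[mask], self.alt[mask])

    @classmethod
    def from_simulation(cls, sim_map, calls, allele_depths, samples,
                        parent_depth: int = 10) -> "VariantMatrix":
        """Assemble a matrix from simulated F2 calls; parents are the
        idealized inbreds (parent1 = aa, parent2 = bb at every site)."""
        chrom = np.concatenate([np.full(g.n_sites, g.name) for g in sim_map.groups])
        pos = np.concatenate([g.bp for g in sim_map.groups])
        n = len(pos)
        pc = np.tile(np.array([AA, BB], dtype=np.int8), (n, 1))
        pd_ = np.zeros((n, 2, 2), dtype=int)
        pd_[:, 0, 0] = parent_depth   # parent1: all a reads
        pd_[:, 1, 1] = parent_depth   # parent2: all b reads
        return cls(chrom, pos, calls, allele_depths, pc, pd_, list(samples))


def write_vcf(vm: VariantMatrix, path, parent_names=("P1", "P2")) -> None:
    """Write a minimal VCF v4.2 with GT:AD; parents first, then F2 samples."""
    header = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
    ]
    for c in dict.fromkeys(vm.chrom.tolist()):
        header.append(f"##contig=<ID={c}>")
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT",
            *parent_names, *vm.samples]
    lines = header + ["\t".join(cols)]
    for i in range(vm.n_sites):
        fields = [str(vm.chrom[i]), str(vm.pos[i]), ".", str(vm.ref[i]), str(vm.alt[i]),
                  ".", "PASS", ".", "GT:AD"]
        for p in range(2):
            d = vm.parent_depths[i, p]
            fields.append(f"{_GT_STRINGS[int(vm.parent_calls[i, p])]}:{d[0]},{d[1]}")
        for j in range(vm.n_individuals):
            d = vm.allele_depths[i, j]
            fields.append(f"{_GT_STRINGS[int(vm.calls[i, j])]}:{d[0]},{d[1]}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path, parent_names=("P1", "P2")) -> VariantMatrix:
    """Read a biallelic VCF with GT and AD into a VariantMatrix.

    The two parent columns are identified by name; all other samples are
    treated as the F2 population.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    for p in parent_names:
        if p not in samples:
            raise ValueError(f"parent sample {p!r} not found in VCF")
    p_idx = [samples.index(p) for p in parent_names]
    f2_idx = [k for k in range(len(samples)) if k not in p_idx]
    chrom, pos, ref, alt = [], [], [], []
    calls, ads, pcalls, pdepths = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        g = np.asarray(var.gt_types, dtype=np.int8)
        g = np.where(g == 3, MISSING, g)
        ad = var.format("AD")
        if ad is None:
            ad = np.zeros((len(samples), 2), dtype=int)
        ad = np.maximum(np.asarray(ad)[:, :2], 0)
        calls.append(g[f2_idx])
        ads.append(ad[f2_idx])
        pcalls.append(g[p_idx])
        pdepths.append(ad[p_idx])
    return VariantMatrix(np.asarray(chrom), np.asarray(pos, dtype=np.int64),
                         np.asarray(calls, dtype=np.int8), np.asarray(ads),
                         np.asarray(pcalls, dtype=np.int8), np.asarray(pdepths),
                         [samples[k] for k in f2_idx],
                         np.asarray(ref), np.asarray(alt))
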