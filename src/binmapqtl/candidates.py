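"""Candidate-gene integration: QTL intervals x differential expression x
coexpression with a designated flavonoid-pathway gene set.

The selection procedure has three steps: (1) collect the genes lying in
any QTL peak's physical interval, (2) keep those differentially expressed
(|log2FC| > 1, FDR < 0.05) at the key developmental stages, (3) keep the
survivors that are themselves flavonoid-pathway genes or share a retained
coexpression edge (weight > 0.2) with a flavonoid DEG in a key module.
A -ddCt utility for qPCR relative quantification is included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# annotation


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file as (gene_id, chrom, start, end, strand)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("Name") or f"{f[0]}:{f[3]}"
            rows.append((gid, f[0], int(f[3]), int(f[4]), f[6]))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


def genes_in_interval(annotation: pd.DataFrame, chrom: str, start: int,
                      end: int) -> pd.DataFrame:
    """Genes overlapping the closed interval [start, end] on ``chrom``.

    Any overlap counts (1-based inclusive coordinates, GFF3 convention);
    the result is sorted by gene start.
    """
    if start > end:
        raise ValueError("interval start must be <= end")
    sub = annotation[(annotation["chrom"] == chrom)
                     & (annotation["end"] >= start)
                     & (annotation["start"] <= end)]
    return sub.sort_values("start", ignore_index=True)


# ---------------------------------------------------------------------------
# differential expression


def deg_filter(de_table: pd.DataFrame, stages=None, lfc_threshold: float = 1.0,
               fdr_threshold: float = 0.05, log_scale: bool = True) -> pd.DataFrame:
    """DEGs: |log2FC| > 1 and FDR < 0.05 at any of the requested stages.

    ``de_table`` needs columns gene, stage, log2fc, fdr.  With
    ``log_scale = False`` the threshold is applied to the raw fold change
    instead (|FC| > threshold), for tables reported on that scale.
    """
    for col in ("gene", "stage", "log2fc", "fdr"):
        if col not in de_table.columns:
            raise ValueError(f"DE table lacks column {col!r}")
    t = de_table
    if stages is not None:
        t = t[t["stage"].isin(set(stages))]
    effect = t["log2fc"].abs() if log_scale else np.abs(np.power(2.0, t["log2fc"]))
    keep = (effect > lfc_threshold) & (t["fdr"] < fdr_threshold)
    out = t[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


def standin_de_test(expr: pd.DataFrame, groups: pd.Series | dict,
                    stage_of: pd.Series | dict | None = None) -> pd.DataFrame:
    """Simple two-group differential-expression test on log2 values.

    A per-gene Welch t-test between the two conditions (per stage when
    ``stage_of`` is provided), with Benjamini-Hochberg FDR and log2fc =
    difference of group means of log2(x + 1).  This is a lightweight
    screen for synthetic data, not a count-model fit.
    """
    groups = pd.Series(groups).reindex(expr.columns)
    conds = pd.unique(groups.dropna())
    if len(conds) != 2:
        raise ValueError("exactly two conditions are required")
    stage_of = pd.Series(stage_of).reindex(expr.columns) if stage_of is not None \
        else pd.Series("all", index=expr.columns)
    logx = np.log2(expr.to_numpy(dtype=float) + 1.0)
    rows = []
    for stage in pd.unique(stage_of.dropna()):
        in_stage = (stage_of == stage).to_numpy()
        a = logx[:, in_stage & (groups == conds[0]).to_numpy()]
        b = logx[:, in_stage & (groups == conds[1]).to_numpy()]
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise ValueError("each group needs >= 2 replicates")
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
        p = np.nan_to_num(p, nan=1.0)
        fdr = multipletests(p, method="fdr_bh")[1]
        lfc = b.mean(axis=1) - a.mean(axis=1)
        rows.append(pd.DataFrame({"gene": expr.index, "stage": stage,
                                  "log2fc": lfc, "p": p, "fdr": fdr}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# candidate selection


@dataclass
class CandidateReport:
    table: pd.DataFrame    # gene, qtl, stages, flavonoid, partners, rationale

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def select_candidates(peaks, annotation: pd.DataFrame, de_table: pd.DataFrame,
                      flavonoid_genes, edges: pd.DataFrame,
                      key_stages=(25, 35), key_module_genes=None) -> CandidateReport:
    """Three-step candidate selection.

    ``peaks`` is a list of QTLPeak (or any objects with group/phys_lo_bp/
    phys_hi_bp); ``edges`` is the retained coexpression edge list
    (gene1, gene2, weight).  ``key_module_genes``, when given, restricts
    the flavonoid coexpression partners to genes of the key modules.
    Enlarging an interval can only add candidates (monotone selection).
    """
    flavonoid = set(flavonoid_genes)
    in_interval: dict[str, str] = {}
    for p in peaks or []:
        if p.phys_lo_bp is None or p.phys_hi_bp is None:
            continue
        sub = genes_in_interval(annotation, p.group, p.phys_lo_bp, p.phys_hi_bp)
        for g in sub["gene_id"]:
            in_interval.setdefault(g, f"{p.group}:{p.phys_lo_bp}-{p.phys_hi_bp}")
    degs = deg_filter(de_table, stages=key_stages)
    deg_stages = degs.groupby("gene")["stage"].agg(lambda s: sorted(set(s)))
    flav_degs = flavonoid & set(deg_stages.index)
    if key_module_genes is not None:
        flav_degs &= set(key_module_genes)

    partner_of: dict[str, list[tuple[str, float]]] = {}
    if edges is not None and len(edges):
        for g1, g2, w in edges[["gene1", "gene2", "weight"]].itertuples(index=False):
            if g2 in flav_degs:
                partner_of.setdefault(g1, []).append((g2, float(w)))
            if g1 in flav_degs:
                partner_of.setdefault(g2, []).append((g1, float(w)))

    rows = []
    for g, interval in in_interval.items():
        if g not in deg_stages.index:
            continue
        is_flav = g in flavonoid
        partners = partner_of.get(g, [])
        if not is_flav and not partners:
            continue
        rationale = "flavonoid gene" if is_flav else "coexpressed with flavonoid DEGs"
        if is_flav and partners:
            rationale = "flavonoid gene; coexpressed with flavonoid DEGs"
        rows.append({
            "gene": g, "qtl": interval, "de_stages": deg_stages[g],
            "flavonoid": is_flav,
            "partners": sorted(partners, key=lambda t: -t[1]),
            "rationale": rationale,
        })
    table = pd.DataFrame(rows, columns=["gene", "qtl", "de_stages", "flavonoid",
                                        "partners", "rationale"])
    return CandidateReport(table=table.sort_values("gene", ignore_index=True)
                           if len(table) else table)


# ---------------------------------------------------------------------------
# qPCR


def delta_delta_ct(ct: pd.DataFrame, reference_gene: str, control_sample: str) -> pd.Series:
    """Relative expression 2^(-ddCt) per (target gene, sample).

    ``ct`` is genes x samples of Ct values.  ddCt = (Ct_target,s -
    Ct_ref,s) - (Ct_target,c - Ct_ref,c) with c the control sample.
    """
    if reference_gene not in ct.index:
        raise ValueError(f"reference gene {reference_gene!r} missing from Ct table")
    if control_sample not in ct.columns:
        raise ValueError(f"control sample {control_sample!r} missing from Ct table")
    d_ct = ct.sub(ct.loc[reference_gene], axis=1)
    dd_ct = d_ct.sub(d_ct[control_sample], axis=0)
    rel = np.power(2.0, -dd_ct)
    return rel.drop(index=reference_gene).stack()
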