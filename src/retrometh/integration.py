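"""Methylome-transcriptome integration.

Maps DMPs to their annotated genes and applies the inverse-relationship
multi-study candidate filter: a (probe, gene) pair is a candidate when
|delta_beta| clears the magnitude threshold and the gene is significantly
differentially expressed, with fold change opposite in sign to delta_beta,
in at least ``min_studies`` independent studies.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diffmeth import bh_adjust, t_test_rows

__all__ = [
    "simple_deg_caller",
    "map_dmps_to_genes",
    "candidate_target_genes",
    "flag_reference_genes",
]

log = logging.getLogger(__name__)

DEG_COLUMNS = ["study_id", "gene", "log2FC", "q"]


def simple_deg_caller(
    expression: pd.DataFrame,
    groups: pd.Series,
    case_label: str,
    control_label: str,
    study_id: str = "study",
    alpha: float = 0.05,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-test on a log2-expression matrix.

    A deliberately simple stand-in DEG caller for synthetic studies:
    log2FC = case mean - control mean, q by BH.  Zero-variance genes are
    flagged degenerate and never called significant.
    """
    case_cols = [s for s in expression.columns if groups.get(s) == case_label]
    ctrl_cols = [s for s in expression.columns if groups.get(s) == control_label]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >=2 samples per group")
    x = expression[case_cols].to_numpy(dtype=float)
    y = expression[ctrl_cols].to_numpy(dtype=float)
    t, df, p, deg = t_test_rows(x, y, pooled=pooled)
    q = bh_adjust(np.where(deg, 1.0, p))
    out = pd.DataFrame(
        {
            "study_id": study_id,
            "gene": expression.index.astype(str),
            "log2FC": x.mean(axis=1) - y.mean(axis=1),
            "p": np.where(deg, 1.0, p),
            "q": q,
            "degenerate": deg,
        }
    ).reset_index(drop=True)
    out["significant"] = (out["q"] < alpha) & ~out["degenerate"]
    return out


def map_dmps_to_genes(dmps: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """One row per (probe, distinct gene) pair for the given DMPs.

    Probes without gene annotation are dropped (count logged).
    """
    ann = annotation.set_index(annotation["probe_id"].astype(str))
    rows = []
    n_intergenic = 0
    for _, dmp in dmps.iterrows():
        pid = str(dmp["probe_id"])
        if pid not in ann.index:
            continue
        genes = [g for g in str(ann.at[pid, "gene_names"]).split(";") if g]
        if not genes:
            n_intergenic += 1
            continue
        seen = set()
        for gene in genes:
            if gene in seen:
                continue
            seen.add(gene)
            rows.append(
                {
                    "probe_id": pid,
                    "gene": gene,
                    "family": dmp.get("family", ""),
                    "delta_beta": dmp["delta_beta"],
                    "p_fdr": dmp.get("p_fdr", np.nan),
                }
            )
    if n_intergenic:
        log.info("map_dmps_to_genes: dropped %d intergenic probes", n_intergenic)
    return pd.DataFrame(rows, columns=["probe_id", "gene", "family", "delta_beta", "p_fdr"])


def candidate_target_genes(
    dmgs: pd.DataFrame,
    deg_tables: pd.DataFrame,
    min_abs_delta: float = 0.05,
    min_studies: int = 2,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Apply the inverse-relationship multi-study candidate filter.

    A DEG record supports a (probe, gene) pair when its gene matches, its
    q < ``q_max`` and sign(log2FC) = -sign(delta_beta); support is counted
    per distinct study_id.  Pairs need |delta_beta| >= ``min_abs_delta``
    and >= ``min_studies`` supporting studies.  Output is sorted by
    |delta_beta| descending.
    """
    cols = ["probe_id", "gene", "family", "delta_beta", "p_fdr",
            "n_supporting_studies", "supporting_studies"]
    if dmgs.empty:
        return pd.DataFrame(columns=cols)
    degs = deg_tables.copy()
    missing = [c for c in DEG_COLUMNS if c not in degs.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")

    rows = []
    by_gene = dict(tuple(degs.groupby("gene")))
    for _, dmg in dmgs.iterrows():
        delta = float(dmg["delta_beta"])
        if abs(delta) < min_abs_delta or delta == 0:
            continue
        recs = by_gene.get(dmg["gene"])
        if recs is None:
            continue
        support = recs[(recs["q"] < q_max) & (np.sign(recs["log2FC"]) == -np.sign(delta))]
        studies = support["study_id"].astype(str).unique()
        if len(studies) < min_studies:
            continue
        serial = ";".join(
            f"{r.study_id}:{r.log2FC:g}:{r.q:g}" for r in support.itertuples(index=False)
        )
        rows.append(
            {
                "probe_id": dmg["probe_id"],
                "gene": dmg["gene"],
                "family": dmg.get("family", ""),
                "delta_beta": delta,
                "p_fdr": dmg.get("p_fdr", np.nan),
                "n_supporting_studies": len(studies),
                "supporting_studies": serial,
            }
        )
    out = pd.DataFrame(rows, columns=cols)
    if len(out):
        out = out.reindex(
            out["delta_beta"].abs().sort_values(ascending=False, kind="mergesort").index
        ).reset_index(drop=True)
    return out


def flag_reference_genes(candidates: pd.DataFrame, gene_list_path) -> pd.DataFrame:
    """Flag candidates whose gene appears in a user-supplied list
    (plain text, one symbol per line; case-sensitive exact match)."""
    with open(gene_list_path) as fh:
        reference = {line.strip() for line in fh if line.strip()}
    out = candidates.copy()
    out["reference_flag"] = out["gene"].astype(str).isin(reference)
    log.info("flag_reference_genes: %d of %d candidates flagged",
             int(out["reference_flag"].sum()), len(out))
    return out
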