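"""Cross-cohort set logic: Venn partitions of significant DMP sets,
variant-unique target-locus selection with the secondary re-test, and
cohort covariate-balance checks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import BetaMatrix, bh_adjust, t_test_rows

__all__ = ["VennPartition", "venn_partition", "select_variant_target_loci", "covariate_balance"]

_REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass(frozen=True)
class VennPartition:
    """The 7 disjoint regions of a three-set Venn diagram."""

    regions: dict

    def counts(self) -> dict:
        return {k: len(v) for k, v in self.regions.items()}

    def unique(self, which: str) -> set:
        if which not in ("A", "B", "C"):
            raise ValueError("which must be 'A', 'B' or 'C'")
        return self.regions[which]


def venn_partition(set_a, set_b, set_c) -> VennPartition:
    """Partition three sets into the 7 exclusive Venn regions."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    regions = {
        "A": a - b - c,
        "B": b - a - c,
        "C": c - a - b,
        "AB": (a & b) - c,
        "AC": (a & c) - b,
        "BC": (b & c) - a,
        "ABC": a & b & c,
    }
    return VennPartition(regions)


def select_variant_target_loci(
    dmp_tables: Mapping[str, pd.DataFrame],
    beta: BetaMatrix,
    variant_label: str,
    heterogeneous_label: str,
    alpha: float = 0.05,
    pooled: bool = False,
) -> pd.DataFrame:
    """Select target loci unique to one variant cohort.

    ``dmp_tables`` maps each case label to its vs-control DMP table (as
    produced by :func:`retrometh.diffmeth.call_dmps`).  Starting from
    probes significant ONLY in the variant cohort's comparison, each probe
    is re-tested (two-sample t) between the variant cohort and the
    heterogeneous case cohort, BH-adjusted over the re-tested set, and kept
    when the re-test ``p_fdr < alpha``.
    """
    if variant_label not in dmp_tables:
        raise ValueError(f"no DMP table for {variant_label!r}")
    sig = {
        label: set(tab.loc[tab["significant"], "probe_id"].astype(str))
        for label, tab in dmp_tables.items()
    }
    others = [lab for lab in dmp_tables if lab != variant_label]
    unique = sig[variant_label].difference(*[sig[o] for o in others]) if others else sig[variant_label]

    cols = ["probe_id", "delta_beta", "p_fdr_vs_control",
            "delta_beta_vs_heterogeneous", "p_vs_heterogeneous", "p_fdr_vs_heterogeneous"]
    if not unique:
        return pd.DataFrame(columns=cols)

    var_s = beta.samples_in(variant_label)
    het_s = beta.samples_in(heterogeneous_label)
    if len(var_s) < 2:
        raise ValueError(f"variant cohort {variant_label!r} has fewer than 2 samples")
    probes = [p for p in beta.values.index if p in unique]
    x = beta.values.loc[probes, var_s].to_numpy()
    y = beta.values.loc[probes, het_s].to_numpy()
    _, _, p, _ = t_test_rows(x, y, pooled=pooled)
    p_fdr = bh_adjust(p)

    base = dmp_tables[variant_label].set_index(dmp_tables[variant_label]["probe_id"].astype(str))
    out = pd.DataFrame(
        {
            "probe_id": probes,
            "delta_beta": base.loc[probes, "delta_beta"].to_numpy(),
            "p_fdr_vs_control": base.loc[probes, "p_fdr"].to_numpy(),
            "delta_beta_vs_heterogeneous": x.mean(axis=1) - y.mean(axis=1),
            "p_vs_heterogeneous": p,
            "p_fdr_vs_heterogeneous": p_fdr,
        }
    )
    return out[out["p_fdr_vs_heterogeneous"] < alpha].reset_index(drop=True)[cols]


def covariate_balance(
    sample_sheet: pd.DataFrame,
    group_labels,
    control_label: str,
) -> dict:
    """Covariate-balance checks across cohorts.

    Pearson chi-square (no continuity correction) for sex x group over the
    listed groups, and pairwise two-sided Mann-Whitney tests for age,
    control vs each case group (exact for <= 8 per group without ties,
    normal approximation with tie correction otherwise).  Missing covariate
    columns skip the corresponding test with a notice.
    """
    report: dict = {"sex_chi2_p": None, "age_mwu": {}, "notices": []}
    sheet = sample_sheet[sample_sheet["group"].isin(list(group_labels))]

    if "sex" in sheet.columns and sheet["sex"].notna().any():
        table = pd.crosstab(sheet["sex"], sheet["group"])
        if table.shape[0] >= 2 and table.shape[1] >= 2:
            chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
            report["sex_chi2_stat"] = float(chi2)
            report["sex_chi2_p"] = float(p)
        else:
            report["notices"].append("sex table degenerate; chi-square skipped")
    else:
        report["notices"].append("sex column missing; chi-square skipped")

    if "age" in sheet.columns and sheet["age"].notna().any():
        ctrl_age = sheet.loc[sheet["group"] == control_label, "age"].dropna().to_numpy()
        for label in group_labels:
            if label == control_label:
                continue
            case_age = sheet.loc[sheet["group"] == label, "age"].dropna().to_numpy()
            if len(ctrl_age) == 0 or len(case_age) == 0:
                report["notices"].append(f"no ages for {label}; Mann-Whitney skipped")
                continue
            pooled = np.concatenate([ctrl_age, case_age])
            if np.all(pooled == pooled[0]):  # zero rank variance
                report["age_mwu"][label] = {
                    "u": len(ctrl_age) * len(case_age) / 2.0, "p": 1.0,
                }
                continue
            exact = (
                len(ctrl_age) <= 8 and len(case_age) <= 8
                and len(np.unique(pooled)) == len(pooled)
            )
            res = stats.mannwhitneyu(
                ctrl_age, case_age,
                alternative="two-sided",
                method="exact" if exact else "asymptotic",
                use_continuity=False,
            )
            report["age_mwu"][label] = {"u": float(res.statistic), "p": float(res.pvalue)}
    else:
        report["notices"].append("age column missing; Mann-Whitney skipped")
    return report
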