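"""Gene-region feature enrichment of significant DMPs.

For each of the six manifest feature categories, a 2x2 Fisher exact test
contrasts DMPs against background (non-DMP) repeat-resident probes of the
same element class.  A probe counts once per distinct feature even if the
feature is listed for several genes; intergenic probes belong to no
feature and contribute to the "not annotated" cells only.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_adjust
from .io_annotation import GENE_FEATURES

__all__ = ["fisher_exact_2x2", "feature_enrichment"]


def fisher_exact_2x2(a: int, b: int, c: int, d: int):
    """Two-sided Fisher exact test for the table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)``.  The odds ratio is the sample ratio
    ``(a*d)/(b*c)`` (inf or 0 on zero cells, NaN when undefined); an
    all-zero margin yields p = 1 with a NaN odds ratio.
    """
    cells = (a, b, c, d)
    if any((not float(x).is_integer()) or x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return math.nan, 1.0
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def _feature_sets(annotation: pd.DataFrame) -> pd.Series:
    """Deduplicated feature set per probe id."""
    feats = annotation["gene_features"].astype(str).map(
        lambda s: frozenset(f for f in s.split(";") if f)
    )
    return pd.Series(feats.to_numpy(), index=annotation["probe_id"].astype(str).to_numpy())


def feature_enrichment(
    dmp_probe_ids,
    annotation: pd.DataFrame,
    element_class: str,
    features=GENE_FEATURES,
) -> pd.DataFrame:
    """Per-feature Fisher enrichment of DMPs vs background probes.

    ``a`` = DMPs of the class annotated to the feature, ``b`` = DMPs not,
    ``c``/``d`` = the same split over non-DMP repeat-resident probes of the
    class.  Raw two-sided p values plus BH adjustment across the features.
    """
    cls = annotation[
        (annotation["element_class"] == element_class)
        & (annotation["repeat_name"].astype(str) != "")
    ]
    if cls.empty:
        return pd.DataFrame(
            columns=["element_class", "feature", "a", "b", "c", "d", "odds_ratio", "p", "p_bh"]
        )
    feat_sets = _feature_sets(cls)
    dmp_ids = set(str(p) for p in dmp_probe_ids) & set(feat_sets.index)
    bg_ids = [p for p in feat_sets.index if p not in dmp_ids]
    n_dmp, n_bg = len(dmp_ids), len(bg_ids)

    rows = []
    for feature in features:
        a = sum(1 for p in dmp_ids if feature in feat_sets[p])
        c = sum(1 for p in bg_ids if feature in feat_sets[p])
        b, d = n_dmp - a, n_bg - c
        odds, p = fisher_exact_2x2(a, b, c, d)
        rows.append(
            {
                "element_class": element_class,
                "feature": feature,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out
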