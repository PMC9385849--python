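import numpy as np
import pandas as pd
import pytest

from retrometh.diffmeth import BetaMatrix
from retrometh.io_annotation import classify_repeat_name


def make_annotation(repeat_names, gene_names=None, gene_features=None):
    """Annotation frame for synthetic probes cg000000..; empty name = not
    repeat-resident."""
    n = len(repeat_names)
    gene_names = gene_names or [""] * n
    gene_features = gene_features or [""] * n
    rows = []
    for i, name in enumerate(repeat_names):
        taxon = classify_repeat_name(name) if name else None
        rows.append(
            {
                "probe_id": f"cg{i:06d}",
                "chrom": "chrS1",
                "pos": 1000 + 500 * i,
                "repeat_name": name,
                "element_class": taxon.element_class if taxon else "unclassified",
                "family": taxon.family if taxon else "unclassified",
                "age_class": taxon.age_class if taxon else "unclassified",
                "overlap_bp": 2 if name else 0,
                "gene_names": gene_names[i],
                "gene_features": gene_features[i],
            }
        )
    return pd.DataFrame(rows)


def make_beta(values, groups_per_sample):
    """BetaMatrix from an array (probes x samples) and group labels."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    samples = [f"S{j:04d}" for j in range(n_samples)]
    df = pd.DataFrame(values, index=[f"cg{i:06d}" for i in range(n_probes)], columns=samples)
    groups = pd.Series(list(groups_per_sample), index=samples)
    return BetaMatrix(df, groups)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
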