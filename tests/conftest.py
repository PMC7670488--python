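import numpy as np
import pandas as pd
import pytest

from lofpipe.containers import GenotypeTable, variant_key


def make_genotype_table(dosage, cohorts, genes=None, func_classes=None):
    """Build a small GenotypeTable from a dosage matrix (rows = samples)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    counts = {"A": 0, "B": 0}
    ids = []
    for c in cohorts:
        counts[c] += 1
        ids.append(f"{c}{counts[c]}")
    samples = pd.DataFrame({"sample_id": ids, "cohort": list(cohorts)})
    genes = genes if genes is not None else [None] * m
    func_classes = func_classes if func_classes is not None else ["stopgain"] * m
    pos = np.arange(1, m + 1) * 100
    variants = pd.DataFrame(
        {
            "variant_id": [variant_key("1", int(p), "A", "C") for p in pos],
            "chrom": "1",
            "pos": pos,
            "ref": "A",
            "alt": "C",
            "gene": genes,
            "func_class": func_classes,
        }
    )
    return GenotypeTable(samples=samples, variants=variants, dosage=dosage)


@pytest.fixture
def toy_gt():
    """4 samples (2 A, 2 B), 3 variants in one gene."""
    return make_genotype_table(
        [[0, 1, 0], [1, 0, 0], [2, 1, 1], [1, 2, 0]],
        "AABB",
        genes=["g1", "g1", "g1"],
    )
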