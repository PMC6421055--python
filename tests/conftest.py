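import numpy as np
import pandas as pd
import pytest

import altox


@pytest.fixture(scope="session")
def small_sim():
    """300-gene simulated experiment with all planted classes present."""
    cfg = altox.SimulationConfig(n_genes=300, seed=2)
    cm, design, truth = altox.simulate_counts(cfg)
    return cm, design, truth


@pytest.fixture(scope="session")
def design16():
    """Plain 4-genotype × 2-condition × 2-replicate design sheet."""
    rows = []
    for g, tol in [("Hermes", "resistant"), ("TMP1919", "resistant"),
                   ("Lira", "sensitive"), ("Orshanskiy", "sensitive")]:
        for cond in ("control", "stress"):
            for rep in (1, 2):
                rows.append({"sample_id": f"{g}_{cond}_r{rep}", "genotype": g,
                             "tolerance": tol, "condition": cond, "replicate": rep})
    return altox.StudyDesign(pd.DataFrame(rows))


@pytest.fixture()
def tiny_counts():
    """3 genes × 2 samples with known column sums [15, 25]."""
    df = pd.DataFrame([[10, 0], [5, 5], [0, 20]],
                      index=["g1", "g2", "g3"], columns=["s1", "s2"])
    return altox.CountMatrix(df)


@pytest.fixture(scope="session")
def phenotype_table():
    """Field-trial phenotype means: 4 cultivars × 3 traits × 2 conditions."""
    data = {
        ("Hermes", "plant height cm"): (60.6, 70.5),
        ("Hermes", "fiber mass mg"): (115.6, 135.6),
        ("Hermes", "seed pod count"): (2.9, 2.8),
        ("TMP1919", "plant height cm"): (69.4, 73.7),
        ("TMP1919", "fiber mass mg"): (93.7, 108.9),
        ("TMP1919", "seed pod count"): (3.5, 4.3),
        ("Lira", "plant height cm"): (56.2, 74.6),
        ("Lira", "fiber mass mg"): (54.4, 131.8),
        ("Lira", "seed pod count"): (2.5, 4.4),
        ("Orshanskiy", "plant height cm"): (61.2, 71.0),
        ("Orshanskiy", "fiber mass mg"): (52.8, 83.7),
        ("Orshanskiy", "seed pod count"): (3.2, 5.4),
    }
    rows = []
    for (cultivar, trait), (stress, control) in data.items():
        rows.append({"cultivar": cultivar, "condition": "stress", "trait": trait,
                     "mean": stress})
        rows.append({"cultivar": cultivar, "condition": "control", "trait": trait,
                     "mean": control})
    return altox.io_design.validate_phenotype_table(pd.DataFrame(rows))


#: printed one-decimal decline percentages consistent with the
#: stress/control round-half-up rule (Hermes height and seed pods are not)
CONSISTENT_DECLINES = {
    ("Hermes", "fiber mass mg"): 85.3,
    ("TMP1919", "plant height cm"): 94.2,
    ("TMP1919", "fiber mass mg"): 86.0,
    ("TMP1919", "seed pod count"): 81.4,
    ("Lira", "plant height cm"): 75.3,
    ("Lira", "fiber mass mg"): 41.3,
    ("Lira", "seed pod count"): 56.8,
    ("Orshanskiy", "plant height cm"): 86.2,
    ("Orshanskiy", "fiber mass mg"): 63.1,
    ("Orshanskiy", "seed pod count"): 59.3,
}
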