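import numpy as np
import pytest

import graphsem as gs


@pytest.fixture
def tiny_cohort():
    """Five samples, one variable of each ordinary dtype + survival."""
    n = 5
    return gs.Cohort.from_columns(
        "TOY",
        [f"s{i}" for i in range(n)],
        {
            "TP53.Mut": np.array([1, 0, 1, 0, 0.0]),
            "GENE.RNA": np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
            "TRIM36.GISTIC": np.array([-1, 0, -2, 1, 0.0]),
            "OS.Survival__time": np.array([10, 20, 15, 30, 25.0]),
            "OS.Survival__event": np.array([1, 0, 1, 0, 1.0]),
        },
        [
            gs.Variable("TP53.Mut", "Mutation", "binary"),
            gs.Variable("GENE.RNA", "mRNA", "continuous"),
            gs.Variable("TRIM36.GISTIC", "CNV", "ordinal"),
            gs.Variable("OS.Survival", "Survival", "survival"),
        ],
    )


@pytest.fixture
def regression_cohort():
    """Seeded n=500 cohort with Y = 0.5 X1 - 0.2 X2 + noise."""
    rng = np.random.default_rng(11)
    n = 500
    x1 = rng.normal(size=n)
    x2 = 0.3 * x1 + rng.normal(size=n)
    y = 0.5 * x1 - 0.2 * x2 + rng.normal(size=n)
    return gs.Cohort.from_columns(
        "REG", [f"s{i:03d}" for i in range(n)],
        {"X1": x1, "X2": x2, "Y": y},
        [gs.Variable(v, "Clinical", "continuous") for v in ("X1", "X2", "Y")],
    )


@pytest.fixture
def cfa_graph():
    return gs.build_graph(
        {
            "name": "cellcycle",
            "nodes": [
                {"id": "TP53.Mut"},
                {"id": "CellCycle", "kind": "latent"},
                {"id": "CCNB1.RNA"},
                {"id": "PCNA.RNA"},
                {"id": "MKI67.RNA"},
            ],
            "edges": [
                {"src": "CellCycle", "dst": "CCNB1.RNA", "type": "loading"},
                {"src": "CellCycle", "dst": "PCNA.RNA", "type": "loading"},
                {"src": "CellCycle", "dst": "MKI67.RNA", "type": "loading"},
                {"src": "TP53.Mut", "dst": "CellCycle"},
            ],
        }
    )


def cfa_sim_spec(seed, n_samples=2000, path=0.8, loadings=(1.0, 0.8, 0.6)):
    return gs.SimSpec(
        n_samples=n_samples, seed=seed,
        binary={"TP53.Mut": {"prevalence": 0.3}},
        structural={
            "CellCycle": {"parents": {"TP53.Mut": path}, "noise_sd": 1.0,
                          "latent": True},
            "CCNB1.RNA": {"parents": {"CellCycle": loadings[0]}, "noise_sd": 0.6},
            "PCNA.RNA": {"parents": {"CellCycle": loadings[1]}, "noise_sd": 0.6},
            "MKI67.RNA": {"parents": {"CellCycle": loadings[2]}, "noise_sd": 0.6},
        },
    )
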