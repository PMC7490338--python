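from pathlib import Path

import numpy as np
import pytest

from regnet.io import ExpressionMatrix
from regnet.simulate import SimulationConfig, simulate_study

DATA_DIR = Path(__file__).parent / "data"


def limma_fixture_matrix() -> ExpressionMatrix:
    """Deterministic 30-feature, 4 vs 4 matrix; the values behind
    tests/data/limma_moderated_t_expected.tsv (see limma_oracle.R)."""
    rng = np.random.default_rng(20240917)
    n_feat, n1, n2 = 30, 4, 4
    sd = rng.uniform(0.2, 1.5, n_feat)
    base = rng.uniform(5, 10, n_feat)
    shift = np.where(rng.random(n_feat) < 0.3, rng.normal(0, 1.5, n_feat), 0.0)
    vals = (base[:, None]
            + np.c_[np.tile(shift[:, None], (1, n1)), np.zeros((n_feat, n2))]
            + rng.normal(0, 1, (n_feat, n1 + n2)) * sd[:, None])
    samples = [f"c{i}" for i in range(n1)] + [f"k{i}" for i in range(n2)]
    groups = {s: ("case" if s.startswith("c") else "control") for s in samples}
    return ExpressionMatrix(
        "fx", "mRNA", "DN", [f"F{i:03d}" for i in range(n_feat)],
        samples, vals, groups,
    )


def make_matrix(values, n_case, dataset_id="ds", kind="mRNA", condition="DN",
                feature_ids=None):
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    samples = [f"s{i}" for i in range(n_samples)]
    groups = {s: ("case" if i < n_case else "control")
              for i, s in enumerate(samples)}
    feats = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(dataset_id, kind, condition, feats, samples,
                            values, groups)


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared across read-only tests."""
    return simulate_study(SimulationConfig(
        seed=11, n_genes=120, n_mirnas=15, repression_edges=10,
        sponge_edges=20, lnc_mrna_edges=10, targets_per_tf=5,
        upstream_bp=400, downstream_bp=100,
    ))
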