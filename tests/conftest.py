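import numpy as np
import pandas as pd
import pytest

from isrdep.containers import ExpressionMatrix
from isrdep.synthetic import generate_design


@pytest.fixture
def design4() -> pd.DataFrame:
    """Balanced 4x4 design, 2F/2M per group."""
    return generate_design(4, seed=0)


def make_matrix(values: np.ndarray, design: pd.DataFrame, scale: str = "log2",
                prefix: str = "g") -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix aligned to a design."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = [f"{prefix}{i + 1}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(ids, name="gene_id"),
                      columns=design["sample_id"])
    return ExpressionMatrix(values=df, scale=scale)


def group_values(design: pd.DataFrame, per_group: dict[str, list[float]]) -> np.ndarray:
    """Build one gene row from per-group sample values (in design order)."""
    row = np.empty(len(design))
    for g, vals in per_group.items():
        idx = np.flatnonzero((design["group"] == g).to_numpy())
        row[idx] = vals
    return row


def censored_floor_matrix(design: pd.DataFrame, n_floor: int = 400, n_signal: int = 1600,
                          floor_level: float = 1.0, seed: int = 0) -> ExpressionMatrix:
    """Signal genes spanning 2-14 log2 plus a detection-floor block: genes
    below the limit read at (just under) floor_level, as a saturating
    detector reports them."""
    rng = np.random.default_rng(seed)
    n = len(design)
    sig = rng.uniform(2, 14, n_signal)[:, None] + rng.normal(0, 0.25, (n_signal, n))
    floor_vals = floor_level - rng.uniform(0.0, 0.05, (n_floor, n))
    ids = [f"noise{i}" for i in range(n_floor)] + [f"sig{i}" for i in range(n_signal)]
    df = pd.DataFrame(np.vstack([floor_vals, sig]), index=ids, columns=design["sample_id"])
    return ExpressionMatrix(df, "normalized_log2")


def bh_brute_force(p: np.ndarray) -> np.ndarray:
    """Quadratic-time step-up BH oracle straight from the definition:
    q(i) = min over j with p(j) >= p(i) of m * p(j) / rank(j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    ranks = np.array([(p <= pj).sum() for pj in p])  # max rank among ties
    crit = m * p / ranks
    q = np.array([crit[p >= pi].min() for pi in p])
    return np.minimum(q, 1.0)
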