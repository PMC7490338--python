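"""Permutation-stability Pearson correlation for unpaired miRNA/mRNA samples.

miRNA and mRNA profiles come from different sample cohorts with unequal group
sizes, so no natural sample pairing exists. Each run draws, without
replacement, i case and i control samples independently from the miRNA and the
mRNA dataset (i = the smallest of the four group sizes), pairs the draws by
order within group, and computes Pearson's r on the pooled 2i points together
with its exact t-transform p-value. Over n_runs such random pseudo-pairings
the *stability* of a pair is the fraction of runs that are significant
(p < alpha) with a sign agreeing with the majority sign among significant
runs; pairs are accepted at stability >= 0.95, optionally restricted to
negative (repressive) associations.

Randomness: every (miRNA, mRNA) pair draws from its own substream derived
from the user seed and a stable hash of the two feature ids, so results do
not depend on the order in which pairs are evaluated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionMatrix


@dataclass
class CorrelationRecord:
    mirna_id: str
    mrna_id: str
    condition: str
    n_runs: int
    subsample_size: int
    stability: float
    median_r: float
    sign: str  # negative | positive | mixed

    def __post_init__(self) -> None:
        if not 0.0 <= self.stability <= 1.0:
            raise ValueError("stability must be in [0, 1]")
        if abs(self.median_r) > 1 + 1e-12:
            raise ValueError("median r out of range")


def pearson_r(x, y) -> float:
    """Pearson correlation via the computational (sum) form.

    r = (n·Σxy − Σx·Σy) / sqrt((n·Σx² − (Σx)²)(n·Σy² − (Σy)²))
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    sx, sy = x.sum(), y.sum()
    vx = n * (x * x).sum() - sx * sx
    vy = n * (y * y).sum() - sy * sy
    if vx <= 0 or vy <= 0:
        raise ValueError("zero variance")
    r = (n * (x * y).sum() - sx * sy) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def _r_to_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the exact t-transform t = r·sqrt((n−2)/(1−r²))."""
    df = n - 2
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def run_correlation(mirna_vals, mrna_vals, i: int, rng: np.random.Generator):
    """One permutation run: subsample i case + i control from each dataset.

    ``mirna_vals`` and ``mrna_vals`` are (case_vector, control_vector) tuples.
    Returns {"r": r, "p": p} for the pooled 2i pseudo-paired points.
    """
    (xc, xl), (yc, yl) = mirna_vals, mrna_vals
    if i < 2:
        raise ValueError("subsample size must be >= 2")
    for v in (xc, xl, yc, yl):
        if len(v) < i:
            raise ValueError(f"subsample size {i} exceeds group size {len(v)}")
    x = np.concatenate([
        rng.choice(np.asarray(xc, dtype=float), i, replace=False),
        rng.choice(np.asarray(xl, dtype=float), i, replace=False),
    ])
    y = np.concatenate([
        rng.choice(np.asarray(yc, dtype=float), i, replace=False),
        rng.choice(np.asarray(yl, dtype=float), i, replace=False),
    ])
    r = pearson_r(x, y)
    return {"r": r, "p": float(_r_to_p(np.array([r]), 2 * i)[0])}


def _pair_rng(seed: int, mirna_id: str, mrna_id: str) -> np.random.Generator:
    """Order-independent substream for one (miRNA, mRNA) pair."""
    digest = hashlib.sha256(f"{mirna_id}\x00{mrna_id}".encode()).digest()
    h1 = int.from_bytes(digest[:4], "big") % (2**31)
    h2 = int.from_bytes(digest[4:8], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), h1, h2]))


def _subsample_indices(rng: np.random.Generator, n_runs: int, n: int, i: int) -> np.ndarray:
    """(n_runs, i) indices, each row a without-replacement draw from range(n)."""
    return np.argsort(rng.random((n_runs, n)), axis=1)[:, :i]


def _stability_stats(xc, xl, yc, yl, i, n_runs, alpha, rng):
    """Vectorized engine: all runs for one pair at once."""
    ix_c = _subsample_indices(rng, n_runs, len(xc), i)
    ix_l = _subsample_indices(rng, n_runs, len(xl), i)
    iy_c = _subsample_indices(rng, n_runs, len(yc), i)
    iy_l = _subsample_indices(rng, n_runs, len(yl), i)
    x = np.concatenate([np.asarray(xc)[ix_c], np.asarray(xl)[ix_l]], axis=1)
    y = np.concatenate([np.asarray(yc)[iy_c], np.asarray(yl)[iy_l]], axis=1)
    n = 2 * i
    sx = x.sum(axis=1)
    sy = y.sum(axis=1)
    vx = n * (x * x).sum(axis=1) - sx * sx
    vy = n * (y * y).sum(axis=1) - sy * sy
    denom = np.sqrt(np.maximum(vx, 0) * np.maximum(vy, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (n * (x * y).sum(axis=1) - sx * sy) / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    p = _r_to_p(r, n)
    sig = (p < alpha) & (denom > 0)
    n_neg = int((sig & (r < 0)).sum())
    n_pos = int((sig & (r > 0)).sum())
    if n_neg >= n_pos:
        majority, n_major = "negative", n_neg
    else:
        majority, n_major = "positive", n_pos
    stability = n_major / n_runs
    sign = majority if stability > 0 else "mixed"
    return stability, float(np.median(r)), sign


def permutation_stability(
    mirna_vals,
    mrna_vals,
    mirna_id: str = "miRNA",
    mrna_id: str = "mRNA",
    condition: str = "DN",
    n_runs: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> CorrelationRecord:
    """Full stability record for one pair; vals are (case, control) tuples.

    The subsample size i is the minimum of the four group sizes.
    """
    (xc, xl), (yc, yl) = mirna_vals, mrna_vals
    i = min(len(xc), len(xl), len(yc), len(yl))
    if i < 2:
        raise ValueError("all four groups need >= 2 samples")
    rng = _pair_rng(seed, mirna_id, mrna_id)
    stability, median_r, sign = _stability_stats(
        np.asarray(xc, float), np.asarray(xl, float),
        np.asarray(yc, float), np.asarray(yl, float),
        i, n_runs, alpha, rng,
    )
    return CorrelationRecord(
        mirna_id=mirna_id, mrna_id=mrna_id, condition=condition,
        n_runs=n_runs, subsample_size=i, stability=stability,
        median_r=median_r, sign=sign,
    )


def correlate_matrices(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    pairs: list[tuple[str, str]] | None = None,
    n_runs: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    condition: str | None = None,
) -> list[CorrelationRecord]:
    """Stability records for (miRNA, mRNA) pairs across two matrices.

    ``pairs`` defaults to the full cross product. The correlation's condition
    tag is taken from the mRNA matrix (the miRNA cohort is shared between
    contrasts).
    """
    condition = condition or mrna.condition
    if pairs is None:
        pairs = [(m, g) for m in mirna.feature_ids for g in mrna.feature_ids]
    case_mask_x = np.array([mirna.groups[s] == "case" for s in mirna.sample_ids])
    case_mask_y = np.array([mrna.groups[s] == "case" for s in mrna.sample_ids])
    records = []
    for mirna_id, mrna_id in pairs:
        xr = mirna.row(mirna_id)
        yr = mrna.row(mrna_id)
        records.append(
            permutation_stability(
                (xr[case_mask_x], xr[~case_mask_x]),
                (yr[case_mask_y], yr[~case_mask_y]),
                mirna_id=mirna_id, mrna_id=mrna_id, condition=condition,
                n_runs=n_runs, alpha=alpha, seed=seed,
            )
        )
    return records


def select_pairs(
    records: list[CorrelationRecord],
    stability_min: float = 0.95,
    require_negative: bool = True,
) -> list[tuple[str, str]]:
    """Pairs accepted at stability >= stability_min (inclusive), optionally
    restricted to negative associations."""
    out = []
    for rec in records:
        if rec.stability < stability_min:
            continue
        if require_negative and rec.sign != "negative":
            continue
        out.append((rec.mirna_id, rec.mrna_id))
    return out


def write_correlation_table(records: list[CorrelationRecord], path,
                            stability_min: float = 0.95,
                            require_negative: bool = True) -> None:
    import pandas as pd

    selected = set(select_pairs(records, stability_min, require_negative))
    rows = [
        {
            "mirna_id": r.mirna_id, "mrna_id": r.mrna_id, "condition": r.condition,
            "i": r.subsample_size, "n_runs": r.n_runs, "stability": r.stability,
            "median_r": r.median_r, "sign": r.sign,
            "selected": int((r.mirna_id, r.mrna_id) in selected),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
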