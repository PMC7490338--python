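"""Differential expression by empirical-Bayes moderated two-sample t-tests.

The per-feature residual variances s²_g are shrunk toward a common prior
variance s0² under a scaled-F hierarchical model: with d_g residual degrees of
freedom per feature and a prior with d0 degrees of freedom,

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g)

and the moderated statistic t_g = Δ_g / (s̃_g·sqrt(1/n1 + 1/n2)) is referred
to a t distribution on d0 + d_g degrees of freedom. The hyperparameters
(d0, s0²) are estimated by the method of moments on log s²_g: if
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), then E[e_g] = log s0² + ψ(d0/2) −
log(d0/2) and Var[e_g] = ψ'(d_g/2) + ψ'(d0/2), so d0 solves a trigamma
equation (inverted here by bisection). When the excess variance of e_g is
non-positive, d0 is taken as infinite and every feature shares s0².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix


@dataclass
class DEResult:
    feature_id: str
    log2_fc: float
    mean_case: float
    mean_control: float
    t_mod: float
    p: float
    df_total: float
    dataset_id: str
    condition: str


@dataclass
class DEGSet:
    dataset_id: str
    condition: str
    features: set[str]
    fc2_features: set[str]

    def __post_init__(self) -> None:
        if not self.fc2_features <= self.features:
            raise ValueError("fc2_features must be a subset of features")


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return special.polygamma(1, x)


def trigamma_inverse(y: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 by bisection.

    trigamma is strictly decreasing on (0, inf) with range (0, inf).
    Returns inf for y <= 0.
    """
    if y <= 0:
        return np.inf
    lo, hi = 1e-8, 1e8
    if _trigamma(lo) < y:
        return lo
    if _trigamma(hi) > y:
        return hi
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if _trigamma(mid) > y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimates (d0, s0²) of the scaled-F prior from sample variances.

    Features with non-positive s² are excluded from the fit (their log is
    undefined) but still receive shrinkage downstream.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1) - _trigamma(df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def moderated_t_test(
    matrix: ExpressionMatrix, prior_df: float | None = None
) -> list[DEResult]:
    """Empirical-Bayes moderated t-test of case vs control for every feature.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Log2-scale expression with >= 2 samples per group.
    prior_df : float, optional
        Force the prior degrees of freedom d0 instead of estimating them:
        ``0`` reproduces the ordinary pooled-variance t-test exactly, ``inf``
        shares a single common variance across features.
    """
    case_mask = np.array([matrix.groups[s] == "case" for s in matrix.sample_ids])
    n1 = int(case_mask.sum())
    n2 = len(matrix.sample_ids) - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")

    x1 = matrix.values[:, case_mask]
    x2 = matrix.values[:, ~case_mask]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    lfc = m1 - m2
    dg = n1 + n2 - 2
    s2 = (((x1 - m1[:, None]) ** 2).sum(axis=1)
          + ((x2 - m2[:, None]) ** 2).sum(axis=1)) / dg

    if prior_df is not None:
        d0 = float(prior_df)
        s02 = float(np.mean(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    elif len(matrix.feature_ids) < 2:
        warnings.warn("fewer than 2 features: falling back to ordinary t-test")
        d0, s02 = 0.0, 1.0
    else:
        d0, s02 = fit_f_dist(s2, dg)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(dg)
    else:
        s2_post = (d0 * s02 + dg * s2) / (d0 + dg)
        df_total = float(d0 + dg)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (lfc != 0), np.sign(lfc) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)

    return [
        DEResult(
            feature_id=f, log2_fc=float(lfc[i]), mean_case=float(m1[i]),
            mean_control=float(m2[i]), t_mod=float(t[i]), p=float(min(p[i], 1.0)),
            df_total=df_total, dataset_id=matrix.dataset_id,
            condition=matrix.condition,
        )
        for i, f in enumerate(matrix.feature_ids)
    ]


def call_degs(
    results: list[DEResult],
    fc_min: float = 1.5,
    p_max: float = 0.05,
    bh: bool = False,
) -> DEGSet:
    """Call differentially expressed features at |FC| >= fc_min and p < p_max.

    The fold-change cutoff is applied on the log2 scale (|log2FC| >= log2(fc_min));
    p_max is a strict upper bound. ``bh=True`` applies Benjamini-Hochberg
    adjustment to the p-values first. The fc2 subset tracks |FC| >= 2.
    """
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    if not results:
        raise ValueError("no DE results supplied")
    ids = {(r.dataset_id, r.condition) for r in results}
    if len(ids) > 1:
        raise ValueError(f"results mix datasets/conditions: {sorted(ids)}")
    dataset_id, condition = next(iter(ids))

    pvals = np.array([r.p for r in results])
    if bh:
        pvals = multipletests(pvals, method="fdr_bh")[1]
    lfc_cut = np.log2(fc_min)
    features = {
        r.feature_id
        for r, p in zip(results, pvals)
        if abs(r.log2_fc) >= lfc_cut and p < p_max
    }
    fc2 = {
        r.feature_id
        for r, p in zip(results, pvals)
        if r.feature_id in features and abs(r.log2_fc) >= 1.0
    }
    return DEGSet(dataset_id, condition, features, fc2)


def intersect_sets(sets: list[DEGSet | set], min_datasets: int) -> dict[str, int]:
    """Features present in >= min_datasets of the given sets, with multiplicity."""
    if not sets:
        raise ValueError("need at least one set")
    if min_datasets > len(sets):
        raise ValueError(f"min_datasets {min_datasets} exceeds {len(sets)} sets")
    counts: dict[str, int] = {}
    for s in sets:
        members = s.features if isinstance(s, DEGSet) else s
        for f in members:
            counts[f] = counts.get(f, 0) + 1
    return {f: c for f, c in counts.items() if c >= min_datasets}


def write_de_table(results: list[DEResult], degs: DEGSet, path) -> None:
    import pandas as pd

    rows = [
        {
            "feature_id": r.feature_id, "log2_fc": r.log2_fc, "p": r.p,
            "dataset_id": r.dataset_id, "condition": r.condition,
            "deg": int(r.feature_id in degs.features),
            "fc2_flag": int(r.feature_id in degs.fc2_features),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
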