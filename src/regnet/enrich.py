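"""Hypergeometric overlap enrichment between target-gene sets.

For sets A (size a) and B (size b) drawn from a universe of N genes with
overlap k, the point probability is C(a,k)·C(N−a,b−k)/C(N,b) and enrichment
significance is the inclusive upper tail P(K >= k), computed in log space.
Significance stars: * p < 1e-2, ** p < 1e-4, *** p < 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class EnrichmentResult:
    set_a_id: str
    set_b_id: str
    N: int
    a: int
    b: int
    k: int
    p: float
    stars: str

    def __post_init__(self) -> None:
        if self.k > min(self.a, self.b) or self.a > self.N or self.b > self.N:
            raise ValueError("impossible overlap configuration")
        if not 0.0 < self.p <= 1.0 + 1e-12:
            raise ValueError(f"p out of (0, 1]: {self.p}")


def _log_comb(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_point(N: int, a: int, b: int, k: int) -> float:
    """Point mass C(a,k)·C(N−a,b−k)/C(N,b); 0 for impossible configurations."""
    if not (0 <= k <= min(a, b)) or a > N or b > N:
        raise ValueError(f"invalid configuration N={N} a={a} b={b} k={k}")
    if b - k > N - a:
        return 0.0
    log_p = (_log_comb(a, np.array(float(k)))
             + _log_comb(N - a, np.array(float(b - k)))
             - _log_comb(N, np.array(float(b))))
    return float(np.exp(log_p))


def hypergeom_upper_tail(N: int, a: int, b: int, k: int) -> float:
    """Inclusive upper tail P(K >= k) = Σ_{j=k}^{min(a,b)} point(N,a,b,j)."""
    js = np.arange(k, min(a, b) + 1, dtype=float)
    feasible = (b - js) <= (N - a)
    js = js[feasible]
    if js.size == 0:
        return 0.0
    log_terms = (_log_comb(a, js) + _log_comb(N - a, b - js) - _log_comb(N, float(b)))
    m = log_terms.max()
    return float(np.exp(m) * np.exp(log_terms - m).sum())


def stars_for(p: float) -> str:
    if p < 1e-6:
        return "***"
    if p < 1e-4:
        return "**"
    if p < 1e-2:
        return "*"
    return "ns"


def overlap_enrichment(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    set_a_id: str = "A",
    set_b_id: str = "B",
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of the overlap of two gene sets."""
    sa, sb, uni = set(set_a), set(set_b), set(universe)
    for name, s in (("A", sa), ("B", sb)):
        outside = s - uni
        if outside:
            raise ValueError(
                f"set {name} element(s) outside universe: {sorted(outside)[:5]}"
            )
    N, a, b, k = len(uni), len(sa), len(sb), len(sa & sb)
    p = min(hypergeom_upper_tail(N, a, b, k), 1.0)
    return EnrichmentResult(set_a_id, set_b_id, N, a, b, k, p, stars_for(p))


def pairwise_enrichment(
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> dict[tuple[str, str], EnrichmentResult]:
    """Symmetric all-vs-all enrichment; diagonal omitted, p(A,B)=p(B,A)."""
    ids = sorted(sets)
    if len(ids) < 2:
        raise ValueError("need at least 2 sets")
    out: dict[tuple[str, str], EnrichmentResult] = {}
    for i, ai in enumerate(ids):
        for bi in ids[i + 1:]:
            res = overlap_enrichment(sets[ai], sets[bi], universe, ai, bi)
            out[(ai, bi)] = res
            out[(bi, ai)] = EnrichmentResult(
                bi, ai, res.N, res.b, res.a, res.k, res.p, res.stars
            )
    return out


def enrichment_table(results: Mapping[tuple[str, str], EnrichmentResult] | list) -> pd.DataFrame:
    items = results.values() if isinstance(results, Mapping) else results
    seen = set()
    rows = []
    for r in items:
        key = tuple(sorted((r.set_a_id, r.set_b_id)))
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {"set_a": r.set_a_id, "set_b": r.set_b_id, "N": r.N, "a": r.a,
             "b": r.b, "k": r.k, "p": r.p, "stars": r.stars}
        )
    return pd.DataFrame(rows, columns=["set_a", "set_b", "N", "a", "b", "k", "p", "stars"])
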