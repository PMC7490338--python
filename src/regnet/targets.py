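"""Evidence filtering of target catalogs and intersection with co-expression.

miRNA->mRNA catalog records survive if they are experimentally validated or
predicted by at least ``min_methods`` (default 4) of the prediction methods.
lncRNA records come from experimentally supported interaction databases and
bypass the method-count rule; they are filtered only by differential-expression
membership. Catalog support is then intersected with the permutation-stability
selected pairs to yield supported interaction edges with "catalog", "pcc", or
dual support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .de import DEGSet
from .io import TargetCatalog

EDGE_KINDS = {
    ("miRNA", "mRNA"): "miRNA->mRNA",
    ("lncRNA", "miRNA"): "lncRNA->miRNA",
    ("lncRNA", "mRNA"): "lncRNA->mRNA",
    ("TF", "mRNA"): "TF->mRNA",
    ("TF", "lncRNA"): "TF->lncRNA",
}


@dataclass
class SupportedEdge:
    source_id: str
    source_kind: str
    target_id: str
    target_kind: str
    condition_tag: str  # EDN | DN | both
    support: set[str] = field(default_factory=set)  # subset of {catalog, pcc, tfbs}
    validated: bool = False
    n_methods: int = 0
    databases: frozenset[str] = frozenset()
    stability: float | None = None
    median_r: float | None = None
    sign: str | None = None

    def __post_init__(self) -> None:
        if not self.support:
            raise ValueError("an edge needs at least one support element")
        if (self.source_kind, self.target_kind) not in EDGE_KINDS:
            raise ValueError(
                f"no edge kind for {self.source_kind}->{self.target_kind}"
            )

    @property
    def edge_kind(self) -> str:
        return EDGE_KINDS[(self.source_kind, self.target_kind)]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source_id, self.target_id, self.edge_kind)


def filter_mirna_targets(catalog: TargetCatalog, min_methods: int = 4) -> TargetCatalog:
    """Keep miRNA records that are validated or predicted by >= min_methods
    methods; lncRNA records pass through unchanged."""
    return catalog.subset(
        lambda r: r.source_kind != "miRNA"
        or r.validated
        or r.n_methods >= min_methods
    )


def restrict_to_de(
    catalog: TargetCatalog,
    degs: DEGSet | set,
    dems: set,
    sources: set | None = None,
) -> TargetCatalog:
    """Keep records whose target is a DEG (mRNA targets) or a DEM / curated
    miRNA (miRNA targets); optionally restrict to an analysis source list."""
    deg_ids = degs.features if isinstance(degs, DEGSet) else set(degs)
    dem_ids = set(dems)

    def keep(r):
        if sources is not None and r.source_id not in sources:
            return False
        if r.target_kind == "mRNA":
            return r.target_id in deg_ids
        return r.target_id in dem_ids

    return catalog.subset(keep)


def combine_target_and_pcc(
    filtered: TargetCatalog,
    selected_pairs: list[tuple[str, str]],
    condition: str,
    records_by_pair: dict | None = None,
) -> list[SupportedEdge]:
    """Merge catalog support with stability-selected pairs for one condition.

    Catalog-only, pcc-only, and dual-support miRNA->mRNA edges are all
    retained, labelled by their support set. ``records_by_pair`` optionally
    maps (mirna, mrna) to a CorrelationRecord to carry stability/median r onto
    the edge. Non-miRNA catalog records are emitted with catalog support.
    """
    selected = set(selected_pairs)
    edges: list[SupportedEdge] = []
    mirna_pairs_in_catalog = set()
    for r in filtered.records:
        support = {"catalog"}
        stability = median_r = sign = None
        if r.source_kind == "miRNA":
            mirna_pairs_in_catalog.add((r.source_id, r.target_id))
            if (r.source_id, r.target_id) in selected:
                support.add("pcc")
                rec = (records_by_pair or {}).get((r.source_id, r.target_id))
                if rec is not None:
                    stability, median_r, sign = rec.stability, rec.median_r, rec.sign
        edges.append(
            SupportedEdge(
                source_id=r.source_id, source_kind=r.source_kind,
                target_id=r.target_id, target_kind=r.target_kind,
                condition_tag=condition, support=support,
                validated=r.validated, n_methods=r.n_methods,
                databases=r.databases, stability=stability,
                median_r=median_r, sign=sign,
            )
        )
    for mirna_id, mrna_id in selected - mirna_pairs_in_catalog:
        rec = (records_by_pair or {}).get((mirna_id, mrna_id))
        edges.append(
            SupportedEdge(
                source_id=mirna_id, source_kind="miRNA", target_id=mrna_id,
                target_kind="mRNA", condition_tag=condition, support={"pcc"},
                stability=None if rec is None else rec.stability,
                median_r=None if rec is None else rec.median_r,
                sign=None if rec is None else rec.sign,
            )
        )
    return edges


def per_mirna_counts(edges: list[SupportedEdge]) -> pd.DataFrame:
    """Per-miRNA |Target|, |PCC|, |Target ∩ PCC| counts (one condition)."""
    rows = {}
    for e in edges:
        if e.source_kind != "miRNA":
            continue
        row = rows.setdefault(e.source_id, {"n_target": 0, "n_pcc": 0, "n_both": 0})
        if "catalog" in e.support:
            row["n_target"] += 1
        if "pcc" in e.support:
            row["n_pcc"] += 1
        if {"catalog", "pcc"} <= e.support:
            row["n_both"] += 1
    df = pd.DataFrame(
        [{"mirna_id": m, **r} for m, r in sorted(rows.items())],
        columns=["mirna_id", "n_target", "n_pcc", "n_both"],
    )
    return df


def condition_merge(
    edges_edn: list[SupportedEdge], edges_dn: list[SupportedEdge]
) -> list[SupportedEdge]:
    """Tag edges present in both conditions as "both"; keep others as-is.

    Commutative: merging (EDN, DN) equals merging (DN, EDN) up to order.
    Dual-condition edges merge their support sets and keep the stronger
    (max) stability.
    """
    by_key_edn = {e.key: e for e in edges_edn}
    by_key_dn = {e.key: e for e in edges_dn}
    merged: list[SupportedEdge] = []
    for key in sorted(set(by_key_edn) | set(by_key_dn)):
        a, b = by_key_edn.get(key), by_key_dn.get(key)
        if a is not None and b is not None:
            stab = max(
                (s for s in (a.stability, b.stability) if s is not None),
                default=None,
            )
            best = a if (a.stability or -1) >= (b.stability or -1) else b
            merged.append(
                SupportedEdge(
                    source_id=a.source_id, source_kind=a.source_kind,
                    target_id=a.target_id, target_kind=a.target_kind,
                    condition_tag="both", support=a.support | b.support,
                    validated=a.validated or b.validated,
                    n_methods=max(a.n_methods, b.n_methods),
                    databases=a.databases | b.databases,
                    stability=stab, median_r=best.median_r, sign=best.sign,
                )
            )
        else:
            merged.append(a if a is not None else b)
    return merged
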