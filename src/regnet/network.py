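"""Assembly of the multi-layer TF-lncRNA-miRNA-mRNA regulatory network.

Edges come from three sources: catalog+correlation supported miRNA->mRNA
repression, experimentally supported lncRNA->miRNA / lncRNA->mRNA targeting,
and promoter-scan derived TF->gene regulation. mRNAs sharing a pool of >= 2
repressing miRNAs that are all targets of a common lncRNA are flagged as
competing endogenous RNA (ceRNA) candidates: the transcripts compete for the
shared miRNAs, so the lncRNA can de-repress the mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .io import GeneSetCollection
from .targets import EDGE_KINDS, SupportedEdge

_KIND_BY_EDGE = {v: k for k, v in EDGE_KINDS.items()}


def edge_from_attrs(source, source_kind, target, target_kind, edge_kind,
                    condition_tag, support) -> SupportedEdge:
    """Rebuild a SupportedEdge from serialized attributes."""
    if EDGE_KINDS.get((source_kind, target_kind)) != edge_kind:
        raise ValueError(
            f"edge kind {edge_kind!r} inconsistent with {source_kind}->{target_kind}"
        )
    return SupportedEdge(
        source_id=str(source), source_kind=str(source_kind),
        target_id=str(target), target_kind=str(target_kind),
        condition_tag=str(condition_tag), support=set(support) or {"catalog"},
    )


@dataclass
class RegulatoryNetwork:
    nodes: dict[str, str] = field(default_factory=dict)  # id -> kind
    edges: list[SupportedEdge] = field(default_factory=list)
    function_tags: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.key in seen:
                raise ValueError(f"duplicate edge {e.key}")
            seen.add(e.key)
            for nid, kind in ((e.source_id, e.source_kind), (e.target_id, e.target_kind)):
                known = self.nodes.get(nid)
                if known is None:
                    raise ValueError(f"edge endpoint {nid!r} missing from nodes")
                if known != kind:
                    raise ValueError(
                        f"node {nid!r} has kind {known!r} but edge says {kind!r}"
                    )

    @classmethod
    def from_edges(cls, edges: Iterable[SupportedEdge]) -> "RegulatoryNetwork":
        edges = _dedup_edges(edges)
        nodes: dict[str, str] = {}
        for e in edges:
            for nid, kind in ((e.source_id, e.source_kind), (e.target_id, e.target_kind)):
                if nodes.setdefault(nid, kind) != kind:
                    raise ValueError(f"conflicting kinds for node {nid!r}")
        return cls(nodes=nodes, edges=edges)

    def edge_multiset(self) -> list[tuple]:
        return sorted(
            (e.source_id, e.target_id, e.edge_kind, e.condition_tag,
             tuple(sorted(e.support)))
            for e in self.edges
        )


def _dedup_edges(edges: Iterable[SupportedEdge]) -> list[SupportedEdge]:
    """Union duplicate (source, target, kind) edges: merge evidence, keep the
    strongest (max) stability; "both" wins over a single condition tag."""
    merged: dict[tuple, SupportedEdge] = {}
    for e in edges:
        prev = merged.get(e.key)
        if prev is None:
            merged[e.key] = e
            continue
        tag = prev.condition_tag
        if prev.condition_tag != e.condition_tag:
            tag = "both"
        stab = max((s for s in (prev.stability, e.stability) if s is not None),
                   default=None)
        best = prev if (prev.stability or -1) >= (e.stability or -1) else e
        merged[e.key] = SupportedEdge(
            source_id=e.source_id, source_kind=e.source_kind,
            target_id=e.target_id, target_kind=e.target_kind,
            condition_tag=tag, support=prev.support | e.support,
            validated=prev.validated or e.validated,
            n_methods=max(prev.n_methods, e.n_methods),
            databases=prev.databases | e.databases,
            stability=stab, median_r=best.median_r, sign=best.sign,
        )
    return [merged[k] for k in sorted(merged)]


def assemble(
    edge_sets: Iterable[list[SupportedEdge]],
    tf_targets: Mapping[str, set[str]] | None = None,
    function_sets: GeneSetCollection | None = None,
    allowed_tf_targets: set[str] | None = None,
    lncrna_ids: set[str] | None = None,
    condition_tag: str = "both",
    require_dual_mirna_support: bool = True,
) -> RegulatoryNetwork:
    """Deduplicated union of all edge sets plus TF->gene edges.

    By default a miRNA->mRNA edge enters the network only with dual support
    (catalog evidence AND a selected negative correlation); single-support
    edges remain in the per-stage tables but not in the assembled network.
    TF->gene edges are added for every (gene, TFs) entry of ``tf_targets``
    where the gene is in ``allowed_tf_targets`` (typically the DEGs) or in
    ``lncrna_ids`` (giving TF->lncRNA edges when lncRNA promoters were
    scanned). Nodes are tagged with every function set containing them.
    """
    all_edges: list[SupportedEdge] = []
    for es in edge_sets:
        for e in es:
            if (require_dual_mirna_support and e.edge_kind == "miRNA->mRNA"
                    and not {"catalog", "pcc"} <= e.support):
                continue
            all_edges.append(e)
    lncrna_ids = lncrna_ids or set()
    if tf_targets:
        for gene, tfs in sorted(tf_targets.items()):
            if allowed_tf_targets is not None and gene not in allowed_tf_targets \
                    and gene not in lncrna_ids:
                continue
            kind = "lncRNA" if gene in lncrna_ids else "mRNA"
            for tf in sorted(tfs):
                all_edges.append(
                    SupportedEdge(
                        source_id=tf, source_kind="TF", target_id=gene,
                        target_kind=kind, condition_tag=condition_tag,
                        support={"tfbs"},
                    )
                )
    net = RegulatoryNetwork.from_edges(all_edges)
    if function_sets is not None:
        for nid in net.nodes:
            tags = function_sets.sets_containing(nid)
            if tags:
                net.function_tags[nid] = tags
    return net


@dataclass
class CeRNATriple:
    mrna_id: str
    shared_mirnas: frozenset[str]
    lncrnas: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.shared_mirnas) < 2:
            raise ValueError("a ceRNA triple needs >= 2 shared miRNAs")
        if not self.lncrnas:
            raise ValueError("a ceRNA triple needs >= 1 lncRNA")


def find_cernas(
    mirna_mrna: list[SupportedEdge],
    lncrna_mirna: list[SupportedEdge],
    min_shared: int = 2,
    mode: str = "intersection",
) -> list[CeRNATriple]:
    """Detect ceRNA candidates.

    For each mRNA, ``shared_mirnas`` is the set of miRNAs repressing it via
    edges that carry both catalog and negative-correlation (pcc) support. A
    triple is emitted when |shared_mirnas| >= min_shared and the lncRNAs
    targeting those miRNAs are non-empty: with mode "intersection" (default) a
    lncRNA must target every shared miRNA; with "union" it may target any.
    Output order is deterministic (sorted by mRNA id) and independent of input
    edge order.
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    regulators: dict[str, set[str]] = {}
    for e in mirna_mrna:
        if e.source_kind != "miRNA" or e.target_kind != "mRNA":
            continue
        if not {"catalog", "pcc"} <= e.support:
            continue
        if e.sign is not None and e.sign != "negative":
            continue
        regulators.setdefault(e.target_id, set()).add(e.source_id)

    lnc_by_mirna: dict[str, set[str]] = {}
    for e in lncrna_mirna:
        if e.source_kind == "lncRNA" and e.target_kind == "miRNA":
            lnc_by_mirna.setdefault(e.target_id, set()).add(e.source_id)

    triples = []
    for mrna in sorted(regulators):
        mirnas = regulators[mrna]
        if len(mirnas) < min_shared:
            continue
        lnc_sets = [lnc_by_mirna.get(m, set()) for m in mirnas]
        if mode == "intersection":
            lncs = set.intersection(*lnc_sets) if lnc_sets else set()
        else:
            lncs = set.union(*lnc_sets) if lnc_sets else set()
        if lncs:
            triples.append(
                CeRNATriple(mrna, frozenset(mirnas), frozenset(lncs))
            )
    return triples


def summarize(network: RegulatoryNetwork) -> dict[str, pd.DataFrame]:
    """Edge counts per (edge_kind, condition_tag) and per-node degrees."""
    edge_rows = [
        {"edge_kind": e.edge_kind, "condition_tag": e.condition_tag}
        for e in network.edges
    ]
    if edge_rows:
        counts = (
            pd.DataFrame(edge_rows)
            .groupby(["edge_kind", "condition_tag"])
            .size()
            .reset_index(name="n_edges")
            .sort_values(["edge_kind", "condition_tag"])
            .reset_index(drop=True)
        )
    else:
        counts = pd.DataFrame(columns=["edge_kind", "condition_tag", "n_edges"])
    deg: dict[str, dict[str, int]] = {
        n: {"out_degree": 0, "in_degree": 0} for n in network.nodes
    }
    for e in network.edges:
        deg[e.source_id]["out_degree"] += 1
        deg[e.target_id]["in_degree"] += 1
    degrees = pd.DataFrame(
        [{"node": n, "kind": network.nodes[n], **d} for n, d in sorted(deg.items())],
        columns=["node", "kind", "out_degree", "in_degree"],
    )
    return {"edge_counts": counts, "degrees": degrees}


def write_cerna_table(triples: list[CeRNATriple], path) -> None:
    rows = [
        {
            "ceRNA_mRNA": t.mrna_id,
            "shared_miRNAs": ";".join(sorted(t.shared_mirnas)),
            "lncRNAs_targeting_miRNAs": ";".join(sorted(t.lncrnas)),
        }
        for t in triples
    ]
    cols = ["ceRNA_mRNA", "shared_miRNAs", "lncRNAs_targeting_miRNAs"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
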