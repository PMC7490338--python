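"""Shared data model and readers/writers for every external format the pipeline touches.

Formats: expression TSV (features x samples), two-column sample-group TSV,
target-catalog TSV, JASPAR-style PFM text, promoter FASTA (+ optional BED6 TSS
table), per-base conservation TSV, GMT gene sets, and network export as edge
TSV or GraphML.

Conventions
-----------
* Coordinates are 0-based, half-open; the promoter window is
  ``[TSS - upstream, TSS + downstream)`` on the gene's strand.
* Feature ids are case-sensitive and whitespace-stripped; miRNA ids are NOT
  normalized (``miR-21`` and ``miR-21-5p`` are distinct features) — harmonizing
  naming schemes is the caller's job.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

FEATURE_KINDS = ("mRNA", "miRNA", "lncRNA")
CONDITIONS = ("EDN", "DN")
GROUPS = ("case", "control")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A features x samples log2 expression matrix with case/control labels."""

    dataset_id: str
    feature_kind: str
    condition: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]
    log2: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dup = next(f for f in self.feature_ids if self.feature_ids.count(f) > 1)
            raise ValueError(f"duplicate feature id {dup!r} in {self.dataset_id}")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for s in self.sample_ids:
            g = self.groups.get(s)
            if g is None:
                raise ValueError(f"sample {s!r} missing from groups file")
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} for sample {s!r}")
        for g in GROUPS:
            if sum(1 for s in self.sample_ids if self.groups[s] == g) < 2:
                raise ValueError(f"fewer than 2 {g!r} samples in {self.dataset_id}")

    # -- convenience views ---------------------------------------------------

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == "case"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == "control"]

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]

    def group_values(self, feature_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (case, control) value vectors for one feature."""
        r = self.row(feature_id)
        mask = np.array([self.groups[s] == "case" for s in self.sample_ids])
        return r[mask], r[~mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


def read_expression_matrix(
    matrix_path,
    groups_path,
    feature_kind: str,
    condition: str,
    dataset_id: str | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV (first column feature id) and its groups TSV.

    Rows containing any non-numeric cell are dropped with a warning; duplicate
    feature ids, samples without a group label, or group labels outside
    {case, control} are errors.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r} in {matrix_path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} rows with non-numeric cells from {matrix_path}"
        )
        numeric = numeric[~bad]

    gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(gdf.columns):
        raise ValueError(f"groups file {groups_path} needs columns sample_id, group")
    groups = {
        str(r.sample_id).strip(): str(r.group).strip() for r in gdf.itertuples()
    }
    return ExpressionMatrix(
        dataset_id=dataset_id or str(matrix_path),
        feature_kind=feature_kind,
        condition=condition,
        feature_ids=[str(i) for i in numeric.index],
        sample_ids=[str(c).strip() for c in numeric.columns],
        values=numeric.to_numpy(dtype=float),
        groups=groups,
    )


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path, groups_path) -> None:
    matrix.to_frame().rename_axis("feature_id").to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {"sample_id": matrix.sample_ids,
         "group": [matrix.groups[s] for s in matrix.sample_ids]}
    ).to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Target catalogs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetRecord:
    source_id: str
    source_kind: str  # miRNA | lncRNA
    target_id: str
    target_kind: str  # mRNA | miRNA
    validated: bool
    n_methods: int
    databases: frozenset[str]


@dataclass
class TargetCatalog:
    """Typed source->target interaction records with evidence annotations."""

    records: list[TargetRecord] = field(default_factory=list)
    max_methods: int = 11

    def __post_init__(self) -> None:
        for r in self.records:
            if r.source_kind == "miRNA" and r.target_kind != "mRNA":
                raise ValueError(
                    f"miRNA source {r.source_id} may only target mRNA, got {r.target_kind}"
                )
            if r.source_kind not in ("miRNA", "lncRNA"):
                raise ValueError(f"unknown source kind {r.source_kind!r}")
            if r.target_kind not in ("mRNA", "miRNA"):
                raise ValueError(f"unknown target kind {r.target_kind!r}")
            if r.n_methods < 0:
                raise ValueError(f"negative n_methods for {r.source_id}->{r.target_id}")
            if r.n_methods > self.max_methods:
                raise ValueError(
                    f"n_methods {r.n_methods} exceeds declared method count "
                    f"{self.max_methods} for {r.source_id}->{r.target_id}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> set[tuple[str, str]]:
        return {(r.source_id, r.target_id) for r in self.records}

    def subset(self, keep) -> "TargetCatalog":
        return TargetCatalog([r for r in self.records if keep(r)], self.max_methods)


def read_target_table(path, source_kind: str | None = None, max_methods: int = 11) -> TargetCatalog:
    """Read a target TSV, merging duplicate (source, target) rows.

    Merge rule: validated = OR, n_methods = max, databases = union.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source_id", "target_id", "target_kind", "validated", "n_methods", "database"}
    if not required <= set(df.columns):
        raise ValueError(f"target table {path} missing columns {required - set(df.columns)}")
    merged: dict[tuple, dict] = {}
    for r in df.itertuples():
        skind = source_kind or getattr(r, "source_kind", "miRNA")
        n_methods = int(r.n_methods)
        if n_methods < 0:
            raise ValueError(f"negative n_methods in row {r.source_id}->{r.target_id}")
        key = (str(r.source_id).strip(), skind, str(r.target_id).strip(), str(r.target_kind).strip())
        entry = merged.setdefault(
            key, {"validated": False, "n_methods": 0, "databases": set()}
        )
        entry["validated"] = entry["validated"] or str(r.validated).strip() in ("1", "true", "True")
        entry["n_methods"] = max(entry["n_methods"], n_methods)
        entry["databases"].add(str(r.database).strip())
    records = [
        TargetRecord(k[0], k[1], k[2], k[3], v["validated"], v["n_methods"],
                     frozenset(v["databases"]))
        for k, v in merged.items()
    ]
    return TargetCatalog(records, max_methods=max_methods)


def write_target_table(catalog: TargetCatalog, path) -> None:
    rows = [
        {
            "source_id": r.source_id,
            "source_kind": r.source_kind,
            "target_id": r.target_id,
            "target_kind": r.target_kind,
            "validated": int(r.validated),
            "n_methods": r.n_methods,
            "database": ";".join(sorted(r.databases)),
        }
        for r in catalog.records
    ]
    cols = ["source_id", "source_kind", "target_id", "target_kind",
            "validated", "n_methods", "database"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------

ALPHABET = "ACGT"


@dataclass
class Motif:
    motif_id: str
    tf_name: str
    counts: np.ndarray  # 4 x L, rows in A,C,G,T order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"motif {self.motif_id}: counts must be 4 x L")
        if self.counts.shape[1] < 4:
            raise ValueError(f"motif {self.motif_id}: length must be >= 4")
        if (self.counts < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"motif {self.motif_id}: zero column sum")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=0))


@dataclass
class PWMSet:
    motifs: list[Motif] = field(default_factory=list)

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def get(self, motif_id: str) -> Motif:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise KeyError(motif_id)


def read_jaspar_pfm(path) -> PWMSet:
    """Parse JASPAR-style PFM text: ``>motif_id tf_name`` then four labelled
    count rows (``A [ 1 2 ... ]`` bracket dialect or bare ``A 1 2 ...``).

    Row order in the file is irrelevant; counts are stored in A,C,G,T order.
    """
    motifs: list[Motif] = []
    header: str | None = None
    rows: dict[str, list[float]] = {}

    def flush():
        nonlocal header, rows
        if header is None:
            return
        missing = [b for b in ALPHABET if b not in rows]
        if missing:
            raise ValueError(f"motif {header}: missing base row(s) {missing}")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"motif {header}: rows of unequal length")
        parts = header.split(None, 1)
        motif_id = parts[0]
        tf_name = parts[1].strip() if len(parts) > 1 else motif_id
        motifs.append(Motif(motif_id, tf_name, np.array([rows[b] for b in ALPHABET])))
        header, rows = None, {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
            else:
                base, rest = line.split(None, 1)
                base = base.upper()
                if base not in ALPHABET:
                    raise ValueError(f"unexpected row label {base!r}")
                if base in rows:
                    raise ValueError(f"motif {header}: duplicate {base} row")
                rows[base] = [float(x) for x in rest.replace("[", " ").replace("]", " ").split()]
    flush()
    return PWMSet(motifs)


def write_jaspar_pfm(pwms: PWMSet, path) -> None:
    with open(path, "w") as fh:
        for m in pwms:
            fh.write(f">{m.motif_id} {m.tf_name}\n")
            for i, b in enumerate(ALPHABET):
                vals = " ".join(f"{v:g}" for v in m.counts[i])
                fh.write(f"{b} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

@dataclass
class Promoter:
    gene_id: str
    sequence: str  # 5'->3' on the gene's strand
    tss_offset: int
    strand: str = "+"


@dataclass
class PromoterSet:
    promoters: dict[str, Promoter] = field(default_factory=dict)
    conservation: dict[str, np.ndarray] = field(default_factory=dict)
    upstream_bp: int = 2000
    downstream_bp: int = 500

    def __post_init__(self) -> None:
        window = self.upstream_bp + self.downstream_bp
        for p in self.promoters.values():
            if len(p.sequence) != window:
                raise ValueError(
                    f"promoter {p.gene_id}: length {len(p.sequence)} != window {window}"
                )
        for g, track in self.conservation.items():
            if g in self.promoters and len(track) != window:
                raise ValueError(f"conservation track for {g} has wrong length")

    def __len__(self) -> int:
        return len(self.promoters)


def read_promoters(
    fasta_path,
    tss_bed_path=None,
    upstream_bp: int = 2000,
    downstream_bp: int = 500,
) -> PromoterSet:
    """Read promoter windows from FASTA, optionally orienting by a BED6 table.

    Each record must span exactly ``upstream_bp + downstream_bp`` bases and is
    stored 5'->3' on the gene's strand: minus-strand records (per BED column 6)
    are reverse-complemented on input. ``tss_offset`` is always ``upstream_bp``.
    """
    strands: dict[str, str] = {}
    if tss_bed_path is not None:
        bed = pd.read_csv(tss_bed_path, sep="\t", header=None, dtype=str)
        if bed.shape[1] < 6:
            raise ValueError("TSS table must be BED6")
        for r in bed.itertuples(index=False):
            strands[str(r[3]).strip()] = str(r[5]).strip()

    window = upstream_bp + downstream_bp
    promoters: dict[str, Promoter] = {}
    seen = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gene_id = rec.id.strip()
        seen.add(gene_id)
        seq = str(rec.seq).upper()
        if len(seq) < window:
            raise ValueError(f"promoter {gene_id}: sequence shorter than window")
        if len(seq) > window:
            raise ValueError(f"promoter {gene_id}: sequence longer than window")
        strand = strands.get(gene_id, "+")
        if strand not in "+-":
            raise ValueError(f"promoter {gene_id}: bad strand {strand!r}")
        if strand == "-":
            seq = reverse_complement(seq)
        promoters[gene_id] = Promoter(gene_id, seq, upstream_bp, strand)
    missing = set(strands) - seen
    if missing:
        raise ValueError(f"genes in BED absent from FASTA: {sorted(missing)}")
    return PromoterSet(promoters, {}, upstream_bp, downstream_bp)


def read_conservation(path, promoters: PromoterSet) -> PromoterSet:
    """Attach a per-base conservation track (TSV: gene_id, position, score)."""
    df = pd.read_csv(path, sep="\t")
    window = promoters.upstream_bp + promoters.downstream_bp
    for gene_id, sub in df.groupby("gene_id"):
        track = np.zeros(window)
        pos = sub["position"].to_numpy(dtype=int)
        track[pos] = sub["score"].to_numpy(dtype=float)
        promoters.conservation[str(gene_id)] = track
    return promoters


def write_promoters(promoters: PromoterSet, fasta_path, tss_bed_path=None,
                    conservation_path=None) -> None:
    with open(fasta_path, "w") as fh:
        for p in promoters.promoters.values():
            seq = p.sequence if p.strand == "+" else reverse_complement(p.sequence)
            fh.write(f">{p.gene_id}\n{seq}\n")
    if tss_bed_path is not None:
        with open(tss_bed_path, "w") as fh:
            for p in promoters.promoters.values():
                # synthetic coordinates: each promoter on its own contig
                fh.write(
                    f"chr_{p.gene_id}\t{promoters.upstream_bp}\t{promoters.upstream_bp + 1}"
                    f"\t{p.gene_id}\t0\t{p.strand}\n"
                )
    if conservation_path is not None:
        rows = []
        for g, track in promoters.conservation.items():
            for i, v in enumerate(track):
                rows.append((g, i, v))
        pd.DataFrame(rows, columns=["gene_id", "position", "score"]).to_csv(
            conservation_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {sid!r} is empty")

    def genes(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def sets_containing(self, gene_id: str) -> set[str]:
        return {sid for sid, (_, g) in self.sets.items() if gene_id in g}


def read_gmt(path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = (parts[1], frozenset(p for p in parts[2:] if p))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, genes) in collection.sets.items():
            fh.write("\t".join([sid, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

EDGE_TSV_COLUMNS = ["source", "source_kind", "target", "target_kind",
                    "edge_kind", "condition_tag", "evidence"]


def write_network(network, path, format: str = "edge_tsv") -> None:
    """Write a RegulatoryNetwork as edge TSV or GraphML (round-trip safe)."""
    from .network import RegulatoryNetwork  # local import to avoid a cycle

    if not isinstance(network, RegulatoryNetwork):
        raise TypeError("expected a RegulatoryNetwork")
    if format == "edge_tsv":
        rows = [
            {
                "source": e.source_id,
                "source_kind": e.source_kind,
                "target": e.target_id,
                "target_kind": e.target_kind,
                "edge_kind": e.edge_kind,
                "condition_tag": e.condition_tag,
                "evidence": ";".join(sorted(e.support)),
            }
            for e in network.edges
        ]
        pd.DataFrame(rows, columns=EDGE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        g = nx.MultiDiGraph()
        for node_id, kind in sorted(network.nodes.items()):
            tags = sorted(network.function_tags.get(node_id, ()))
            g.add_node(node_id, kind=kind, function_tags=";".join(tags))
        for e in network.edges:
            g.add_edge(
                e.source_id, e.target_id, key=e.edge_kind,
                edge_kind=e.edge_kind, condition_tag=e.condition_tag,
                evidence=";".join(sorted(e.support)),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge_tsv"):
    from .network import RegulatoryNetwork, edge_from_attrs

    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        edges = [
            edge_from_attrs(
                r.source, r.source_kind, r.target, r.target_kind,
                r.edge_kind, r.condition_tag,
                set(str(r.evidence).split(";")) if pd.notna(r.evidence) and r.evidence else set(),
            )
            for r in df.itertuples()
        ]
        return RegulatoryNetwork.from_edges(edges)
    elif format == "graphml":
        g = nx.read_graphml(path)
        kinds = {n: d.get("kind") for n, d in g.nodes(data=True)}
        edges = []
        for u, v, d in g.edges(data=True):
            ev = d.get("evidence", "")
            edges.append(
                edge_from_attrs(
                    u, kinds[u], v, kinds[v], d["edge_kind"], d["condition_tag"],
                    set(ev.split(";")) if ev else set(),
                )
            )
        net = RegulatoryNetwork.from_edges(edges)
        for n, d in g.nodes(data=True):
            tags = d.get("function_tags", "")
            if tags:
                net.function_tags[n] = set(tags.split(";"))
            net.nodes.setdefault(n, d.get("kind"))
        return net
    raise ValueError(f"unknown network format {format!r}")
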