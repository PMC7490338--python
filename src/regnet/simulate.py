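"""Synthetic multi-omics study generator with planted ground truth.

Emulates the structure of an unpaired case/control expression study of a
progressive disease with two contrasts (early = EDN, established = DN):

* three expression matrices with unequal group sizes (defaults: mRNA-EDN
  4 vs 4, mRNA-DN 9 vs 13, miRNA-DN 8 vs 4);
* planted differential expression (log2 shifts in case samples);
* planted miRNA->mRNA repression: miRNA and mRNA matrices are generated from
  a shared latent subject pool per condition, then *disjoint* subject subsets
  are exposed per dataset — exactly the unpaired-cohort situation the
  permutation-stability correlation is designed for, while keeping a
  well-defined true (pooled) correlation. A planted target is
  baseline − beta·(miRNA value) + noise within the same subject;
* target catalogs containing every planted edge (validated) plus 3x decoy
  records (unvalidated, < 4 prediction methods) so the evidence filter is
  exercised; lncRNA->miRNA sponge records and lncRNA->mRNA records;
* promoters carrying planted TF motif instances (random strand) with high
  (0.9) site conservation over a low (0.2) background;
* a ground-truth ledger for recovery scoring.

Everything is reproducible from the seed: one numpy Generator
(PCG64 via ``np.random.default_rng``) consumed in a fixed generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    Motif,
    Promoter,
    PromoterSet,
    PWMSet,
    TargetCatalog,
    TargetRecord,
    reverse_complement,
    write_expression_matrix,
    write_gmt,
    write_jaspar_pfm,
    write_promoters,
    write_target_table,
)

DEFAULT_GROUP_SIZES = {
    "mRNA-EDN": (4, 4),
    "mRNA-DN": (9, 13),
    "miRNA-DN": (8, 4),
}

FUNCTION_CATEGORIES = [
    "apoptosis", "angiogenesis", "inflammation",
    "immune_response", "transcriptional_regulation",
]


@dataclass
class SimulationConfig:
    n_genes: int = 300
    n_mirnas: int = 30
    n_lncrnas: int = 8
    n_tfs: int = 4
    group_sizes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    de_fraction: float = 0.1
    de_log2_effect: float = 1.5
    repression_edges: int = 20
    repression_beta: float = 1.0
    # case shift of repressing miRNAs; with noise_sd 0.3 and beta 1.0 this
    # puts the population pooled correlation of a planted pair near -0.9
    mirna_de_log2_effect: float = 3.0
    sponge_edges: int = 40
    lnc_mrna_edges: int = 20
    motif_plant_rate: float = 0.8
    noise_sd: float = 0.3
    seed: int = 0
    decoy_factor: int = 3
    upstream_bp: int = 2000
    downstream_bp: int = 500
    motif_length: int = 8
    targets_per_tf: int = 8
    n_promoter_background: int = 8

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_lncrnas", "n_tfs",
                     "repression_edges", "sponge_edges", "lnc_mrna_edges"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for f in ("de_fraction", "motif_plant_rate"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")
        for ds, (nc, nl) in self.group_sizes.items():
            if nc < 2 or nl < 2:
                raise ValueError(f"dataset {ds}: each group needs >= 2 samples")


@dataclass
class GroundTruth:
    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    de_mirnas: dict[str, float] = field(default_factory=dict)
    planted_edges: list[dict] = field(default_factory=list)
    planted_sites: list[dict] = field(default_factory=list)

    def edges_of_kind(self, edge_kind: str) -> list[tuple[str, str]]:
        return [(e["source"], e["target"]) for e in self.planted_edges
                if e["edge_kind"] == edge_kind]


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    matrices: dict[str, ExpressionMatrix]
    catalog: TargetCatalog
    pwms: PWMSet
    promoters: PromoterSet
    gene_sets: GeneSetCollection
    truth: GroundTruth
    tf_targets_truth: dict[str, set[str]]
    # subject-level latent tables per condition, for population-correlation
    # checks: {"EDN": (mirna_df, mrna_df, case_mask), ...}
    latent: dict[str, tuple[pd.DataFrame, pd.DataFrame, np.ndarray]]


def _plan_repression(cfg: SimulationConfig, genes, mirnas, rng):
    """Choose planted (miRNA, target) pairs; a fifth of the edge budget goes
    to targets repressed by two miRNAs (ceRNA-style shared pools)."""
    n_edges = cfg.repression_edges
    if n_edges == 0:
        return [], {}, []
    n_shared = min(n_edges // 5, n_edges // 2)
    n_single = n_edges - 2 * n_shared
    n_targets = n_shared + n_single
    if n_targets > cfg.n_genes:
        raise ValueError("not enough genes for the requested repression edges")
    n_rep_mirnas = min(cfg.n_mirnas, max(2, math.ceil(n_edges / 2)))
    rep_mirnas = list(rng.choice(mirnas, n_rep_mirnas, replace=False))
    targets = list(rng.choice(genes, n_targets, replace=False))
    edges = []
    regulators: dict[str, list[str]] = {}
    for t in targets[:n_shared]:
        pair = list(rng.choice(rep_mirnas, 2, replace=False))
        regulators[t] = pair
        edges.extend((m, t) for m in pair)
    for t in targets[n_shared:]:
        m = str(rng.choice(rep_mirnas))
        regulators[t] = [m]
        edges.append((m, t))
    return edges, regulators, rep_mirnas


def _random_pairs(rng, sources, targets, n, forbidden):
    """n distinct (source, target) pairs avoiding ``forbidden``."""
    out = []
    seen = set(forbidden)
    attempts = 0
    while len(out) < n and attempts < 50 * max(n, 1):
        attempts += 1
        pair = (str(rng.choice(sources)), str(rng.choice(targets)))
        if pair in seen:
            continue
        seen.add(pair)
        out.append(pair)
    return out


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    mirnas = [f"miR-s{i:03d}" for i in range(1, cfg.n_mirnas + 1)]
    lncrnas = [f"lnc-s{i:02d}" for i in range(1, cfg.n_lncrnas + 1)]
    tfs = [f"TF{i}" for i in range(1, cfg.n_tfs + 1)]

    # --- planted structure -------------------------------------------------
    rep_edges, regulators, rep_mirnas = _plan_repression(cfg, genes, mirnas, rng)
    planted_targets = set(regulators)

    free_genes = [g for g in genes if g not in planted_targets]
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    n_de = min(n_de, len(free_genes))
    de_gene_ids = list(rng.choice(free_genes, n_de, replace=False)) if n_de else []
    gene_effect = {
        g: float(cfg.de_log2_effect * rng.choice([-1.0, 1.0])) for g in de_gene_ids
    }

    mirna_effect = {m: cfg.mirna_de_log2_effect for m in rep_mirnas}
    other_mirnas = [m for m in mirnas if m not in mirna_effect]
    n_de_mir = min(int(round(cfg.de_fraction * cfg.n_mirnas)), len(other_mirnas))
    for m in (rng.choice(other_mirnas, n_de_mir, replace=False) if n_de_mir else []):
        mirna_effect[str(m)] = float(cfg.de_log2_effect * rng.choice([-1.0, 1.0]))

    mu_mirna = rng.uniform(6.0, 10.0, cfg.n_mirnas)
    mu_gene = rng.uniform(6.0, 12.0, cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    mirna_index = {m: i for i, m in enumerate(mirnas)}

    # --- latent subject pools, disjoint exposure ---------------------------
    def condition_datasets(cond):
        return {ds: sz for ds, sz in cfg.group_sizes.items() if ds.endswith(cond)}

    matrices: dict[str, ExpressionMatrix] = {}
    latent: dict[str, tuple[pd.DataFrame, pd.DataFrame, np.ndarray]] = {}
    for cond in ("EDN", "DN"):
        dsets = condition_datasets(cond)
        if not dsets:
            continue
        n_case = sum(sz[0] for sz in dsets.values())
        n_ctl = sum(sz[1] for sz in dsets.values())
        is_case = np.r_[np.ones(n_case, bool), np.zeros(n_ctl, bool)]
        n_subj = n_case + n_ctl

        x = mu_mirna[:, None] + rng.normal(0, cfg.noise_sd, (cfg.n_mirnas, n_subj))
        for m, eff in mirna_effect.items():
            x[mirna_index[m], is_case] += eff
        y = mu_gene[:, None] + rng.normal(0, cfg.noise_sd, (cfg.n_genes, n_subj))
        for g, eff in gene_effect.items():
            y[gene_index[g], is_case] += eff
        for tgt, regs in regulators.items():
            gi = gene_index[tgt]
            y[gi] = (mu_gene[gi]
                     - cfg.repression_beta * sum(x[mirna_index[m]] for m in regs)
                     + rng.normal(0, cfg.noise_sd, n_subj))

        latent[cond] = (
            pd.DataFrame(x, index=mirnas), pd.DataFrame(y, index=genes), is_case,
        )

        # expose disjoint subject slices per dataset
        case_cursor, ctl_cursor = 0, n_case
        for ds in sorted(dsets):
            nc, nl = dsets[ds]
            cols = list(range(case_cursor, case_cursor + nc)) + \
                   list(range(ctl_cursor, ctl_cursor + nl))
            case_cursor += nc
            ctl_cursor += nl
            kind = "miRNA" if ds.startswith("miRNA") else "mRNA"
            values = (x if kind == "miRNA" else y)[:, cols]
            feats = mirnas if kind == "miRNA" else genes
            sample_ids = [f"{ds}_case{i+1}" for i in range(nc)] + \
                         [f"{ds}_ctl{i+1}" for i in range(nl)]
            groups = {s: ("case" if i < nc else "control")
                      for i, s in enumerate(sample_ids)}
            matrices[ds] = ExpressionMatrix(
                dataset_id=ds, feature_kind=kind, condition=cond,
                feature_ids=list(feats), sample_ids=sample_ids,
                values=values, groups=groups,
            )

    # --- target catalog: planted + decoys + lncRNA layers ------------------
    records: list[TargetRecord] = []
    for m, t in rep_edges:
        records.append(TargetRecord(m, "miRNA", t, "mRNA", True,
                                    int(rng.integers(0, 12)),
                                    frozenset({"synthTarBase"})))
    decoys = _random_pairs(rng, mirnas, genes, cfg.decoy_factor * len(rep_edges),
                           forbidden=set(rep_edges))
    for m, t in decoys:
        records.append(TargetRecord(m, "miRNA", t, "mRNA", False,
                                    int(rng.integers(0, 4)),
                                    frozenset({"synthRecords"})))

    sponge_edges: list[tuple[str, str]] = []
    if cfg.n_lncrnas >= 1 and rep_mirnas:
        # two "hub" lncRNAs sponge every repressing miRNA (ceRNA backbone)
        for lnc in lncrnas[: min(2, cfg.n_lncrnas)]:
            sponge_edges.extend((lnc, m) for m in rep_mirnas)
    extra = max(0, cfg.sponge_edges - len(sponge_edges))
    if cfg.n_lncrnas and cfg.n_mirnas:
        sponge_edges.extend(
            _random_pairs(rng, lncrnas, mirnas, extra, forbidden=set(sponge_edges))
        )
    for lnc, m in sponge_edges:
        records.append(TargetRecord(lnc, "lncRNA", m, "miRNA", True, 0,
                                    frozenset({"synthLncBase"})))

    lnc_gene_pool = list(planted_targets | set(de_gene_ids)) or genes
    lnc_mrna = _random_pairs(rng, lncrnas, sorted(lnc_gene_pool),
                             cfg.lnc_mrna_edges, forbidden=set()) \
        if cfg.n_lncrnas else []
    for lnc, g in lnc_mrna:
        records.append(TargetRecord(lnc, "lncRNA", g, "mRNA", True, 0,
                                    frozenset({"synthNPInter"})))
    catalog = TargetCatalog(records)

    # --- PWMs, promoters, planted sites ------------------------------------
    motifs = []
    for k, tf in enumerate(tfs):
        consensus = rng.integers(0, 4, cfg.motif_length)
        counts = np.full((4, cfg.motif_length), 5.0)
        counts[consensus, np.arange(cfg.motif_length)] = 85.0
        motifs.append(Motif(f"M{k+1:03d}", tf, counts))
    pwms = PWMSet(motifs)

    candidate_targets = sorted(set(de_gene_ids) | planted_targets) or genes
    tf_targets_truth: dict[str, set[str]] = {tf: set() for tf in tfs}
    promoter_genes: set[str] = set()
    for tf in tfs:
        n_t = min(cfg.targets_per_tf, len(candidate_targets))
        chosen = rng.choice(candidate_targets, n_t, replace=False) if n_t else []
        tf_targets_truth[tf] = {str(g) for g in chosen}
        promoter_genes |= tf_targets_truth[tf]
    background_genes = [g for g in genes if g not in promoter_genes]
    n_bg = min(cfg.n_promoter_background, len(background_genes))
    promoter_genes |= {str(g) for g in rng.choice(background_genes, n_bg, replace=False)} \
        if n_bg else set()

    window = cfg.upstream_bp + cfg.downstream_bp
    bases = np.array(list("ACGT"))
    promoters: dict[str, Promoter] = {}
    conservation: dict[str, np.ndarray] = {}
    planted_sites: list[dict] = []
    planted_site_positions: dict[str, list[tuple[int, int]]] = {}
    for g in sorted(promoter_genes):
        seq = "".join(rng.choice(bases, window))
        strand = str(rng.choice(["+", "-"]))
        promoters[g] = Promoter(g, seq, cfg.upstream_bp, strand)
        conservation[g] = np.full(window, 0.2)
        planted_site_positions[g] = []
    for tf, motif in zip(tfs, motifs):
        site_seq = motif.consensus
        for g in sorted(tf_targets_truth[tf]):
            if rng.random() > cfg.motif_plant_rate:
                tf_targets_truth[tf].discard(g)
                continue
            pos = int(rng.integers(0, window - cfg.motif_length + 1))
            on_minus = bool(rng.random() < 0.5)
            planted = reverse_complement(site_seq) if on_minus else site_seq
            p = promoters[g]
            promoters[g] = Promoter(
                g, p.sequence[:pos] + planted + p.sequence[pos + cfg.motif_length:],
                p.tss_offset, p.strand,
            )
            conservation[g][pos:pos + cfg.motif_length] = 0.9
            planted_site_positions[g].append((pos, pos + cfg.motif_length))
            planted_sites.append(
                {"gene_id": g, "motif_id": motif.motif_id, "tf_name": tf,
                 "position": pos, "strand": "-" if on_minus else "+"}
            )
    promoter_set = PromoterSet(promoters, conservation,
                               cfg.upstream_bp, cfg.downstream_bp)

    # --- function gene sets -------------------------------------------------
    assignment = rng.integers(0, len(FUNCTION_CATEGORIES), cfg.n_genes)
    sets = {}
    for ci, cat in enumerate(FUNCTION_CATEGORIES):
        members = frozenset(g for g, a in zip(genes, assignment) if a == ci)
        if members:
            sets[cat] = (f"synthetic {cat} gene set", members)
    gene_sets = GeneSetCollection(sets)

    # --- ground truth -------------------------------------------------------
    truth = GroundTruth(
        de_genes={
            cond: {
                **gene_effect,
                **{t: -cfg.repression_beta * cfg.mirna_de_log2_effect * len(regs)
                   for t, regs in regulators.items()},
            }
            for cond in ("EDN", "DN")
        },
        de_mirnas=dict(mirna_effect),
        planted_edges=(
            [{"source": m, "target": t, "edge_kind": "miRNA->mRNA",
              "beta": cfg.repression_beta} for m, t in rep_edges]
            + [{"source": l, "target": m, "edge_kind": "lncRNA->miRNA", "beta": 0.0}
               for l, m in sponge_edges]
            + [{"source": l, "target": g, "edge_kind": "lncRNA->mRNA", "beta": 0.0}
               for l, g in lnc_mrna]
        ),
        planted_sites=planted_sites,
    )

    return SimulatedStudy(
        config=cfg, matrices=matrices, catalog=catalog, pwms=pwms,
        promoters=promoter_set, gene_sets=gene_sets, truth=truth,
        tf_targets_truth=tf_targets_truth, latent=latent,
    )


# ---------------------------------------------------------------------------
# Study directory export / truth ledger
# ---------------------------------------------------------------------------

def export_truth(truth: GroundTruth, path) -> None:
    """TSV ledger of planted edges/effects/sites for recovery scoring."""
    rows = []
    for cond, effects in truth.de_genes.items():
        for g, eff in sorted(effects.items()):
            rows.append({"record": "de_gene", "condition": cond, "source": g,
                         "target": "", "value": eff})
    for m, eff in sorted(truth.de_mirnas.items()):
        rows.append({"record": "de_mirna", "condition": "DN", "source": m,
                     "target": "", "value": eff})
    for e in truth.planted_edges:
        rows.append({"record": e["edge_kind"], "condition": "both",
                     "source": e["source"], "target": e["target"],
                     "value": e["beta"]})
    for s in truth.planted_sites:
        rows.append({"record": "tfbs", "condition": "both",
                     "source": s["tf_name"], "target": s["gene_id"],
                     "value": s["position"]})
    cols = ["record", "condition", "source", "target", "value"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write a self-contained study directory in the formats the readers use."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for ds, mat in study.matrices.items():
        mpath = out / f"{ds}.expr.tsv"
        gpath = out / f"{ds}.groups.tsv"
        write_expression_matrix(mat, mpath, gpath)
        files[f"{ds}.matrix"] = str(mpath)
        files[f"{ds}.groups"] = str(gpath)
    write_target_table(study.catalog, out / "targets.tsv")
    files["targets"] = str(out / "targets.tsv")
    write_jaspar_pfm(study.pwms, out / "motifs.pfm")
    files["pfm"] = str(out / "motifs.pfm")
    write_promoters(study.promoters, out / "promoters.fasta", out / "tss.bed",
                    out / "conservation.tsv")
    files["promoters"] = str(out / "promoters.fasta")
    files["tss"] = str(out / "tss.bed")
    files["conservation"] = str(out / "conservation.tsv")
    write_gmt(study.gene_sets, out / "function_sets.gmt")
    files["gene_sets"] = str(out / "function_sets.gmt")
    export_truth(study.truth, out / "truth.tsv")
    files["truth"] = str(out / "truth.tsv")
    return files
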