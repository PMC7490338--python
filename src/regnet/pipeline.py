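"""End-to-end pipeline: DE -> permutation co-expression -> target integration
-> TFBS scan -> enrichment -> ceRNA -> network assembly.

Driven by a flat YAML config; every stage writes its TSV output so any stage
can be rerun in isolation, and a JSON manifest records files, row counts, the
seed, a hash of the effective config, and a content hash per output file.
Identical config + seed produces byte-identical outputs and manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexpr, de, enrich, io, network, targets, tfbs
from .simulate import SimulationConfig, simulate_study, write_study

log = logging.getLogger("regnet")


@dataclass
class PipelineConfig:
    # input paths
    mrna_edn_matrix: str | None = None
    mrna_edn_groups: str | None = None
    mrna_dn_matrix: str | None = None
    mrna_dn_groups: str | None = None
    mirna_dn_matrix: str | None = None
    mirna_dn_groups: str | None = None
    targets: str | None = None
    pfm: str | None = None
    promoters: str | None = None
    tss: str | None = None
    conservation: str | None = None
    gene_sets: str | None = None
    dem_list: str | None = None  # optional curated DEM list (one id per line)
    # thresholds
    fc_min: float = 1.5
    p_max: float = 0.05
    alpha: float = 0.01
    stability: float = 0.95
    min_methods: int = 4
    tfbs_p_max: float = 1e-4
    min_cons: float = 0.5
    upstream_bp: int = 2000
    downstream_bp: int = 500
    min_shared: int = 2
    n_runs: int = 1000
    null_samples: int = 100000
    cerna_condition: str = "DN"
    seed: int = 0
    out_dir: str = "regnet_out"

    def validate(self) -> None:
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        for name in ("p_max", "alpha", "stability", "tfbs_p_max", "min_cons"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_shared < 1 or self.min_methods < 0 or self.n_runs < 1:
            raise ValueError("invalid count threshold")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _count_rows(path: Path) -> int:
    with open(path, "rb") as fh:
        return max(0, sum(1 for _ in fh) - 1)  # minus header


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                      "files": {}}

    def register(name: str, path: Path) -> None:
        manifest["files"][name] = {
            "path": str(path), "rows": _count_rows(path), "sha256": _sha256(path),
        }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                raise StageError(name, str(exc)) from exc
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return result
        return wrap

    # -- load inputs ---------------------------------------------------------
    def _load():
        mats = {}
        specs = [
            ("mRNA-EDN", config.mrna_edn_matrix, config.mrna_edn_groups, "mRNA", "EDN"),
            ("mRNA-DN", config.mrna_dn_matrix, config.mrna_dn_groups, "mRNA", "DN"),
            ("miRNA-DN", config.mirna_dn_matrix, config.mirna_dn_groups, "miRNA", "DN"),
        ]
        for ds, mp, gp, kind, cond in specs:
            if mp is None:
                continue
            if not Path(mp).exists() or gp is None or not Path(gp).exists():
                raise ValueError(f"missing matrix/groups file for {ds}")
            mats[ds] = io.read_expression_matrix(mp, gp, kind, cond, dataset_id=ds)
        if config.targets is None or not Path(config.targets).exists():
            raise ValueError("missing target catalog")
        catalog = io.read_target_table(config.targets)
        return mats, catalog

    mats, catalog = stage("load")(_load)

    # -- differential expression --------------------------------------------
    degs: dict[str, de.DEGSet] = {}
    dems: set[str] = set()

    def _de():
        for ds, mat in sorted(mats.items()):
            results = de.moderated_t_test(mat)
            called = de.call_degs(results, config.fc_min, config.p_max)
            degs[ds] = called
            de.write_de_table(results, called, out / f"de.{ds}.tsv")
            register(f"de.{ds}", out / f"de.{ds}.tsv")
            if mat.feature_kind == "miRNA":
                dems.update(called.features)
        if config.dem_list and Path(config.dem_list).exists():
            with open(config.dem_list) as fh:
                dems.update(line.strip() for line in fh if line.strip())

    stage("de")(_de)

    # -- permutation co-expression -------------------------------------------
    records_by_cond: dict[str, list[coexpr.CorrelationRecord]] = {}

    def _coexpr():
        mirna_mat = mats.get("miRNA-DN")
        if mirna_mat is None:
            return
        analysis_mirnas = sorted(dems & set(mirna_mat.feature_ids)) or \
            sorted(mirna_mat.feature_ids)
        for ds, cond in (("mRNA-EDN", "EDN"), ("mRNA-DN", "DN")):
            if ds not in mats:
                continue
            genes = sorted(degs[ds].features)
            pairs = [(m, g) for m in analysis_mirnas for g in genes]
            recs = coexpr.correlate_matrices(
                mirna_mat, mats[ds], pairs, n_runs=config.n_runs,
                alpha=config.alpha, seed=config.seed, condition=cond,
            )
            records_by_cond[cond] = recs
            coexpr.write_correlation_table(
                recs, out / f"coexpr.{cond}.tsv", config.stability, True,
            )
            register(f"coexpr.{cond}", out / f"coexpr.{cond}.tsv")

    stage("coexpr")(_coexpr)

    # -- target integration ---------------------------------------------------
    edges_by_cond: dict[str, list[targets.SupportedEdge]] = {}

    def _targets():
        filtered = targets.filter_mirna_targets(catalog, config.min_methods)
        for cond, recs in sorted(records_by_cond.items()):
            ds = f"mRNA-{cond}"
            restricted = targets.restrict_to_de(filtered, degs[ds], dems)
            selected = coexpr.select_pairs(recs, config.stability, True)
            by_pair = {(r.mirna_id, r.mrna_id): r for r in recs}
            edges = targets.combine_target_and_pcc(restricted, selected, cond, by_pair)
            edges_by_cond[cond] = edges
            counts = targets.per_mirna_counts(edges)
            counts.insert(1, "condition", cond)
            counts.to_csv(out / f"targets.{cond}.tsv", sep="\t", index=False)
            register(f"targets.{cond}", out / f"targets.{cond}.tsv")

    stage("targets")(_targets)

    # -- TFBS scanning --------------------------------------------------------
    tf_map: dict[str, set[str]] = {}

    def _tfbs():
        if config.pfm is None:
            return
        if not Path(config.pfm).exists():
            raise ValueError(f"PFM file {config.pfm} not found")
        pwms = io.read_jaspar_pfm(config.pfm)
        promoters = io.read_promoters(config.promoters, config.tss,
                                      config.upstream_bp, config.downstream_bp)
        if config.conservation and Path(config.conservation).exists():
            io.read_conservation(config.conservation, promoters)
        sites = tfbs.scan_all(pwms, promoters, n_null_samples=config.null_samples,
                              seed=config.seed)
        sites = tfbs.conservation_filter(sites, promoters, config.min_cons)
        tfbs.write_sites_table(sites, out / "tfbs.sites.tsv")
        register("tfbs.sites", out / "tfbs.sites.tsv")
        full, _report = tfbs.assign_tf_targets(sites, config.tfbs_p_max)
        tf_map.update(full)

    stage("tfbs")(_tfbs)

    # -- enrichment -----------------------------------------------------------
    def _enrich():
        tf_sets = {}
        for gene, tfset in tf_map.items():
            for tf in tfset:
                tf_sets.setdefault(tf, set()).add(gene)
        lnc_sets: dict[str, set] = {}
        for edges in edges_by_cond.values():
            for e in edges:
                if e.source_kind == "lncRNA" and e.target_kind == "mRNA":
                    lnc_sets.setdefault(e.source_id, set()).add(e.target_id)
        universe = set()
        for ds in ("mRNA-EDN", "mRNA-DN"):
            if ds in mats:
                universe |= set(mats[ds].feature_ids)
        frames = []
        for label, sets in (("TF", tf_sets), ("lncRNA", lnc_sets)):
            if len(sets) >= 2:
                res = enrich.pairwise_enrichment(sets, universe)
                tab = enrich.enrichment_table(res)
                tab.insert(0, "set_kind", label)
                frames.append(tab)
        cols = ["set_kind", "set_a", "set_b", "N", "a", "b", "k", "p", "stars"]
        tab = pd.concat(frames, ignore_index=True) if frames \
            else pd.DataFrame(columns=cols)
        tab.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        register("enrichment", out / "enrichment.tsv")

    stage("enrich")(_enrich)

    # -- ceRNA + assembly -----------------------------------------------------
    def _cerna_and_assemble():
        # a miRNA->mRNA edge must be dual-supported *within* a condition to
        # count there; "both" then means dual support under both contrasts
        def dual(edges):
            return [e for e in edges if e.edge_kind != "miRNA->mRNA"
                    or {"catalog", "pcc"} <= e.support]

        merged = targets.condition_merge(
            dual(edges_by_cond.get("EDN", [])), dual(edges_by_cond.get("DN", [])),
        )
        cond = config.cerna_condition
        cerna_input = merged if cond == "both" else [
            e for e in merged if e.condition_tag in (cond, "both")
        ]
        lnc_mirna = [e for e in merged
                     if e.source_kind == "lncRNA" and e.target_kind == "miRNA"]
        triples = network.find_cernas(cerna_input, lnc_mirna, config.min_shared)
        network.write_cerna_table(triples, out / "cerna.tsv")
        register("cerna", out / "cerna.tsv")

        gene_sets = io.read_gmt(config.gene_sets) \
            if config.gene_sets and Path(config.gene_sets).exists() else None
        all_degs = set()
        for ds in ("mRNA-EDN", "mRNA-DN"):
            if ds in degs:
                all_degs |= degs[ds].features
        net = network.assemble(
            [merged], tf_map, gene_sets, allowed_tf_targets=all_degs,
        )
        io.write_network(net, out / "network.edges.tsv", "edge_tsv")
        register("network.edges", out / "network.edges.tsv")
        io.write_network(net, out / "network.graphml", "graphml")
        register("network.graphml", out / "network.graphml")
        summary = network.summarize(net)
        summary["edge_counts"].to_csv(out / "network.summary.tsv", sep="\t", index=False)
        register("network.summary", out / "network.summary.tsv")
        return net, triples

    net, triples = stage("assemble")(_cerna_and_assemble)

    manifest["n_edges"] = len(net.edges)
    manifest["n_cerna_triples"] = len(triples)
    manifest_blob = json.dumps(manifest, sort_keys=True, indent=1)
    (out / "manifest.json").write_text(manifest_blob)
    manifest["manifest_hash"] = hashlib.sha256(manifest_blob.encode()).hexdigest()
    return manifest


def demo(seed: int = 0, out_dir: str = "regnet_demo",
         sim_config: SimulationConfig | None = None,
         n_runs: int = 1000, null_samples: int = 20000) -> dict:
    """Generate a small synthetic study and run the full pipeline on it.

    Returns the manifest, augmented with a recovery report against the
    planted ground truth.
    """
    out = Path(out_dir)
    cfg = sim_config or SimulationConfig(seed=seed)
    study = simulate_study(cfg)
    files = write_study(study, out / "study")
    pconfig = PipelineConfig(
        mrna_edn_matrix=files["mRNA-EDN.matrix"], mrna_edn_groups=files["mRNA-EDN.groups"],
        mrna_dn_matrix=files["mRNA-DN.matrix"], mrna_dn_groups=files["mRNA-DN.groups"],
        mirna_dn_matrix=files["miRNA-DN.matrix"], mirna_dn_groups=files["miRNA-DN.groups"],
        targets=files["targets"], pfm=files["pfm"], promoters=files["promoters"],
        tss=files["tss"], conservation=files["conservation"],
        gene_sets=files["gene_sets"], seed=seed, out_dir=str(out / "results"),
        n_runs=n_runs, null_samples=null_samples,
        upstream_bp=cfg.upstream_bp, downstream_bp=cfg.downstream_bp,
    )
    manifest = run_pipeline(pconfig)
    manifest["recovery"] = _recovery_report(study, Path(pconfig.out_dir))
    (out / "results" / "recovery.json").write_text(
        json.dumps(manifest["recovery"], sort_keys=True, indent=1)
    )
    return manifest


def _recovery_report(study, results_dir: Path) -> dict:
    """Score pipeline output against the planted truth of a simulated study."""
    planted = set(study.truth.edges_of_kind("miRNA->mRNA"))
    edges = pd.read_csv(results_dir / "network.edges.tsv", sep="\t")
    mm = edges[edges["edge_kind"] == "miRNA->mRNA"]
    dual = mm[mm["evidence"].str.contains("catalog")
              & mm["evidence"].str.contains("pcc")]
    found = {(r.source, r.target) for r in dual.itertuples()}
    recovered = planted & found
    return {
        "planted_repression_edges": len(planted),
        "recovered_dual_support": len(recovered),
        "recovery_rate": (len(recovered) / len(planted)) if planted else None,
        "false_dual_support": len(found - planted),
    }
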