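"""End-to-end pipeline orchestration.

Runs the stages synth -> preprocess -> diffexpr -> wgcn -> genesets ->
ppin -> ffl against one output directory, writing plain-text artifacts and
a JSON manifest per stage (parameters, input checksums, row counts).
Re-running with unchanged inputs skips completed stages; every source of
randomness derives from the single configured seed, so identical configs
reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, ffl, genesets, ppin_enrich, preprocess, synth, wgcn
from .data import (
    read_expression_tsv, read_gmt, write_expression_tsv, write_gmt,
    write_samples_tsv,
)

log = logging.getLogger("atheronet")

ALL_STAGES = ("synth", "preprocess", "diffexpr", "wgcn", "genesets", "ppin", "ffl")


@dataclass
class RunConfig:
    """One ledger of every stage parameter, defaulting to the study
    thresholds: 50% low-variance filter, BH p < 0.05 with |log2FC| > 0.1,
    scale-free fit target R^2 = 0.8, eigengene merge height 0.25
    (correlation 0.75), PPI combined score > 0.4, top-10 term reporting.
    """

    outdir: str = "runs/demo"
    seed: int = 7
    stages: tuple[str, ...] = ALL_STAGES
    # synthetic-cohort parameters (used when no external inputs are given)
    synth: synth.SynthConfig = field(default_factory=lambda: synth.SynthConfig(
        n_genes=2000, n_samples_per_group=30, n_batches=2, frac_de=0.15,
        de_log2fc=2.0, n_modules=5, module_size=40, module_cor=0.7,
        noise_sd=1.0, batch_sd=0.3, n_tfs=12, n_mirnas=12,
        n_planted_ffls=30, edge_noise_frac=0.0, de_in_modules=True,
    ))
    n_vc_genes: int = 50
    # external input paths (optional; override the synth stage outputs)
    expr_path: str | None = None
    samples_path: str | None = None
    gmt_path: str | None = None
    ppi_path: str | None = None
    mirna_mrna_path: str | None = None
    tf_mrna_path: str | None = None
    mirna_tf_path: str | None = None
    # stage parameters
    lv_fraction: float = 0.5
    outlier_z_cut: float = -2.5
    p_cut: float = 0.05
    fc_cut: float = 0.1
    top_k_genes: int = 10
    min_abs_cor: float = 0.3
    r2_target: float = 0.8
    min_module_size: int = 30
    merge_height: float = 0.25
    score_cut: float = 0.4
    top_k_terms: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_cfg = synth.SynthConfig(**raw.pop("synth", {}))
        cfg = cls(**{k: v for k, v in raw.items() if k != "synth"}, synth=synth_cfg)
        if "seed" in raw:
            cfg.synth = synth.SynthConfig(
                **{**asdict(synth_cfg), "seed": int(raw["seed"])}
            )
        cfg.stages = tuple(cfg.stages)
        return cfg

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # the synthetic cohort inherits the run seed
        if self.synth.seed != self.seed:
            self.synth = synth.SynthConfig(
                **{**asdict(self.synth), "seed": self.seed}
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _checksums(paths: list[Path]) -> dict[str, str]:
    return {p.name: _sha256(p) for p in paths if p.exists()}


class PipelineError(RuntimeError):
    pass


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order, returning the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())

    def stage_done(name: str, inputs: list[Path], outputs: list[Path]) -> bool:
        entry = manifest.get(name)
        if not entry:
            return False
        if entry.get("inputs") != _checksums(inputs):
            return False
        return all(p.exists() for p in outputs)

    def record(name: str, inputs: list[Path], outputs: list[Path],
               params: dict, counts: dict) -> None:
        manifest[name] = {
            "inputs": _checksums(inputs),
            "outputs": _checksums(outputs),
            "params": params,
            "counts": counts,
        }
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        log.info("stage %s: %s", name, counts)

    # --- synth --------------------------------------------------------------
    expr_p = Path(cfg.expr_path) if cfg.expr_path else out / "expression.tsv"
    samp_p = Path(cfg.samples_path) if cfg.samples_path else out / "samples.tsv"
    gmt_p = Path(cfg.gmt_path) if cfg.gmt_path else out / "genesets.gmt"
    ppi_p = Path(cfg.ppi_path) if cfg.ppi_path else out / "ppi_edges.tsv"
    mm_p = Path(cfg.mirna_mrna_path) if cfg.mirna_mrna_path else out / "mirna_mrna.tsv"
    tm_p = Path(cfg.tf_mrna_path) if cfg.tf_mrna_path else out / "tf_mrna.tsv"
    mt_p = Path(cfg.mirna_tf_path) if cfg.mirna_tf_path else out / "mirna_tf.tsv"

    if "synth" in cfg.stages and not cfg.expr_path:
        outputs = [expr_p, samp_p, gmt_p, ppi_p, mm_p, tm_p, mt_p,
                   out / "truth.json"]
        if not stage_done("synth", [], outputs):
            ds, truth = synth.gen_expression(cfg.synth)
            write_expression_tsv(ds, expr_p)
            write_samples_tsv(ds, samp_p)
            # planted calcification core: DE module genes
            vc_core = sorted(truth.de_genes)[: cfg.n_vc_genes]
            lib_sets = synth.gen_geneset_library(
                cfg.synth, set(vc_core), universe=ds.gene_ids
            )
            write_gmt(lib_sets, gmt_p)
            ppi = synth.gen_ppi_edges(cfg.synth, set(vc_core),
                                      universe=ds.gene_ids, target_density=0.5)
            ppi.to_csv(ppi_p, sep="\t", index=False)
            tables, itruth = synth.gen_interactions(cfg.synth, mrna_pool=vc_core)
            synth.write_interaction_tsvs(tables, out)
            truth.planted_ffls = itruth.planted_ffls
            truth.to_json(out / "truth.json")
            record("synth", [], outputs, asdict(cfg.synth),
                   {"genes": ds.n_genes, "samples": ds.n_samples,
                    "planted_de": len(truth.de_genes),
                    "planted_ffls": len(truth.planted_ffls)})

    # --- preprocess ----------------------------------------------------------
    pre_expr = out / "preprocessed.tsv"
    pre_samp = out / "preprocessed_samples.tsv"
    removed_p = out / "removed_samples.tsv"
    if "preprocess" in cfg.stages:
        inputs = [expr_p, samp_p]
        outputs = [pre_expr, pre_samp, removed_p]
        if not stage_done("preprocess", inputs, outputs):
            if not expr_p.exists():
                raise PipelineError("preprocess: missing expression input "
                                    f"{expr_p} (enable the synth stage or "
                                    "pass expr_path)")
            ds = read_expression_tsv(expr_p, samp_p)
            ds, report = preprocess.preprocess(
                ds, lv_fraction=cfg.lv_fraction, z_cut=cfg.outlier_z_cut
            )
            write_expression_tsv(ds, pre_expr)
            write_samples_tsv(ds, pre_samp)
            pd.DataFrame({"sample": report.removed}).to_csv(
                removed_p, sep="\t", index=False
            )
            record("preprocess", inputs, outputs,
                   {"lv_fraction": cfg.lv_fraction, "z_cut": cfg.outlier_z_cut},
                   {"genes": ds.n_genes, "samples": ds.n_samples,
                    "removed_samples": len(report.removed)})

    # --- diffexpr ------------------------------------------------------------
    de_p = out / "differential_expression.tsv"
    if "diffexpr" in cfg.stages:
        inputs = [pre_expr, pre_samp]
        outputs = [de_p]
        if not stage_done("diffexpr", inputs, outputs):
            if not pre_expr.exists():
                raise PipelineError("diffexpr: missing preprocessed input; "
                                    "enable the preprocess stage")
            ds = read_expression_tsv(pre_expr, pre_samp)
            res = diffexpr.moderated_t_test(ds)
            res = diffexpr.screen_degs(res, p_cut=cfg.p_cut, fc_cut=cfg.fc_cut)
            res.table.to_csv(de_p, sep="\t", index_label="gene",
                             float_format="%.10g")
            record("diffexpr", inputs, outputs,
                   {"p_cut": cfg.p_cut, "fc_cut": cfg.fc_cut,
                    "d0": res.d0, "s0_sq": res.s0_sq},
                   {"genes": len(res.table), "up": res.n_up(),
                    "down": res.n_down()})

    # --- wgcn ----------------------------------------------------------------
    modules_p = out / "modules.tsv"
    sft_p = out / "sft_fit.tsv"
    me_p = out / "eigengenes.tsv"
    if "wgcn" in cfg.stages:
        inputs = [pre_expr, pre_samp, de_p]
        outputs = [modules_p, sft_p, me_p]
        if not stage_done("wgcn", inputs, outputs):
            if not de_p.exists():
                raise PipelineError("wgcn: missing differential-expression "
                                    "input; enable the diffexpr stage")
            ds = read_expression_tsv(pre_expr, pre_samp)
            de_tab = pd.read_csv(de_p, sep="\t", index_col="gene")
            degs = list(de_tab.index[de_tab["status"] != "ns"])
            ds = ds.subset_genes([g for g in ds.gene_ids if g in set(degs)])
            ds, noisy = wgcn.filter_noisy_genes(ds, min_abs_cor=cfg.min_abs_cor)
            wcfg = wgcn.WGCNConfig(
                r2_target=cfg.r2_target,
                min_module_size=cfg.min_module_size,
                merge_height=cfg.merge_height,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sft = wgcn.pick_soft_threshold(ds, wcfg)
            adj = wgcn.adjacency_matrix(ds, sft.beta)
            tom = wgcn.tom_similarity(adj)
            part = wgcn.detect_modules(tom, ds.gene_ids, wcfg)
            if part.modules():
                eig = wgcn.module_eigengenes(ds, part)
                part, eig = wgcn.merge_close_modules(
                    ds, part, eig, merge_height=cfg.merge_height
                )
                eig.profiles.to_csv(me_p, sep="\t", index_label="sample",
                                    float_format="%.10g")
            else:
                pd.DataFrame().to_csv(me_p, sep="\t")
            sft.table.to_csv(sft_p, sep="\t", index=False, float_format="%.10g")
            pd.DataFrame(
                {"gene": list(part.module_of),
                 "module": list(part.module_of.values())}
            ).to_csv(modules_p, sep="\t", index=False)
            record("wgcn", inputs, outputs,
                   {"beta": sft.beta, "r2": sft.r2,
                    "merge_height": cfg.merge_height,
                    "min_module_size": cfg.min_module_size,
                    "n_noisy_dropped": len(noisy)},
                   {"degs_used": ds.n_genes,
                    "modules": len(part.modules()),
                    "retained": len(wgcn.drop_unassigned(part))})

    # --- genesets ------------------------------------------------------------
    cass_p = out / "cass_genes.tsv"
    venn_p = out / "venn_counts.json"
    if "genesets" in cfg.stages:
        inputs = [modules_p, gmt_p]
        outputs = [cass_p, venn_p]
        if not stage_done("genesets", inputs, outputs):
            if not modules_p.exists():
                raise PipelineError("genesets: missing module assignments; "
                                    "enable the wgcn stage")
            mods = pd.read_csv(modules_p, sep="\t")
            retained = set(mods.loc[mods["module"] != wgcn.GREY, "gene"])
            lib = genesets.GeneSetLibrary.from_dict(read_gmt(gmt_p))
            vc = genesets.compile_vc_genes(lib)
            cass, venn = genesets.intersect_cass(retained, vc)
            pd.DataFrame({"gene": sorted(cass)}).to_csv(cass_p, sep="\t",
                                                        index=False)
            venn_p.write_text(json.dumps(
                {"degs_only": venn.degs_only, "vc_only": venn.vc_only,
                 "both": venn.both}, indent=1))
            record("genesets", inputs, outputs, {"n_vc": len(vc)},
                   {"cass": len(cass)})

    # --- ppin ----------------------------------------------------------------
    ppin_nodes_p = out / "ppin_degrees.tsv"
    ppin_sif_p = out / "ppin.sif"
    enrich_p = out / "enrichment.tsv"
    if "ppin" in cfg.stages:
        inputs = [cass_p, ppi_p, gmt_p]
        outputs = [ppin_nodes_p, ppin_sif_p, enrich_p]
        if not stage_done("ppin", inputs, outputs):
            if not cass_p.exists():
                raise PipelineError("ppin: missing CASS gene list; enable "
                                    "the genesets stage")
            cass = set(pd.read_csv(cass_p, sep="\t")["gene"].astype(str))
            net = ppin_enrich.load_ppi_edges(ppi_p, score_cut=cfg.score_cut)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub = ppin_enrich.induced_subgraph(net, cass)
                deg = ppin_enrich.node_degrees(sub)
                lib = genesets.GeneSetLibrary.from_dict(read_gmt(gmt_p))
                rows = ppin_enrich.fisher_enrichment(set(sub.nodes), lib)
                top = ppin_enrich.top_k_terms(rows, k=cfg.top_k_terms)
            deg.to_csv(ppin_nodes_p, sep="\t", index=False)
            with open(ppin_sif_p, "w") as fh:
                for a, b in sorted(map(sorted, sub.edges)):
                    fh.write(f"{a}\tpp\t{b}\n")
            ppin_enrich.enrichment_table(top).to_csv(
                enrich_p, sep="\t", index=False, float_format="%.10g"
            )
            record("ppin", inputs, outputs,
                   {"score_cut": cfg.score_cut, "top_k": cfg.top_k_terms},
                   {"nodes": sub.number_of_nodes(),
                    "edges": sub.number_of_edges(),
                    "top_terms": len(top)})

    # --- ffl -----------------------------------------------------------------
    triples_p = out / "ffl_triples.tsv"
    cent_p = out / "ffl_centralities.tsv"
    motif_p = out / "ffl_motif.json"
    if "ffl" in cfg.stages:
        inputs = [ppin_nodes_p, de_p, mm_p, tm_p, mt_p]
        outputs = [triples_p, cent_p, motif_p]
        if not stage_done("ffl", inputs, outputs):
            if not ppin_nodes_p.exists():
                raise PipelineError("ffl: missing PPI degree table; enable "
                                    "the ppin stage")
            ppin_genes = set(
                pd.read_csv(ppin_nodes_p, sep="\t")["gene"].astype(str)
            )
            tables = synth.read_interaction_tsvs(mm_p, tm_p, mt_p)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tables = ffl.compile_pairs(tables, ppin_genes) if ppin_genes \
                    else tables
            triples = ffl.enumerate_ffls(tables)
            de_tab = pd.read_csv(de_p, sep="\t", index_col="gene")
            status = de_tab["status"].to_dict()
            graph = ffl.build_ffl_graph(triples, mrna_status=status)
            pd.DataFrame(
                [(t.tf, t.mirna, t.mrna, t.loop_type) for t in triples],
                columns=["tf", "mirna", "mrna", "loop_type"],
            ).to_csv(triples_p, sep="\t", index=False)
            if triples:
                cent = ffl.centralities(graph)
                cent.to_csv(cent_p, sep="\t", index_label="node",
                            float_format="%.10g")
                motif, fallback = ffl.highest_order_motif(graph, cent)
                stats_df = ffl.class_degree_stats(graph)
                motif_payload = {
                    "tf": motif.tf, "mirna": motif.mirna, "mrna": motif.mrna,
                    "loop_type": motif.loop_type, "fallback": fallback,
                    "n_nodes": graph.graph.number_of_nodes(),
                    "n_edges": graph.graph.number_of_edges(),
                    "class_degree_stats": stats_df.to_dict(orient="records"),
                }
            else:
                pd.DataFrame().to_csv(cent_p, sep="\t")
                motif_payload = {"warning": "no FFL triples enumerated"}
            motif_p.write_text(json.dumps(motif_payload, indent=1,
                                          sort_keys=True))
            record("ffl", inputs, outputs, {},
                   {"triples": len(triples),
                    "nodes": graph.graph.number_of_nodes(),
                    "edges": graph.graph.number_of_edges()})

    return manifest
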