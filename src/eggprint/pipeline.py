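"""Full-chain orchestration: simulate/ingest -> normalize -> screen ->
nested ANN -> duplicate collapse -> reverse residualization -> MMC ->
relevance networks -> report.

One master seed governs every stochastic stage through derived sub-seeds,
so a config + seed pair reproduces the run report bit for bit. Every
artifact written carries a provenance comment naming the tool version, seed
and config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from eggprint import dataio
from eggprint.annmodel import AnnConfig, compare_probe_sets, genotype_variance, nested_subset_run
from eggprint.fingerprint import clustergram, mmc_cluster, reverse_residualize
from eggprint.networks import build_relevance_networks, write_graphml, write_sif
from eggprint.preprocess import probe_screen, vsn_normalize
from eggprint.spawnstats import classify_spawns, comparison_frame, group_comparison
from eggprint.synthetic import SimulationConfig, generate_dataset

logger = logging.getLogger("eggprint")

DEFAULT_CONFIG: dict = {
    "simulation": {},  # SimulationConfig overrides; or use "data": {paths}
    "screen": {"mode": "binary", "p_cutoff": 0.10, "target": "pct_4h_viable"},
    "ann": {"sizes": [1469, 250, 100], "n_models": 20, "hidden_units": 3,
            "l2_penalty": 1.0, "max_iterations": 2000},
    "mmc": {"sharpness_max": 30, "correlation": "pearson"},
    "network": {"threshold": 0.6, "min_component_size": 5},
    "target": "pct_4h_viable",
    "seed": 0,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, completed: list[str]):
        super().__init__(f"stage {stage!r} failed: {message}; completed: {completed}")
        self.stage = stage
        self.completed = completed


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _sub_seed(master: int, label: str) -> int:
    h = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") & 0x7FFFFFFF


def run_pipeline(cfg: dict, outdir: str | Path, seed: int | None = None,
                 write_artifacts: bool = True) -> dict:
    """Execute the full analysis chain; returns (and writes) the run report.

    ``seed`` overrides ``cfg['seed']``. A stage failure raises
    :class:`PipelineError` naming the stage and the artifacts of all
    completed stages.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = json.loads(json.dumps(cfg))  # deep copy, normalize types
    if seed is not None:
        cfg["seed"] = int(seed)
    master = int(cfg.get("seed", 0))
    chash = config_hash(cfg)
    completed: list[str] = []
    report: dict = {"config_hash": chash, "seed": master, "stages": {}}
    target = cfg.get("target", "pct_4h_viable")

    def _stage(name):
        def deco(fn):
            try:
                logger.info("stage %s", name)
                out = fn()
            except Exception as exc:  # noqa: BLE001 - repackaged with context
                raise PipelineError(name, str(exc), completed) from exc
            completed.append(name)
            return out
        return deco

    # --- ingest or simulate -------------------------------------------------
    @_stage("ingest")
    def study():
        if "data" in cfg and cfg["data"]:
            d = cfg["data"]
            expr = dataio.read_expression(d["expression"], d.get("format", "tsv"))
            pheno = dataio.read_phenotype(d["phenotype"])
            ann = dataio.read_annotation(d["annotation"])
            geno = dataio.read_genotype(d["genotype"]) if d.get("genotype") else None
            return expr, pheno, ann, geno, None
        sim = SimulationConfig(**cfg.get("simulation", {}),
                               seed=_sub_seed(master, "simulate"))
        ds = generate_dataset(sim)
        if write_artifacts:
            dataio.write_expression(ds.expression, outdir / "expression_raw.tsv", seed=master)
            dataio.write_phenotype(ds.phenotype, outdir / "phenotype.csv", seed=master)
            dataio.write_annotation(ds.annotation, outdir / "annotation.csv", seed=master)
            dataio.write_genotype(ds.genotype, outdir / "genotype.csv", seed=master)
            ds.truth.to_json(outdir / "truth.json")
        return ds.expression, ds.phenotype, ds.annotation, ds.genotype, ds.truth

    expr_raw, pheno, ann, geno, truth = study

    @_stage("spawnstats")
    def spawn():
        ph = classify_spawns(pheno)
        comp = comparison_frame(group_comparison(ph))
        if write_artifacts:
            comp.to_csv(outdir / "spawnstats.csv", index=False)
        return ph, comp

    pheno_labeled, spawn_table = spawn
    report["stages"]["spawnstats"] = {
        "n_high": int((pheno_labeled.table["quality_label"] == "high").sum()),
        "n_low": int((pheno_labeled.table["quality_label"] == "low").sum()),
        "metrics": spawn_table.to_dict(orient="records"),
    }

    @_stage("normalize")
    def normalized():
        norm, params = vsn_normalize(expr_raw)
        if write_artifacts:
            dataio.write_expression(norm, outdir / "expression_vsn.tsv", seed=master)
        return norm, params

    expr_norm, vsn_params = normalized
    report["stages"]["normalize"] = {
        "glog_c": float(vsn_params.c),
        "n_iterations": vsn_params.n_iterations,
    }

    @_stage("screen")
    def screened():
        sc = probe_screen(expr_norm, pheno_labeled,
                          mode=cfg["screen"]["mode"],
                          p_cutoff=cfg["screen"]["p_cutoff"],
                          target=cfg["screen"].get("target", target))
        if write_artifacts:
            sc.table.to_csv(outdir / "screen.tsv", sep="\t", index=False)
        return sc

    screen = screened
    report["stages"]["screen"] = {
        "n_selected": len(screen.selected),
        "fraction_selected": len(screen.selected) / expr_norm.n_probes,
        "mode": screen.mode,
    }

    @_stage("train")
    def trained():
        if not screen.selected:
            raise ValueError("screen selected no probes; cannot train")
        sizes = [min(s, len(screen.selected)) for s in cfg["ann"]["sizes"]]
        sizes = sorted(set(sizes), reverse=True)
        ann_cfg = AnnConfig(
            n_models=cfg["ann"]["n_models"],
            hidden_units=cfg["ann"]["hidden_units"],
            l2_penalty=cfg["ann"]["l2_penalty"],
            max_iterations=cfg["ann"]["max_iterations"],
            seed=_sub_seed(master, "train"),
        )
        runs = nested_subset_run(expr_norm, pheno_labeled, screen,
                                 sizes=sizes, config=ann_cfg, target=target)
        comparison = (
            compare_probe_sets({k: v[0] for k, v in runs.items()})
            if len(runs) >= 2 else None
        )
        if write_artifacts:
            for k, (_res, sens) in runs.items():
                sens.table.to_csv(outdir / f"sensitivity_{k}.tsv", sep="\t", index=False)
        return sizes, runs, comparison

    sizes, runs, comparison = trained
    report["stages"]["train"] = {
        "sizes": sizes,
        "per_size": {
            str(k): {
                "mean_model_r2": res.mean_train_r2,
                "sem_model_r2": res.sem_train_r2,
                "mean_cv_r2": res.mean_cv_r2,
                "sem_cv_r2": res.sem_cv_r2,
                "max_share": float(sens.table["share"].max()),
            }
            for k, (res, sens) in runs.items()
        },
    }
    if comparison is not None:
        report["stages"]["train"]["anova_cv"] = {
            "F": comparison.anova_f, "p": comparison.anova_p,
            "duncan_letters": {str(k): v for k, v in comparison.letters.items()},
        }

    if geno is not None:
        @_stage("genotype")
        def geno_share():
            gcfg = AnnConfig(n_models=cfg["ann"]["n_models"], l2_penalty=0.01,
                             seed=_sub_seed(master, "genotype"))
            return genotype_variance(geno, pheno_labeled, gcfg, target=target)

        report["stages"]["genotype"] = {"cv_r2_share": geno_share}

    # --- fingerprint: collapse the refinement set, residualize, cluster -----
    refine_size = sizes[min(1, len(sizes) - 1)]

    @_stage("fingerprint")
    def fingerprinted():
        top_probes = runs[sizes[0]][1].top(refine_size)
        sub = expr_norm.subset_probes(top_probes)
        collapsed = dataio.collapse_duplicates(sub, ann)
        resid = reverse_residualize(
            collapsed, pheno_labeled,
            AnnConfig(seed=_sub_seed(master, "residualize"), l2_penalty=1e-3),
            target_name=target,
        )
        part = mmc_cluster(
            resid,
            sharpness_grid=list(range(1, cfg["mmc"]["sharpness_max"] + 1)),
            correlation=cfg["mmc"]["correlation"],
        )
        if write_artifacts:
            cg = clustergram(collapsed, image_path=str(outdir / "clustergram.png"))
            cg.matrix.to_csv(outdir / "clustergram_matrix.tsv", sep="\t")
            part_rows = [
                {"gene_id": g, "module": m, "sharpness": part.sharpness,
                 "Q": part.modularity}
                for g, m in part.module_of.items()
            ]
            import pandas as pd

            pd.DataFrame(part_rows).to_csv(outdir / "modules.tsv", sep="\t", index=False)
        return collapsed, resid, part

    collapsed, resid, partition = fingerprinted
    report["stages"]["fingerprint"] = {
        "n_probes_refined": refine_size,
        "n_genes_collapsed": collapsed.n_probes,
        "n_modules": partition.n_modules,
        "sharpness": partition.sharpness,
        "modularity": partition.modularity,
        "low_confidence": partition.low_confidence,
    }

    @_stage("network")
    def networked():
        net = build_relevance_networks(
            resid, partition,
            threshold=cfg["network"]["threshold"],
            min_component_size=cfg["network"]["min_component_size"],
        )
        if write_artifacts:
            write_sif(net, outdir / "relevance.sif")
            write_graphml(net, outdir / "relevance.graphml")
        return net

    net = networked
    report["stages"]["network"] = {
        "n_edges": net.graph.number_of_edges(),
        "n_components": len(net.components),
        "n_depicted_components": len(net.depicted_components),
        "depicted_sizes": sorted(
            (len(c) for c in net.depicted_components), reverse=True
        ),
    }

    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        fp = set(truth.fingerprint_gene_ids)
        top = runs[sizes[0]][1].top(refine_size)
        gene_of = ann.gene_for()
        top_genes = {gene_of[p] for p in top}
        common = [g for g in collapsed.probe_ids if g in truth.module_of]
        report["truth_recovery"] = {
            "top_refined_planted_fraction": len(top_genes & fp) / len(top_genes),
            "mmc_ari": float(
                adjusted_rand_score(
                    [truth.module_of[g] for g in common],
                    [partition.module_of[g] for g in common],
                )
            ) if common else None,
        }

    report_json = json.dumps(report, sort_keys=True, indent=1)
    report["report_sha256"] = hashlib.sha256(report_json.encode()).hexdigest()
    if write_artifacts:
        (outdir / "report.json").write_text(report_json + "\n")
        (outdir / "summary.txt").write_text(render_summary(report))
    return report


def render_summary(report: dict) -> str:
    """Human-readable run summary mirroring the structure of the ensemble
    results table (per-size model and CV R^2 with SEM)."""
    lines = [
        f"eggprint run (seed={report['seed']}, config {report['config_hash']})",
        "",
        f"{'probes':>8} {'model R2':>12} {'CV R2':>12}",
    ]
    train = report["stages"].get("train", {})
    for k, row in sorted(train.get("per_size", {}).items(), key=lambda kv: -int(kv[0])):
        lines.append(
            f"{k:>8} {row['mean_model_r2']:.3f}+-{row['sem_model_r2']:.3f} "
            f"{row['mean_cv_r2']:.3f}+-{row['sem_cv_r2']:.3f}"
        )
    fp = report["stages"].get("fingerprint", {})
    if fp:
        lines += [
            "",
            f"collapsed genes: {fp['n_genes_collapsed']}  "
            f"modules: {fp['n_modules']} (Q*={fp['modularity']:.3f} "
            f"at s*={fp['sharpness']:.0f})",
        ]
    net = report["stages"].get("network", {})
    if net:
        lines.append(
            f"relevance networks: {net['n_depicted_components']} depicted "
            f"component(s) of sizes {net['depicted_sizes']}"
        )
    if "genotype" in report["stages"]:
        lines.append(
            f"genotype CV R2 share: {report['stages']['genotype']['cv_r2_share']:.4f}"
        )
    return "\n".join(lines) + "\n"
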