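"""End-to-end orchestration of the driver-gene discovery pipeline.

Stage order: differential expression -> coexpression modules on the DEG
subset -> CFG prioritization of disease-module genes -> drug-target
matrix completion -> network proximity.  Each stage reads the previous
stage's in-memory outputs and writes its tables to the output directory,
so any stage can also be re-run from disk.  One master seed derives every
stage seed by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cfg as cfg_mod
from . import coexpr, dex, dtembed, io, netprox, synthdata

logger = logging.getLogger(__name__)

# fixed offsets deriving per-stage seeds from the master seed
SEED_OFFSETS = {
    "expression": 11,
    "evidence": 23,
    "drug_target": 37,
    "interactome": 53,
    "dex": 71,
    "imc": 89,
    "proximity": 101,
}


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults."""

    out_dir: Path = Path("pipeline_out")
    master_seed: int = 0
    # synthetic-data stage
    simulation: synthdata.SimulationConfig | None = None
    # coexpression stage
    min_module_size: int = 30
    cut_height: float = 0.99
    r2_target: float = 0.80
    # CFG stage
    min_cfg_score: int = 4
    evidence_prevalence: float = 0.6
    # drug-target stage
    imc_rank: int = 5
    imc_alpha: float = 0.1
    imc_lambda: float = 0.01
    # proximity stage
    sigmoid_steepness: float = 30.0
    sigmoid_midpoint: float = 0.33
    similarity_threshold: float = 0.5

    def stage_seed(self, stage: str) -> int:
        return (self.master_seed + SEED_OFFSETS[stage]) % (2**31)


@dataclass
class RunManifest:
    """Record of one pipeline run: parameters, outputs, hashes, warnings."""

    parameters: dict = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    hashes: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    stage_stats: dict[str, dict] = field(default_factory=dict)

    def record(self, name: str, path: Path) -> None:
        self.outputs[name] = str(path)
        self.hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "parameters": self.parameters,
                    "outputs": self.outputs,
                    "hashes": self.hashes,
                    "warnings": self.warnings,
                    "stage_stats": self.stage_stats,
                },
                fh,
                indent=2,
                default=str,
            )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage on synthetic inputs and write all tables.

    Returns a manifest listing outputs, SHA-256 hashes and per-stage
    counts.  A stage failure raises with the stage name in the message;
    downstream stages are not run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(parameters={"master_seed": config.master_seed})

    # --- stage 0: synthetic inputs -------------------------------------
    # default study: modules large and DEG-enriched enough that the DEG
    # subset still carries recoverable coexpression modules
    sim = config.simulation or synthdata.SimulationConfig(
        n_genes=600,
        module_sizes=(70, 70, 70),
        deg_fraction=0.4,
        deg_module_enrichment=0.8,
        seed=config.stage_seed("expression"),
    )
    study = _stage(manifest, "simulate", synthdata.simulate_expression, sim)
    io.write_expression_tsv(study, out / "expression.tsv", out / "phenotype.tsv")
    manifest.record("expression", out / "expression.tsv")
    manifest.record("phenotype", out / "phenotype.tsv")

    # --- stage 1: differential expression ------------------------------
    degs = _stage(manifest, "dex", dex.deg_table, study)
    deg_out = degs.reset_index(names="gene")
    io.write_table(deg_out, out / "deg.tsv")
    manifest.record("deg", out / "deg.tsv")
    deg_genes = degs.index[degs["is_deg"]]
    manifest.stage_stats["dex"] = {
        "genes": int(len(degs)),
        "degs": int(len(deg_genes)),
    }
    logger.info("dex: %d DEGs of %d genes", len(deg_genes), len(degs))

    # --- stage 2: coexpression on the DEG subset -----------------------
    def _coexpr():
        sub = synthdata.ExpressionStudy(
            values=study.values.loc[deg_genes],
            phenotype=study.phenotype,
            dataset_name=study.dataset_name,
        )
        corr = coexpr.correlation_matrix(sub)
        scan = coexpr.pick_soft_threshold(corr, r2_target=config.r2_target)
        adj = coexpr.adjacency(corr, scan.chosen_power)
        t = coexpr.tom(adj)
        partition = coexpr.cluster_modules(
            pd.DataFrame(t, index=corr.index, columns=corr.index),
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
        )
        eigs = coexpr.module_eigengenes(sub, partition)
        if partition.labels:
            traits = coexpr.module_trait_correlation(eigs, sub.phenotype)
            ad_module = coexpr.select_ad_module(traits)
        else:
            traits = pd.DataFrame(columns=["correlation", "p_value"])
            ad_module = None
        return sub, scan, partition, eigs, traits, ad_module

    sub, scan, partition, eigs, traits, ad_module = _stage(
        manifest, "coexpr", _coexpr
    )
    io.write_table(
        pd.DataFrame(
            {
                "power": scan.powers,
                "fit_r2": scan.fit_r2,
                "mean_connectivity": scan.mean_connectivity,
            }
        ),
        out / "soft_threshold.tsv",
    )
    io.write_table(
        partition.assignment.rename("module").rename_axis("gene").reset_index(),
        out / "modules.tsv",
    )
    io.write_table(eigs.reset_index(names="sample"), out / "eigengenes.tsv")
    io.write_table(traits.reset_index(), out / "module_trait.tsv")
    for name in ("soft_threshold", "modules", "eigengenes", "module_trait"):
        manifest.record(name, out / f"{name}.tsv")
    manifest.stage_stats["coexpr"] = {
        "power": scan.chosen_power,
        "modules": len(partition.labels),
        "ad_module": ad_module,
    }
    logger.info(
        "coexpr: power %d, %d modules, AD module %s",
        scan.chosen_power, len(partition.labels), ad_module,
    )

    # --- stage 3: CFG prioritization -----------------------------------
    if ad_module is None:
        module_genes = list(deg_genes)
        manifest.warnings.append("no AD-associated module; CFG run on all DEGs")
    else:
        label = int(str(ad_module).removeprefix("ME"))
        module_genes = list(partition.assignment.index[partition.assignment == label])

    def _cfg():
        evidence = synthdata.simulate_evidence(
            module_genes,
            prevalence=config.evidence_prevalence,
            seed=config.stage_seed("evidence"),
        )
        scored = cfg_mod.score_table(evidence)
        return scored, cfg_mod.prioritize(scored, min_score=config.min_cfg_score)

    scored, prioritized = _stage(manifest, "cfg", _cfg)
    io.write_table(scored, out / "cfg_scores.tsv")
    io.write_table(prioritized, out / "cfg_prioritized.tsv")
    manifest.record("cfg_scores", out / "cfg_scores.tsv")
    manifest.record("cfg_prioritized", out / "cfg_prioritized.tsv")
    manifest.stage_stats["cfg"] = {
        "module_genes": len(module_genes),
        "prioritized": int(len(prioritized)),
    }
    logger.info("cfg: %d of %d genes prioritized", len(prioritized), len(module_genes))

    # --- stage 4: drug-target matrix completion ------------------------
    def _dtembed():
        data = synthdata.simulate_drug_target(seed=config.stage_seed("drug_target"))
        model = dtembed.fit_imc(
            data,
            k=config.imc_rank,
            alpha=config.imc_alpha,
            lam=config.imc_lambda,
            seed=config.stage_seed("imc"),
        )
        scores = dtembed.predict_scores(model, data.X, data.Y)
        return data, model, scores

    data, model, scores = _stage(manifest, "dtembed", _dtembed)
    score_frame = pd.DataFrame(scores, index=data.drug_ids, columns=data.target_ids)
    score_frame.index.name = "drug"
    score_frame.to_csv(out / "dt_scores.tsv", sep="\t")
    manifest.record("dt_scores", out / "dt_scores.tsv")
    manifest.stage_stats["dtembed"] = {
        "n_drugs": int(data.P.shape[0]),
        "n_targets": int(data.P.shape[1]),
        "iterations": len(model.objective_trace) - 1,
        "final_objective": model.objective_trace[-1],
    }

    # --- stage 5: network proximity ------------------------------------
    def _netprox():
        fixture = synthdata.simulate_interactome(seed=config.stage_seed("interactome"))
        results = netprox.score_drug_modules(
            fixture.graph,
            fixture.drug_modules,
            fixture.disease_module,
            c=config.sigmoid_steepness,
            d_mid=config.sigmoid_midpoint,
        )
        return fixture, results

    fixture, results = _stage(manifest, "netprox", _netprox)
    prox_frame = pd.DataFrame(
        [{"drug": r.drug, "proximity": r.p, "f": r.f} for r in results]
    )
    io.write_table(prox_frame, out / "proximity.tsv")
    manifest.record("proximity", out / "proximity.tsv")
    manifest.stage_stats["netprox"] = {"pairs": len(results)}

    manifest.save(out / "manifest.json")
    return manifest


def _stage(manifest: RunManifest, name: str, fn, *args):
    """Run one stage, converting failures into stage-named errors."""
    import warnings as _warnings

    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            result = fn(*args)
        for w in caught:
            manifest.warnings.append(f"{name}: {w.message}")
        return result
    except Exception as exc:  # re-raise with the failing stage named
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
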