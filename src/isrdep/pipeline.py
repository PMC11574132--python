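"""Pipeline configuration and the end-to-end demo runner.

``run_pipeline`` chains simulate -> (normalize) -> de -> classify ->
intersect -> enrich on synthetic data with known truth, writing every
intermediate as TSV plus a checksum manifest. Identical config + seed
yields identical manifest checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, io, normalize, synthetic
from .containers import parse_contrast
from .dependence import PROFILES, classify_dependence
from .signatures import GeneSet, SignatureTable, core_signature, hypergeometric_overlap, shared_in_k

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def demo_config_path() -> Path:
    """Path to the bundled demo configuration."""
    return Path(__file__).parent / "data" / "demo_config.yaml"


#: every knob with its default; unknown keys are rejected before any stage runs
CONFIG_DEFAULTS: dict = {
    "seed": 0,
    "outdir": "isrdep_demo",
    "mode": "intensity",        # intensity -> microarray path; counts -> rnaseq path
    "n_genes": 2000,
    "n_per_group": 4,
    "k_models": 3,
    "shared_core": 51,
    "model_private": 20,
    "noise_sd": 0.25,
    "dispersion": 0.05,
    "library_size": 2_000_000,
    "effect_size": 2.0,
    "reversion_fraction": 1.0,
    "span": normalize.DEFAULT_SPAN,
    "tolerance": normalize.DEFAULT_TOLERANCE,
    "pedestal": normalize.DEFAULT_PEDESTAL,
    "iterations": 1,
    "target_set_size": 80,
    "log_level": "INFO",
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load and validate a pipeline config; unknown keys are an error."""
    cfg = dict(CONFIG_DEFAULTS)
    raw: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
    raw.update(overrides or {})
    unknown = set(raw) - set(CONFIG_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(raw)
    if cfg["mode"] not in ("intensity", "counts"):
        raise ConfigError(f"mode must be intensity or counts, got {cfg['mode']!r}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute the full demo chain; returns the artifact manifest."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def record(path: Path, stage: str) -> None:
        manifest.append({"file": path.name, "stage": stage, "sha256": _sha256(path)})

    params = synthetic.SimulationParams(
        n_genes=config["n_genes"],
        n_per_group=config["n_per_group"],
        noise_sd=config["noise_sd"],
        dispersion=config["dispersion"],
        library_size=config["library_size"],
        seed=config["seed"],
    )
    eff = {
        "effect_size": config["effect_size"],
        "reversion_fraction": config["reversion_fraction"],
    }

    # --- simulate ---------------------------------------------------------
    sim = synthetic.simulate_multi_model(
        k_models=config["k_models"],
        shared_core=config["shared_core"],
        model_private=config["model_private"],
        params=params,
        mode=config["mode"],
        effect_params=eff,
    )
    design_path = outdir / "design.tsv"
    io.write_design(sim.design, design_path)
    record(design_path, "simulate")
    for model_id, (em, truth) in zip(sim.model_ids, sim.models):
        p = outdir / f"{model_id}_expression.tsv"
        io.write_expression(em, p)
        record(p, "simulate")
        t = outdir / f"{model_id}_truth.tsv"
        io.write_truth(truth, t)
        record(t, "simulate")

    # --- normalize / de / classify per model ------------------------------
    call_frames: dict[str, pd.DataFrame] = {}
    universe: set[str] | None = None
    for model_id, (em, truth) in zip(sim.model_ids, sim.models):
        if config["mode"] == "counts":
            filtered, _, removed = normalize.rnaseq_preprocess(
                em,
                sim.design,
                pedestal=config["pedestal"],
                span=config["span"],
                tolerance=config["tolerance"],
                iterations=config["iterations"],
            )
            p = outdir / f"{model_id}_normalized.tsv"
            io.write_expression(filtered, p)
            record(p, "normalize")
            rm = outdir / f"{model_id}_removed.txt"
            rm.write_text("\n".join(removed) + ("\n" if removed else ""))
            record(rm, "normalize")
            anc = diffexpr.ancova_fit(filtered, sim.design)
            anc = diffexpr.posthoc_pairwise(anc)
            stress = diffexpr.posthoc_contrast_result(anc, "g3_vs_g1")
            rescue = diffexpr.posthoc_contrast_result(anc, "g4_vs_g3")
            gate_p = anc.table["group_fdr"]
            profile = "rnaseq"
        else:
            stress = diffexpr.oneway_anova(em, sim.design, parse_contrast("g3_vs_g1"), "g3_vs_g1")
            rescue = diffexpr.oneway_anova(em, sim.design, parse_contrast("g4_vs_g3"), "g4_vs_g3")
            gate_p = None
            profile = "microarray"
        for cr in (stress, rescue):
            p = outdir / f"{model_id}_{cr.name}.tsv"
            io.write_contrast(cr.table, p)
            record(p, "de")
        calls = classify_dependence(stress, rescue, PROFILES[profile](), gate_p=gate_p)
        p = outdir / f"{model_id}_calls.tsv"
        io.write_contrast(calls, p)
        record(p, "classify")
        call_frames[model_id] = calls
        universe = set(calls.index) if universe is None else universe & set(calls.index)

    # --- intersect --------------------------------------------------------
    table = SignatureTable.from_calls(
        {m: df.loc[sorted(set(df.index) & universe)] for m, df in call_frames.items()},
        universe=universe,
    )
    core = core_signature(table)
    shared2 = shared_in_k(table, k=2)
    core_df = pd.DataFrame(sorted(core), columns=["gene_id", "direction"])
    p = outdir / "core_signature.tsv"
    core_df.to_csv(p, sep="\t", index=False)
    record(p, "intersect")

    # --- enrich -----------------------------------------------------------
    # synthetic reference target set: the planted core plus seeded decoys,
    # standing in for an external ChIP-target list
    rng = np.random.default_rng(config["seed"] + 7)
    core_genes = {g for g, _ in core}
    decoy_pool = sorted(universe - sim.shared_core)
    n_decoys = max(0, config["target_set_size"] - len(sim.shared_core & universe))
    decoys = set(rng.choice(decoy_pool, size=min(n_decoys, len(decoy_pool)), replace=False))
    target = GeneSet(
        name="synthetic_targets",
        members=(sim.shared_core & universe) | decoys,
        source="synthetic",
    )
    gmt_path = outdir / "synthetic_targets.gmt"
    io.write_gmt([target], gmt_path)
    record(gmt_path, "enrich")
    enr = hypergeometric_overlap(core_genes, target, universe)

    summary = {
        "n_models": len(sim.model_ids),
        "universe_size": len(universe),
        "core_signature_size": len(core),
        "shared_in_2_size": len(shared2),
        "planted_core_size": len(sim.shared_core),
        "core_recovered_from_planted": len(core_genes & sim.shared_core),
        "enrichment": {
            "overlap": enr.overlap_count,
            "query": enr.query_size,
            "set": enr.set_size,
            "universe": enr.universe_size,
            "p": enr.p,
            "fold_enrichment": enr.fold_enrichment,
        },
    }
    sp = outdir / "summary.json"
    sp.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    record(sp, "enrich")

    manifest_obj = {"config": {k: config[k] for k in sorted(config)}, "files": manifest}
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest_obj, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d artifacts in %s", len(manifest), outdir)
    return manifest_obj
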