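"""End-to-end orchestration: generate -> count -> fitness -> phenotype ->
regress -> simulate -> report.

A single configuration mapping (YAML/JSON-friendly) drives all stages;
every stochastic stage derives its generator from the top-level seed, so
a rerun with the same configuration produces byte-identical data
artifacts.  Timestamps go to the run log only, never into data files.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .core import (
    ENVIRONMENTS,
    ValidationError,
    write_landscape,
    write_sites,
)
from .counting import count_sample, write_counts
from .fitness import (
    build_landscape,
    replicate_correlation,
    selection_rates,
    write_table,
)
from .phenotyping import hybrid_analysis, phenotype_table
from .regression import build_design_matrix, fit_sparse_model, write_coefficients
from .simulator import SimulationConfig, run_simulation
from .synthetic import (
    DEFAULT_SITES,
    GroundTruthModel,
    arrays_to_records,
    generate_library_frequencies,
    generate_true_landscapes,
    simulate_competition_reads,
    write_fastq,
    write_reference_fasta,
)

logger = logging.getLogger(__name__)

MIXED_ENVIRONMENTS = ("B", "C", "D")


def default_config() -> dict[str, Any]:
    """Desk-scale demo configuration exercising every stage."""
    return {
        "seed": 1,
        "generate": {
            "n_umis": 20_000,
            "mean_reads": 5.0,
            "per_base_error": 0.001,
            "concentration": 100.0,
            "replicates": 2,
            "fastq_sample": True,  # render one small FASTQ pair
        },
        "count": {"min_reads": 3},
        "fitness": {"T": 1.0},
        "phenotype": {"threshold": 0.33, "k": 27},
        "regress": {"criterion": "bic"},
        "simulate": {
            "models": ["static_C", "continuous_shifting"],
            "N": 1_000_000,
            "generations": 100,
            "replicates": 5,
            "target_r": 0.96,
        },
    }


def _validate_config(config: Mapping[str, Any]) -> None:
    if "seed" not in config:
        raise ValidationError("config must declare an explicit top-level seed")
    for stage in ("generate", "count", "fitness", "phenotype", "regress", "simulate"):
        if stage not in config:
            raise ValidationError(f"config missing stage block {stage!r}")


def _stage_seed(base_seed: int, stage: int, item: int = 0) -> int:
    """Deterministic per-stage integer seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), stage, item])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> Path:
    """Execute all stages into ``outdir`` and return the artifact directory."""
    _validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    started = time.time()
    try:
        _run_stages(dict(config), out)
    finally:
        logger.info("pipeline finished in %.1f s", time.time() - started)
        logger.removeHandler(handler)
        handler.close()
    return out


def _run_stages(config: dict[str, Any], out: Path) -> None:
    seed = int(config["seed"])
    from . import __version__ as _version
    echo = {"config": config, "package_version": _version}
    (out / "config_echo.json").write_text(json.dumps(echo, indent=2, sort_keys=True) + "\n")

    # --- generate ----------------------------------------------------------
    gen_cfg = config["generate"]
    model = GroundTruthModel.default(seed=_stage_seed(seed, 0))
    truth = generate_true_landscapes(model)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for env_id, landscape in truth.items():
        write_landscape(landscape, truth_dir / f"landscape_{env_id}.tsv")
    write_sites(DEFAULT_SITES, out / "sites.tsv")
    write_reference_fasta(out / "reference.fasta")

    f0 = generate_library_frequencies(
        concentration=gen_cfg["concentration"], seed=_stage_seed(seed, 1)
    )
    n_replicates = int(gen_cfg["replicates"])
    counts_dir = out / "counts"
    counts_dir.mkdir(exist_ok=True)
    samples: dict[tuple[str, int], tuple] = {}
    item = 0
    for env_id in ENVIRONMENTS:
        for rep in range(n_replicates):
            item += 1
            t0, t4 = simulate_competition_reads(
                truth[env_id],
                f0,
                n_umis=int(gen_cfg["n_umis"]),
                mean_reads=float(gen_cfg["mean_reads"]),
                per_base_error=float(gen_cfg["per_base_error"]),
                seed=_stage_seed(seed, 2, item),
            )
            samples[(env_id, rep)] = (t0, t4)
            logger.info(
                "generated %s rep %d: %d/%d UMIs", env_id, rep, t0.n_umis, t4.n_umis
            )
    if gen_cfg.get("fastq_sample"):
        t0, t4 = samples[("C", 0)]
        for arrays, tag in ((t0, "t0"), (t4, "t4")):
            records = arrays_to_records(arrays, seed=_stage_seed(seed, 3))
            write_fastq(records, out / f"sample_C0_{tag}.fastq")

    # --- count + fitness ---------------------------------------------------
    min_reads = int(config["count"]["min_reads"])
    duration = float(config["fitness"]["T"])
    tables_dir = out / "rates"
    tables_dir.mkdir(exist_ok=True)
    landscapes_dir = out / "landscapes"
    landscapes_dir.mkdir(exist_ok=True)
    estimated = {}
    correlations = {}
    tables_by_env: dict[str, list] = {e: [] for e in ENVIRONMENTS}
    for (env_id, rep), (t0, t4) in samples.items():
        sample_id = f"{env_id}{rep}"
        gc0 = count_sample(t0, min_reads, sample_id, "t0")
        gc4 = count_sample(t4, min_reads, sample_id, "t4")
        write_counts(gc0, counts_dir / f"{sample_id}_t0.tsv")
        write_counts(gc4, counts_dir / f"{sample_id}_t4.tsv")
        table = selection_rates(gc0, gc4, duration, ENVIRONMENTS[env_id])
        table.sample_id = sample_id
        write_table(table, tables_dir / f"{sample_id}.tsv")
        tables_by_env[env_id].append(table)
        logger.info("counted %s: kept %d UMIs at t0", sample_id, int(gc0.counts.sum()))
    for env_id, tables in tables_by_env.items():
        estimated[env_id] = build_landscape(tables, ENVIRONMENTS[env_id])
        write_landscape(estimated[env_id], landscapes_dir / f"landscape_{env_id}.tsv")
        if len(tables) >= 2:
            r, n = replicate_correlation(tables[0], tables[1])
            correlations[env_id] = {"pearson_r": r, "n_shared": n}

    # --- phenotype ---------------------------------------------------------
    phen_cfg = config["phenotype"]
    records = phenotype_table(
        estimated["A"], estimated["E"], threshold=float(phen_cfg["threshold"])
    )
    records.to_csv(out / "phenotypes.tsv", sep="\t", index=False, float_format="%.12g", na_rep="NA")
    trios, fraction_below = hybrid_analysis(
        records, threshold=float(phen_cfg["threshold"]), k=phen_cfg.get("k")
    )
    trios.to_csv(out / "hybrid_trios.tsv", sep="\t", index=False, float_format="%.12g", na_rep="NA")

    # --- regress -----------------------------------------------------------
    observations = []
    for env_id in MIXED_ENVIRONMENTS:
        competitor = ENVIRONMENTS[env_id].competitor
        for table in tables_by_env[env_id]:
            frame = table.to_frame()
            frame = frame[np.isfinite(frame["S"])]
            for genotype, s in zip(frame["genotype"], frame["S"]):
                observations.append((genotype, competitor, s, table.sample_id))
    obs_frame = pd.DataFrame(
        observations, columns=["genotype", "competitor", "S", "replicate"]
    )
    design = build_design_matrix(obs_frame)
    fitted = fit_sparse_model(
        design, criterion=config["regress"]["criterion"], seed=_stage_seed(seed, 4)
    )
    write_coefficients(fitted, out / "coefficients.tsv")
    logger.info(
        "regression: %d rows, %d nonzero terms, R2 %.3f",
        len(design.y),
        fitted.n_nonzero,
        fitted.r2,
    )

    # --- simulate ----------------------------------------------------------
    sim_cfg = config["simulate"]
    sim_dir = out / "simulations"
    sim_dir.mkdir(exist_ok=True)
    sim_summary = {}
    item = 0
    for model_name in sim_cfg["models"]:
        endpoints = []
        final_entropies = []
        for rep in range(int(sim_cfg["replicates"])):
            item += 1
            sc = SimulationConfig(
                N=int(sim_cfg["N"]),
                generations=int(sim_cfg["generations"]),
                model=model_name,
                target_r=float(sim_cfg["target_r"]),
                seed=_stage_seed(seed, 5, item),
            )
            trajectory = run_simulation(sc, estimated)
            endpoints.append(trajectory.endpoint_label)
            final_entropies.append(float(trajectory.entropy[-1]))
            if rep == 0:
                with open(sim_dir / f"{model_name}_rep0.jsonl", "w") as handle:
                    for gen in range(len(trajectory.entropy)):
                        record = {
                            "gen": gen,
                            "entropy": round(float(trajectory.entropy[gen]), 6),
                            "pop_si": round(float(trajectory.population_si[gen]), 6),
                            "active": trajectory.active_landscape[gen - 1] if gen else None,
                        }
                        handle.write(json.dumps(record) + "\n")
        sim_summary[model_name] = {
            "endpoint_labels": endpoints,
            "median_endpoint_entropy": float(np.median(final_entropies)),
        }
        logger.info("simulated %s x%d", model_name, int(sim_cfg["replicates"]))

    # --- report ------------------------------------------------------------
    report = {
        "replicate_correlations": correlations,
        "hybrid_fraction_below": fraction_below,
        "n_valid_trios": int(trios["valid"].sum()),
        "regression": {
            "n_observations": int(len(design.y)),
            "n_features": int(design.X.shape[1]),
            "n_nonzero": fitted.n_nonzero,
            "r2": fitted.r2,
        },
        "simulations": sim_summary,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    lines = ["| quantity | value |", "| --- | --- |"]
    for env_id, cor in correlations.items():
        lines.append(f"| replicate Pearson r ({env_id}) | {cor['pearson_r']:.3f} |")
    lines.append(f"| hybrid trios below parental line | {fraction_below:.3f} |")
    lines.append(f"| regression nonzero terms | {fitted.n_nonzero} |")
    for model_name, summ in sim_summary.items():
        lines.append(
            f"| median endpoint entropy ({model_name}) | "
            f"{summ['median_endpoint_entropy']:.3f} |"
        )
    (out / "report.md").write_text("\n".join(lines) + "\n")
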