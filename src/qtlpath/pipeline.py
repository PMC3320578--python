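"""Configuration-driven three-step analysis runner.

For one motif (or an externally supplied dataset) the pipeline executes
the full analysis: (1) simulate an mQTL dataset, (2) compute QTL
evidence and raw/conditional metabolite correlations, (3) sample causal
graphs by MCMC and summarize the top-scoring networks.  All outputs are
plain text (CSV/TSV/DOT/JSON) and are a pure function of the
configuration and the master seed; no timestamps are written into any
artifact, so reruns are byte-identical.

The master seed is fanned out to stage seeds through
``numpy.random.SeedSequence(master_seed).spawn``: child 0 seeds the
simulation, child 1 the MCMC chains, child 2 the propagation-experiment
imputation noise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .bn import MCMCConfig, consensus_network, run_mcmc
from .correlate import conditional_correlation
from .dataset import MQTLDataset
from .motifs import MOTIF_NAMES, build_motif
from .simulate import GeneticPerturbationSpec, SimulationConfig, simulate_population

__all__ = ["PipelineConfig", "run_motif_pipeline", "load_dataset"]

logger = logging.getLogger("qtlpath.pipeline")


@dataclass
class PipelineConfig:
    """Everything needed for one end-to-end motif run."""

    motif: str
    out_dir: str | Path = "qtlpath_out"
    master_seed: int = 0
    motif_params: dict | None = None
    perturbation: GeneticPerturbationSpec = field(default_factory=GeneticPerturbationSpec)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    use_interactions: bool = False
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.motif not in MOTIF_NAMES:
            raise ValueError(f"unknown motif {self.motif!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file; keyword overrides (CLI flags) win and the
        override is logged."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {
            "motif": raw.get("motif"),
            "out_dir": raw.get("out_dir", "qtlpath_out"),
            "master_seed": raw.get("master_seed", 0),
            "motif_params": raw.get("motif_params"),
            "use_interactions": raw.get("use_interactions", False),
            "top_k": raw.get("top_k", 10),
        }
        if "perturbation" in raw:
            kwargs["perturbation"] = GeneticPerturbationSpec(**raw["perturbation"])
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig(**raw["simulation"])
        if "mcmc" in raw:
            kwargs["mcmc"] = MCMCConfig(**raw["mcmc"])
        for key, value in overrides.items():
            if value is None:
                continue
            if key in kwargs and kwargs[key] != value:
                logger.info("flag overrides config: %s=%r", key, value)
            kwargs[key] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "motif": self.motif,
                "master_seed": self.master_seed,
                "motif_params": self.motif_params,
                "perturbation": vars(self.perturbation),
                "simulation": {
                    k: v for k, v in vars(self.simulation).items()
                },
                "mcmc": {k: v for k, v in vars(self.mcmc).items()},
                "use_interactions": self.use_interactions,
                "top_k": self.top_k,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(master_seed: int, n: int = 3) -> list[int]:
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0]) for c in children]


def _write_matrix(df, path: Path) -> None:
    df.to_csv(path, float_format="%.10g")


def run_motif_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> correlate -> infer and write all artifacts.

    Returns a manifest mapping artifact names to paths.  Raises with the
    stage name on any failure after serializing intermediate state.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_seed, mcmc_seed, prop_seed = _stage_seeds(config.master_seed)
    manifest: dict = {}
    report: dict = {
        "motif": config.motif,
        "master_seed": config.master_seed,
        "config_hash": config.config_hash(),
        "stage_seeds": {
            "simulate": sim_seed,
            "mcmc": mcmc_seed,
            "propagation": prop_seed,
        },
    }
    timings: dict = {}

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        motif = build_motif(config.motif, config.motif_params)
        sim_config = replace(config.simulation, seed=sim_seed)
        data = simulate_population(motif, config.perturbation, sim_config)
        data.to_csv(out / "dataset.csv")
        manifest["dataset"] = out / "dataset.csv"
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs (%d rows)", stage, timings[stage], data.n_samples)

        stage = "correlate"
        t0 = time.perf_counter()
        interactions = None
        if config.use_interactions and len(data.genotype_columns) >= 2:
            g = data.genotype_columns
            interactions = [(g[i], g[j]) for i in range(len(g)) for j in range(i + 1, len(g))]
        result = conditional_correlation(data, interactions=interactions)
        _write_matrix(result.qtl_evidence, out / "qtl_evidence.csv")
        _write_matrix(result.raw, out / "correlation_raw.csv")
        _write_matrix(result.conditional, out / "correlation_conditional.csv")
        manifest.update(
            qtl_evidence=out / "qtl_evidence.csv",
            correlation_raw=out / "correlation_raw.csv",
            correlation_conditional=out / "correlation_conditional.csv",
        )
        report["conditioning_design"] = result.design
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", stage, timings[stage])

        stage = "infer"
        t0 = time.perf_counter()
        mcmc_config = replace(config.mcmc, seed=mcmc_seed, seeds=None)
        posterior = run_mcmc(data, mcmc_config)
        consensus = consensus_network(posterior, data, k=config.top_k)
        consensus.to_tsv(out / "consensus.tsv")
        consensus.to_dot(out / "consensus.dot")
        manifest.update(consensus=out / "consensus.tsv", consensus_dot=out / "consensus.dot")
        report["mcmc"] = posterior.summary()
        report["consensus_k"] = consensus.k
        timings[stage] = time.perf_counter() - t0
        logger.info(
            "stage %s done in %.2fs (acceptance %s)",
            stage,
            timings[stage],
            [round(c.acceptance_rate, 3) for c in posterior.chains],
        )
    except Exception as exc:
        failure = out / "failed_stage.json"
        failure.write_text(
            json.dumps({"stage": stage, "error": str(exc), "report": report},
                       indent=2, default=str)
        )
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    logger.info("wall time per stage: %s", {k: round(v, 2) for k, v in timings.items()})
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
    )
    manifest["report"] = out / "report.json"
    return manifest


def load_dataset(
    path: str | Path, role_map: Mapping[str, Sequence[str]] | None = None
) -> MQTLDataset:
    """Load and validate a sample x variable CSV as an MQTLDataset.

    Column roles come from a sidecar ``.meta.json``, an explicit
    ``role_map`` (keys ``genotype``/``epistasis``/``metabolite``) or the
    ``Q``/``E`` prefix convention.  Genotype columns must be two-level.
    """
    return MQTLDataset.from_csv(path, role_map=role_map)
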