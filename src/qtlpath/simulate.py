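"""Stochastic simulation of genetically perturbed pathway motifs.

Each motif is driven by an input flux perturbed by a Brownian path,
integrated over a fixed horizon for every genotype combination, and the
endpoint concentrations are collected as one sample of an mQTL-style
dataset.  Within-genotype variation therefore comes only from the
stochastic input; between-genotype variation comes from the genetic flux
multipliers.

The Brownian perturbation is applied as a piecewise-constant offset to
the input flux rate on the path's grid; between grid points the ODE is
deterministic.  The workhorse integrator is a fixed-step RK4 vectorized
over an entire population (all genotypes x replicates at once); a scipy
adaptive path (``method="adaptive"``) is kept for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dataset import MQTLDataset
from .motifs import PathwayMotif

__all__ = [
    "BrownianInput",
    "GeneticPerturbationSpec",
    "SimulationConfig",
    "brownian_path",
    "enumerate_genotypes",
    "apply_genetic_perturbation",
    "propagate",
    "simulate_population",
]


# ----------------------------------------------------------------------
# Specs
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GeneticPerturbationSpec:
    """Flux-capacity multipliers attached to the two genotype classes."""

    low_multiplier: float = 0.5
    high_multiplier: float = 1.5

    def __post_init__(self) -> None:
        if not 0 <= self.low_multiplier < self.high_multiplier:
            raise ValueError("require 0 <= low_multiplier < high_multiplier")


@dataclass(frozen=True)
class BrownianInput:
    """A discretized Brownian path W on a uniform grid over [0, T]."""

    T: float
    n_steps: int
    sigma: float
    seed: int
    path: np.ndarray

    def __post_init__(self) -> None:
        if self.path.shape != (self.n_steps + 1,):
            raise ValueError("path length must be n_steps + 1")
        if self.path[0] != 0.0:
            raise ValueError("Brownian path must start at 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for population simulation.

    ``T``/``n_steps`` define the Brownian grid, ``substeps`` the RK4
    steps per grid cell.  ``rel_tol``/``abs_tol`` are used by the
    adaptive cross-check integrator.  ``initial_state`` may be a scalar
    (broadcast) or a per-species vector.
    """

    T: float = 100.0
    n_steps: int = 1000
    substeps: int = 2
    sigma: float = 0.015
    n_reps: int = 50
    initial_state: float | tuple[float, ...] = 0.1
    seed: int = 0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-6
    method: str = "rk4"

    def __post_init__(self) -> None:
        if self.T <= 0 or self.n_steps < 1 or self.substeps < 1:
            raise ValueError("T, n_steps, substeps must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.method not in ("rk4", "adaptive"):
            raise ValueError("method must be 'rk4' or 'adaptive'")


# ----------------------------------------------------------------------
# Building blocks
# ----------------------------------------------------------------------
def brownian_path(T: float, n_steps: int, sigma: float, seed: int) -> BrownianInput:
    """Sample W with W(0)=0 and independent N(0, sigma^2 * T/n_steps) increments."""
    if T <= 0 or n_steps < 1:
        raise ValueError("T and n_steps must be positive")
    rng = np.random.default_rng(seed)
    dt = T / n_steps
    increments = rng.normal(0.0, sigma * np.sqrt(dt), size=n_steps)
    path = np.concatenate(([0.0], np.cumsum(increments)))
    return BrownianInput(T=T, n_steps=n_steps, sigma=sigma, seed=seed, path=path)


def enumerate_genotypes(R: int) -> np.ndarray:
    """All 2^R genotype vectors over {-1, +1}, in lexicographic order.

    Row 0 is all -1; the last locus varies fastest.
    """
    if R < 0:
        raise ValueError("number of loci must be non-negative")
    if R == 0:
        return np.zeros((1, 0), dtype=int)
    grid = np.indices((2,) * R).reshape(R, -1).T
    return (2 * grid - 1).astype(int)


def apply_genetic_perturbation(
    motif: PathwayMotif,
    genotype: Sequence[int],
    spec: GeneticPerturbationSpec = GeneticPerturbationSpec(),
) -> np.ndarray:
    """Per-flux vmax multipliers for one genotype vector.

    ``genotype`` is aligned with ``motif.loci``.  Fluxes without a locus
    get multiplier 1.  If the motif has an epistasis rule and the
    (signal, enzyme) alleles match a null combination, the target flux
    multiplier is forced to 0 regardless of its own locus.
    """
    genotype = np.asarray(genotype, dtype=int)
    loci = motif.loci
    if genotype.shape != (len(loci),):
        raise ValueError(f"genotype length {genotype.shape} != number of loci {len(loci)}")
    allele = dict(zip(loci, genotype.tolist()))
    mult = np.ones(len(motif.fluxes))
    for j, f in enumerate(motif.fluxes):
        locus = motif.genetic_loci.get(f.id)
        if locus is not None:
            mult[j] = (
                spec.high_multiplier if allele[locus] == 1 else spec.low_multiplier
            )
    rule = motif.epistasis
    if rule is not None:
        combo = (allele[rule.loci[0]], allele[rule.loci[1]])
        if combo in rule.null_combinations:
            mult[motif._flux_index[rule.target_flux]] = 0.0
    return mult


# ----------------------------------------------------------------------
# Integration
# ----------------------------------------------------------------------
def _rhs(motif: PathwayMotif, x: np.ndarray, multipliers: np.ndarray, pert: np.ndarray):
    """Mass-balance right-hand side, tolerant of tiny negative overshoot."""
    rates = motif.flux_rates(np.maximum(x, 0.0), multipliers)
    idx = motif._input_flux_indices
    rates[..., idx] = np.maximum(rates[..., idx] + pert, 0.0)
    return rates @ motif._stoich.T


def _integrate_rk4(
    motif: PathwayMotif,
    x0: np.ndarray,
    multipliers: np.ndarray,
    W: np.ndarray,
    T: float,
    n_steps: int,
    substeps: int,
    return_trajectory: bool = False,
):
    """Fixed-step RK4 over the Brownian grid, batched on the leading axis.

    ``x0``: (batch, n_species); ``multipliers``: (batch, n_fluxes);
    ``W``: (batch, n_inputs, n_steps+1) piecewise-constant perturbations
    (value at the left grid point is held over the cell).
    """
    h = T / n_steps / substeps
    x = x0.astype(float).copy()
    traj = [x.copy()] if return_trajectory else None
    for k in range(n_steps):
        pert = W[:, :, k]
        for _ in range(substeps):
            k1 = _rhs(motif, x, multipliers, pert)
            k2 = _rhs(motif, x + 0.5 * h * k1, multipliers, pert)
            k3 = _rhs(motif, x + 0.5 * h * k2, multipliers, pert)
            k4 = _rhs(motif, x + h * k3, multipliers, pert)
            x = np.maximum(x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
        if return_trajectory:
            traj.append(x.copy())
    if return_trajectory:
        return x, np.stack(traj, axis=1)
    return x


def _integrate_adaptive(
    motif: PathwayMotif,
    x0: np.ndarray,
    multipliers: np.ndarray,
    W: np.ndarray,
    T: float,
    n_steps: int,
    rel_tol: float,
    abs_tol: float,
) -> np.ndarray:
    """Reference integrator: scipy RK45 cell by cell (single trajectory)."""
    dt = T / n_steps
    x = x0.astype(float).copy()
    for k in range(n_steps):
        pert = W[:, k]

        def f(t, y):
            return _rhs(motif, y, multipliers, pert)

        sol = solve_ivp(
            f, (0.0, dt), x, method="RK45", rtol=rel_tol, atol=abs_tol
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"integration failed in cell {k}: {sol.message}")
        x = np.maximum(sol.y[:, -1], 0.0)
    return x


def _initial_state(motif: PathwayMotif, config: SimulationConfig) -> np.ndarray:
    x0 = np.asarray(config.initial_state, dtype=float)
    if x0.ndim == 0:
        x0 = np.full(len(motif.species), float(x0))
    if x0.shape != (len(motif.species),):
        raise ValueError("initial_state length does not match motif species")
    if np.any(x0 < 0):
        raise ValueError("initial_state must be non-negative")
    return x0


def propagate(
    motif: PathwayMotif,
    multipliers: Sequence[float],
    inputs: BrownianInput | Sequence[BrownianInput],
    config: SimulationConfig = SimulationConfig(),
    return_trajectory: bool = False,
):
    """Integrate one trajectory; return endpoint concentrations X(T).

    ``inputs`` supplies one Brownian path per input flux of the motif (a
    single path may be given for single-input motifs).  With
    ``return_trajectory=True`` also returns the state at every grid
    point, shape ``(n_steps+1, n_species)``.
    """
    if isinstance(inputs, BrownianInput):
        inputs = [inputs]
    if len(inputs) != motif.n_inputs:
        raise ValueError(
            f"motif has {motif.n_inputs} input flux(es); {len(inputs)} path(s) given"
        )
    for b in inputs:
        if b.n_steps != config.n_steps or b.T != config.T:
            raise ValueError("Brownian grid must match the simulation config")
    W = np.stack([b.path for b in inputs])  # (n_inputs, n_steps+1)
    x0 = _initial_state(motif, config)
    multipliers = np.asarray(multipliers, dtype=float)
    if np.any(multipliers < 0):
        raise ValueError("multipliers must be non-negative")
    try:
        if config.method == "adaptive":
            if return_trajectory:
                raise ValueError("trajectories only available with method='rk4'")
            return _integrate_adaptive(
                motif, x0, multipliers, W, config.T, config.n_steps,
                config.rel_tol, config.abs_tol,
            )
        out = _integrate_rk4(
            motif,
            x0[None, :],
            multipliers[None, :],
            W[None, :, :],
            config.T,
            config.n_steps,
            config.substeps,
            return_trajectory=return_trajectory,
        )
    except FloatingPointError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"integration failed for motif {motif.name}, seeds "
            f"{[b.seed for b in inputs]}: {exc}"
        ) from exc
    if return_trajectory:
        x, traj = out
        return x[0], traj[0]
    return out[0]


# ----------------------------------------------------------------------
# Population simulation
# ----------------------------------------------------------------------
def _epistasis_column(motif: PathwayMotif, genotypes: np.ndarray) -> np.ndarray:
    """Composite one-degree-of-freedom variable: -1 for null combos, +1 else."""
    rule = motif.epistasis
    loci = motif.loci
    i_sig = loci.index(rule.loci[0])
    i_enz = loci.index(rule.loci[1])
    col = np.ones(len(genotypes), dtype=int)
    for r, g in enumerate(genotypes):
        if (int(g[i_sig]), int(g[i_enz])) in rule.null_combinations:
            col[r] = -1
    return col


def simulate_population(
    motif: PathwayMotif,
    pert: GeneticPerturbationSpec = GeneticPerturbationSpec(),
    config: SimulationConfig = SimulationConfig(),
) -> MQTLDataset:
    """Simulate ``n_reps`` independent input paths for every genotype.

    Returns a dataset with ``n_reps * 2^R`` rows: genotype columns named
    after the motif loci, a composite epistasis column (if the motif has
    a rule) and endpoint metabolite columns named after the species.
    The whole table is a pure function of (motif, pert, config).
    """
    loci = motif.loci
    genotypes = enumerate_genotypes(len(loci))
    n_geno = len(genotypes)
    n_rows = n_geno * config.n_reps

    # one multiplier vector per genotype, broadcast to rows
    mult_geno = np.stack(
        [apply_genetic_perturbation(motif, g, pert) for g in genotypes]
    )
    row_geno = np.repeat(np.arange(n_geno), config.n_reps)
    multipliers = mult_geno[row_geno]

    # independent Brownian path(s) per row, reproducibly derived from the
    # master seed via SeedSequence spawning (row-major: genotype x rep)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_rows)
    dt = config.T / config.n_steps
    W = np.empty((n_rows, motif.n_inputs, config.n_steps + 1))
    W[:, :, 0] = 0.0
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        inc = rng.normal(
            0.0, config.sigma * np.sqrt(dt), size=(motif.n_inputs, config.n_steps)
        )
        W[r, :, 1:] = np.cumsum(inc, axis=1)

    x0 = np.tile(_initial_state(motif, config), (n_rows, 1))
    endpoints = _integrate_rk4(
        motif, x0, multipliers, W, config.T, config.n_steps, config.substeps
    )
    endpoints = np.maximum(endpoints, 0.0)

    data = {}
    for i, locus in enumerate(loci):
        data[locus] = genotypes[row_geno, i]
    epi_cols: list[str] = []
    if motif.epistasis is not None:
        col = _epistasis_column(motif, genotypes)[row_geno]
        name = f"E_{motif.epistasis.label}"
        data[name] = col
        epi_cols.append(name)
    for i, sp in enumerate(motif.species):
        data[sp] = endpoints[:, i]
    frame = pd.DataFrame(data)

    ds = MQTLDataset(
        frame,
        genotype_columns=list(loci),
        epistasis_columns=epi_cols,
        metabolite_columns=list(motif.species),
        metadata={
            "motif": motif.name,
            "motif_definition": motif.to_dict(),
            "seed": config.seed,
            "config": {
                "T": config.T,
                "n_steps": config.n_steps,
                "substeps": config.substeps,
                "sigma": config.sigma,
                "n_reps": config.n_reps,
            },
            "perturbation": {
                "low_multiplier": pert.low_multiplier,
                "high_multiplier": pert.high_multiplier,
            },
        },
    )
    ds.validate(require_nonnegative_metabolites=True)
    return ds


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
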