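"""Linear structural-equation data with controllable residual propagation.

Generates trait tables of the form ``Y_j = mu_j + sum_l beta_lj Q_l +
sum_i gamma_ij Y_i + eps_j`` with acyclic trait-to-trait coefficients and
i.i.d. balanced binary genotypes.  This is the generative structure under
which QTL-conditional correlation isolates non-genetic (propagated)
variance, and it provides ground truth for network-inference tests.

`impute_no_propagation` rebuilds one trait from its fitted genetic model
plus fresh independent noise, severing any propagated residual variance
while preserving the genetic signal and the marginal variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import MQTLDataset

__all__ = ["SEMSpec", "generate_sem_population", "impute_no_propagation"]


@dataclass
class SEMSpec:
    """Specification of a linear SEM with genetic drivers.

    ``beta`` has shape (loci, traits); ``gamma`` has shape (traits,
    traits) with ``gamma[i, j]`` the causal effect of trait i on trait j
    and must define a DAG.  ``epistasis_pairs`` optionally adds product
    columns ``E_<a>x<b> = Q_a * Q_b`` that act through ``beta_epistasis``
    (shape (pairs, traits)).
    """

    n: int
    loci: int
    mu: Sequence[float]
    beta: np.ndarray
    gamma: np.ndarray
    sigma: Sequence[float]
    seed: int = 0
    trait_names: list[str] | None = None
    locus_names: list[str] | None = None
    epistasis_pairs: list[tuple[int, int]] = field(default_factory=list)
    beta_epistasis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        k = len(self.mu)
        if self.gamma.shape != (k, k):
            raise ValueError("gamma must be (traits, traits)")
        if self.beta.shape != (self.loci, k):
            raise ValueError("beta must be (loci, traits)")
        if self.sigma.shape != (k,) or np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive, one per trait")
        if self.n < 1 or self.loci < 0:
            raise ValueError("n >= 1 and loci >= 0 required")
        g = nx.from_numpy_array(self.gamma != 0, create_using=nx.DiGraph)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("gamma must define an acyclic trait graph")
        self._order = list(nx.topological_sort(g))
        if self.trait_names is None:
            self.trait_names = [f"Y{i + 1}" for i in range(k)]
        if self.locus_names is None:
            self.locus_names = [f"Q{i + 1}" for i in range(self.loci)]
        if self.epistasis_pairs:
            self.beta_epistasis = np.atleast_2d(
                np.asarray(self.beta_epistasis, dtype=float)
            )
            if self.beta_epistasis.shape != (len(self.epistasis_pairs), k):
                raise ValueError("beta_epistasis must be (pairs, traits)")

    @property
    def n_traits(self) -> int:
        return len(self.mu)


def generate_sem_population(spec: SEMSpec) -> MQTLDataset:
    """Draw one sample table from the SEM.

    Genotypes are i.i.d. uniform on {-1, +1} (unlinked loci); traits are
    filled in topological order with independent Gaussian residuals.
    """
    rng = np.random.default_rng(spec.seed)
    Q = rng.choice([-1, 1], size=(spec.n, spec.loci))
    E = np.empty((spec.n, len(spec.epistasis_pairs)), dtype=int)
    for j, (a, b) in enumerate(spec.epistasis_pairs):
        E[:, j] = Q[:, a] * Q[:, b]
    Y = np.zeros((spec.n, spec.n_traits))
    eps = rng.normal(0.0, 1.0, size=(spec.n, spec.n_traits)) * spec.sigma
    for j in spec._order:
        Y[:, j] = spec.mu[j] + Q @ spec.beta[:, j] + eps[:, j]
        if spec.epistasis_pairs:
            Y[:, j] += E @ spec.beta_epistasis[:, j]
        parents = np.nonzero(spec.gamma[:, j])[0]
        for i in parents:
            Y[:, j] += spec.gamma[i, j] * Y[:, i]

    epi_names = [
        f"E_{spec.locus_names[a]}x{spec.locus_names[b]}"
        for a, b in spec.epistasis_pairs
    ]
    frame = pd.DataFrame(
        np.column_stack([Q, E, Y]) if epi_names else np.column_stack([Q, Y]),
        columns=spec.locus_names + epi_names + spec.trait_names,
    )
    for c in spec.locus_names + epi_names:
        frame[c] = frame[c].astype(int)
    return MQTLDataset(
        frame,
        genotype_columns=spec.locus_names,
        epistasis_columns=epi_names,
        metabolite_columns=spec.trait_names,
        metadata={"generator": "sem", "seed": spec.seed},
    )


def _genetic_design(data: MQTLDataset, qtl: Sequence[str], interactions) -> np.ndarray:
    cols = [data.frame[c].to_numpy(dtype=float) for c in qtl]
    if interactions:
        for a, b in interactions:
            cols.append(
                data.frame[a].to_numpy(dtype=float) * data.frame[b].to_numpy(dtype=float)
            )
    X = np.column_stack(cols) if cols else np.empty((data.n_samples, 0))
    return sm.add_constant(X, has_constant="add")


def impute_no_propagation(
    data: MQTLDataset,
    y1: str,
    y2: str,
    qtl: Sequence[str],
    interactions: Sequence[tuple[str, str]] | None = None,
    seed: int = 0,
) -> MQTLDataset:
    """Replace ``y2`` by its genetic fit plus fresh independent noise.

    The genetic part of ``y2`` is estimated by OLS on the QTL columns
    (plus optional pairwise interaction products); the residual is
    discarded and replaced with Gaussian noise of matching variance, so
    any residual variance propagated from ``y1`` is removed while the
    genetic model and marginal variance are preserved.  ``y1`` and every
    other column are untouched.
    """
    if y2 not in data.metabolite_columns:
        raise KeyError(f"{y2!r} is not a metabolite column")
    X = _genetic_design(data, qtl, interactions)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient genetic design for imputation")
    y = data.frame[y2].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    resid_sd = float(np.std(fit.resid, ddof=X.shape[1]))
    rng = np.random.default_rng(seed)
    new_y2 = fit.fittedvalues + rng.normal(0.0, resid_sd, size=len(y))
    out = data.with_metabolites(pd.DataFrame({y2: new_y2}))
    out.metadata["imputed_no_propagation"] = {
        "trait": y2,
        "qtl": list(qtl),
        "seed": seed,
        "residual_sd": resid_sd,
    }
    return out
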