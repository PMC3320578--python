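"""QTL evidence, metabolite correlation and QTL-conditional correlation.

The analysis is deliberately simple: Pearson correlation between the
genotype coding and each metabolite serves as QTL evidence (sign and
magnitude give direction and effect size); conditional correlation is
the Pearson correlation of least-squares residuals after each metabolite
is regressed on the genetic design (QTL columns, composite epistasis
variables and optional interaction products).  Correlation that survives
conditioning reflects variance from outside the genetic factors, e.g.
input fluctuations propagating through the pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import MQTLDataset
from .sem import impute_no_propagation

__all__ = [
    "ConditionalCorrelationResult",
    "PropagationReport",
    "pearson_matrix",
    "qtl_evidence",
    "condition_on_qtl",
    "conditional_correlation",
    "residual_propagation_experiment",
]


def _pearson(values: np.ndarray, labels: Sequence[str]) -> pd.DataFrame:
    """Correlation matrix with NaN (and a warning) for constant columns."""
    n, k = values.shape
    if n < 3:
        raise ValueError("at least 3 samples required for correlation")
    sd = values.std(axis=0)
    constant = sd == 0
    if constant.any():
        bad = [labels[i] for i in np.nonzero(constant)[0]]
        warnings.warn(
            f"constant columns {bad}: correlations reported as NaN", stacklevel=3
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(values.T)
    C = np.asarray(C, dtype=float).reshape(k, k)
    C[constant, :] = np.nan
    C[:, constant] = np.nan
    np.fill_diagonal(C, np.where(constant, np.nan, 1.0))
    C = np.clip(C, -1.0, 1.0)
    return pd.DataFrame(C, index=list(labels), columns=list(labels))


def pearson_matrix(data: MQTLDataset, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Pearson correlation of the selected columns (metabolites by default)."""
    if columns is None:
        columns = data.metabolite_columns
    values = data.frame[list(columns)].to_numpy(dtype=float)
    return _pearson(values, columns)


def qtl_evidence(data: MQTLDataset) -> pd.DataFrame:
    """Genetic-factor x metabolite correlation matrix.

    Rows are genotype and composite epistasis columns; entry (j, i) is
    the Pearson correlation of factor j's coding with metabolite i.
    """
    rows = data.genetic_columns
    cols = data.metabolite_columns
    full = _pearson(
        data.frame[rows + cols].to_numpy(dtype=float), rows + cols
    )
    return full.loc[rows, cols]


def _design_matrix(
    data: MQTLDataset,
    qtl_columns: Sequence[str],
    interactions: Sequence[tuple[str, str]] | None,
) -> tuple[np.ndarray, list[str]]:
    names = list(qtl_columns)
    cols = [data.frame[c].to_numpy(dtype=float) for c in qtl_columns]
    for pair in interactions or []:
        a, b = pair
        cols.append(
            data.frame[a].to_numpy(dtype=float) * data.frame[b].to_numpy(dtype=float)
        )
        names.append(f"{a}:{b}")
    X = np.column_stack([np.ones(data.n_samples)] + cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"conditioning design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"columns: {['const'] + names}"
        )
    return X, names


def condition_on_qtl(
    data: MQTLDataset,
    qtl_columns: Sequence[str] | None = None,
    interactions: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Least-squares residuals of every metabolite on the genetic design.

    Residuals are exactly orthogonal to the intercept and every design
    column.  By default conditions on all genotype and epistasis columns.
    """
    if qtl_columns is None:
        qtl_columns = data.genetic_columns
    X, _ = _design_matrix(data, qtl_columns, interactions)
    Y = data.metabolites().to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return pd.DataFrame(R, columns=data.metabolite_columns, index=data.frame.index)


@dataclass
class ConditionalCorrelationResult:
    """Raw and QTL-conditional metabolite correlation plus QTL evidence."""

    raw: pd.DataFrame
    conditional: pd.DataFrame
    qtl_evidence: pd.DataFrame
    design: list[str] = field(default_factory=list)


def conditional_correlation(
    data: MQTLDataset,
    qtl_columns: Sequence[str] | None = None,
    interactions: Sequence[tuple[str, str]] | None = None,
) -> ConditionalCorrelationResult:
    """Metabolite correlation before and after conditioning on QTL."""
    if qtl_columns is None:
        qtl_columns = data.genetic_columns
    raw = pearson_matrix(data)
    residuals = condition_on_qtl(data, qtl_columns, interactions)
    cond = _pearson(residuals.to_numpy(), data.metabolite_columns)
    _, names = _design_matrix(data, qtl_columns, interactions)
    return ConditionalCorrelationResult(
        raw=raw,
        conditional=cond,
        qtl_evidence=qtl_evidence(data),
        design=names,
    )


@dataclass
class PropagationReport:
    """Outcome of the residual-propagation experiment for one trait pair."""

    y1: str
    y2: str
    observed_residual_corr: float
    imputed_residual_corr: float
    genetic_model: dict
    qtl: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "y1": self.y1,
            "y2": self.y2,
            "observed_residual_corr": self.observed_residual_corr,
            "imputed_residual_corr": self.imputed_residual_corr,
            "genetic_model": self.genetic_model,
            "qtl": self.qtl,
        }


def _residual_pair_corr(
    data: MQTLDataset,
    y1: str,
    y2: str,
    qtl: Sequence[str],
    interactions,
) -> float:
    X, _ = _design_matrix(data, qtl, interactions)
    out = []
    for y in (y1, y2):
        v = data.frame[y].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, v, rcond=None)
        out.append(v - X @ beta)
    return float(np.corrcoef(out[0], out[1])[0, 1])


def residual_propagation_experiment(
    data: MQTLDataset,
    y1: str,
    y2: str,
    qtl: Sequence[str] | None = None,
    interactions: Sequence[tuple[str, str]] | None = None,
    seed: int = 0,
) -> PropagationReport:
    """Measure how much of the y1-y2 residual correlation is propagated.

    Computes the QTL-conditional correlation of the pair on the observed
    data, then on a copy in which ``y2`` is re-imputed from its genetic
    model with independent noise (no propagation).  A large observed and
    near-zero imputed correlation demonstrates that non-genetic variance
    propagating between the traits, not shared genetics, carries the
    causal signal.
    """
    if qtl is None:
        qtl = data.genetic_columns
    observed = _residual_pair_corr(data, y1, y2, qtl, interactions)
    imputed_data = impute_no_propagation(
        data, y1, y2, qtl, interactions=interactions, seed=seed
    )
    imputed = _residual_pair_corr(imputed_data, y1, y2, qtl, interactions)

    X, names = _design_matrix(data, qtl, interactions)
    fit = sm.OLS(data.frame[y2].to_numpy(dtype=float), X).fit()
    genetic_model = {
        "terms": ["const"] + names,
        "coefficients": [float(c) for c in fit.params],
        "standard_errors": [float(s) for s in fit.bse],
        "residual_sd": float(np.sqrt(fit.scale)),
    }
    return PropagationReport(
        y1=y1,
        y2=y2,
        observed_residual_corr=observed,
        imputed_residual_corr=imputed,
        genetic_model=genetic_model,
        qtl=list(qtl),
    )
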