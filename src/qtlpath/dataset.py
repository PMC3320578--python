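"""Tabular container for sample x (genotype, epistasis, metabolite) data.

A :class:`MQTLDataset` is a thin, validated wrapper around a pandas
DataFrame.  Column roles are tracked explicitly so that downstream code
never has to guess which columns are genetic factors and which are
quantitative traits.  By convention, simulated data uses column names
``Q_*`` (genotype, coded -1/+1), ``E_*`` (composite epistasis variables,
coded -1/+1) and ``S*`` (metabolite endpoint concentrations); the roles
can also be supplied explicitly for externally produced tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["MQTLDataset"]


def _infer_roles(columns: Sequence[str]) -> tuple[list[str], list[str], list[str]]:
    """Infer column roles from the naming convention."""
    geno = [c for c in columns if c.startswith("Q")]
    epi = [c for c in columns if c.startswith("E")]
    metab = [c for c in columns if c not in geno and c not in epi]
    return geno, epi, metab


@dataclass
class MQTLDataset:
    """Samples x variables table with typed columns.

    Parameters
    ----------
    frame
        One row per sample.  All entries must be finite numbers.
    genotype_columns, epistasis_columns, metabolite_columns
        Explicit role assignment.  If all three are ``None`` the roles are
        inferred from column-name prefixes (``Q``/``E``/other).
    metadata
        Free-form provenance (motif name, seeds, config hash, ...).
    """

    frame: pd.DataFrame
    genotype_columns: list[str] | None = None
    epistasis_columns: list[str] | None = None
    metabolite_columns: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.genotype_columns is None
            and self.epistasis_columns is None
            and self.metabolite_columns is None
        ):
            g, e, m = _infer_roles(list(self.frame.columns))
            self.genotype_columns, self.epistasis_columns, self.metabolite_columns = g, e, m
        else:
            self.genotype_columns = list(self.genotype_columns or [])
            self.epistasis_columns = list(self.epistasis_columns or [])
            self.metabolite_columns = list(self.metabolite_columns or [])
        self.validate()

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self, require_nonnegative_metabolites: bool = False) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        known = set(self.genotype_columns) | set(self.epistasis_columns) | set(
            self.metabolite_columns
        )
        unknown = [c for c in self.frame.columns if c not in known]
        if unknown:
            raise ValueError(f"columns with no assigned role: {unknown}")
        missing = [c for c in known if c not in self.frame.columns]
        if missing:
            raise ValueError(f"role columns absent from frame: {missing}")
        values = self.frame.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = self.frame.columns[~np.isfinite(values).all(axis=0)].tolist()
            raise ValueError(f"non-finite or missing values in columns: {bad}")
        for col in self.genotype_columns:
            levels = np.unique(self.frame[col].to_numpy())
            if len(levels) != 2:
                raise ValueError(
                    f"genotype column {col!r} has {len(levels)} level(s); exactly 2 required"
                )
        if require_nonnegative_metabolites:
            for col in self.metabolite_columns:
                if (self.frame[col].to_numpy() < 0).any():
                    raise ValueError(f"negative metabolite values in column {col!r}")

    # ------------------------------------------------------------------
    # convenience accessors
    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def genetic_columns(self) -> list[str]:
        """Genotype plus composite epistasis columns."""
        return list(self.genotype_columns) + list(self.epistasis_columns)

    def genotypes(self) -> pd.DataFrame:
        return self.frame[self.genotype_columns]

    def metabolites(self) -> pd.DataFrame:
        return self.frame[self.metabolite_columns]

    def with_metabolites(self, new: pd.DataFrame) -> "MQTLDataset":
        """Return a copy with metabolite columns replaced (same roles)."""
        frame = self.frame.copy()
        for col in new.columns:
            if col not in self.metabolite_columns:
                raise KeyError(f"{col!r} is not a metabolite column")
            frame[col] = new[col].to_numpy()
        return MQTLDataset(
            frame,
            genotype_columns=self.genotype_columns,
            epistasis_columns=self.epistasis_columns,
            metabolite_columns=self.metabolite_columns,
            metadata=dict(self.metadata),
        )

    # ------------------------------------------------------------------
    # I/O: CSV with a JSON sidecar for roles and provenance
    # ------------------------------------------------------------------
    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        self.frame.to_csv(path, index=False, float_format="%.12g")
        if sidecar:
            meta = {
                "genotype_columns": self.genotype_columns,
                "epistasis_columns": self.epistasis_columns,
                "metabolite_columns": self.metabolite_columns,
                "metadata": self.metadata,
            }
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n"
            )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        role_map: Mapping[str, Sequence[str]] | None = None,
    ) -> "MQTLDataset":
        """Load a dataset from CSV.

        Roles are taken from (in order of precedence) `role_map` with keys
        ``genotype``/``epistasis``/``metabolite``, a ``.meta.json`` sidecar
        next to the file, or the column-name convention.
        """
        path = Path(path)
        frame = pd.read_csv(path)
        non_numeric = [
            c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)
        ]
        if non_numeric:
            raise ValueError(f"non-numeric columns: {non_numeric}")
        if frame.isna().any().any():
            bad = frame.columns[frame.isna().any()].tolist()
            raise ValueError(f"missing values in columns: {bad}")
        if role_map is not None:
            return cls(
                frame,
                genotype_columns=list(role_map.get("genotype", [])),
                epistasis_columns=list(role_map.get("epistasis", [])),
                metabolite_columns=list(role_map.get("metabolite", [])),
            )
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            return cls(
                frame,
                genotype_columns=meta["genotype_columns"],
                epistasis_columns=meta["epistasis_columns"],
                metabolite_columns=meta["metabolite_columns"],
                metadata=meta.get("metadata", {}),
            )
        return cls(frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MQTLDataset(n={self.n_samples}, "
            f"genotype={self.genotype_columns}, "
            f"epistasis={self.epistasis_columns}, "
            f"metabolites={self.metabolite_columns})"
        )
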