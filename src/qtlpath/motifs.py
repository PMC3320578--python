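"""Pathway motif definitions: flux laws, mass balance, genetic control.

Six small metabolic architectures are provided, each described as a set
of saturating flux laws connected by a stoichiometry matrix.  Fluxes may
be under genetic control (a binary locus scales the flux capacity) and
one motif carries an epistasis rule under which particular genotype
combinations abolish a flux entirely.

Flux kinds
----------
``input``
    Constant uptake from an unmodeled external pool; the only flux kind
    subject to the stochastic input perturbation.
``uni_substrate``
    Michaelis-Menten: ``v = Vmax * s / (Km + s)``.
``bi_substrate``
    Separable two-substrate saturation:
    ``v = Vmax * s1 * s2 / ((Km1 + s1) * (Km2 + s2))``.
``substrate_inhibited``
    ``v = Vmax * s / (Km + s + s * i / Ki)`` where ``i`` is the
    concentration of the inhibitor species.  When the inhibitor is the
    substrate itself this is the classical uncompetitive substrate
    inhibition form ``Vmax * s / (Km + s + s^2/Ki)``; as ``Ki -> inf``
    the law converges to plain Michaelis-Menten.
``sink``
    Michaelis-Menten consumption with no product (efflux/degradation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "FluxSpec",
    "EpistasisRule",
    "PathwayMotif",
    "MOTIF_NAMES",
    "mm_flux",
    "bisubstrate_flux",
    "substrate_inhibited_flux",
    "build_motif",
    "net_rate",
]

MOTIF_NAMES = (
    "linear",
    "merge_bisubstrate",
    "merge_independent",
    "branch",
    "branch_inhibited",
    "branch_epistasis",
)

_FLUX_KINDS = ("uni_substrate", "bi_substrate", "substrate_inhibited", "input", "sink")


# ----------------------------------------------------------------------
# Elementary flux laws
# ----------------------------------------------------------------------
def _check_nonneg(name: str, value) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be non-negative")


def mm_flux(vmax: float, km: float, s) -> float | np.ndarray:
    """Michaelis-Menten rate ``vmax * s / (km + s)``.

    Monotone increasing in ``s`` and bounded above by ``vmax``; equals
    ``vmax / 2`` at ``s == km``.
    """
    if vmax <= 0 or km <= 0:
        raise ValueError("vmax and km must be positive")
    _check_nonneg("substrate concentration", s)
    s = np.asarray(s, dtype=float)
    out = vmax * s / (km + s)
    return float(out) if out.ndim == 0 else out


def bisubstrate_flux(vmax: float, km1: float, km2: float, s1, s2) -> float | np.ndarray:
    """Separable bi-substrate rate ``vmax * s1 s2 / ((km1+s1)(km2+s2))``.

    Zero whenever either substrate is absent; saturates to ``vmax``.
    """
    if vmax <= 0 or km1 <= 0 or km2 <= 0:
        raise ValueError("vmax, km1, km2 must be positive")
    _check_nonneg("substrate concentration", s1)
    _check_nonneg("substrate concentration", s2)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    out = vmax * s1 * s2 / ((km1 + s1) * (km2 + s2))
    return float(out) if out.ndim == 0 else out


def substrate_inhibited_flux(vmax: float, km: float, ki: float, s) -> float | np.ndarray:
    """Substrate-inhibited rate ``vmax * s / (km + s + s^2/ki)``.

    Rises, peaks at ``s = sqrt(km * ki)`` and declines; converges
    pointwise to :func:`mm_flux` as ``ki -> inf``.
    """
    if vmax <= 0 or km <= 0 or ki <= 0:
        raise ValueError("vmax, km, ki must be positive")
    _check_nonneg("substrate concentration", s)
    s = np.asarray(s, dtype=float)
    out = vmax * s / (km + s + s * s / ki)
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------------
# Declarative motif description
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class FluxSpec:
    """One reaction: kinetic law plus parameters.

    ``substrates`` is empty for ``input`` fluxes, and has two entries only
    for ``bi_substrate``.  ``km`` holds one constant per substrate.
    ``inhibitor``/``ki`` apply only to ``substrate_inhibited`` fluxes; the
    inhibitor may be any species (e.g. the product, for end-product
    feedback) and defaults to the substrate itself.
    """

    id: str
    kind: str
    substrates: tuple[str, ...] = ()
    vmax: float = 1.0
    km: tuple[float, ...] = ()
    ki: float | None = None
    inhibitor: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _FLUX_KINDS:
            raise ValueError(f"unknown flux kind {self.kind!r}")
        if self.vmax <= 0:
            raise ValueError(f"flux {self.id}: vmax must be positive")
        if any(k <= 0 for k in self.km):
            raise ValueError(f"flux {self.id}: km values must be positive")
        n_sub = len(self.substrates)
        if self.kind == "input":
            if n_sub != 0:
                raise ValueError(f"input flux {self.id} takes no substrates")
        elif self.kind == "bi_substrate":
            if n_sub != 2 or len(self.km) != 2:
                raise ValueError(
                    f"bi_substrate flux {self.id} needs two substrates and two km values"
                )
        else:
            if n_sub != 1 or len(self.km) != 1:
                raise ValueError(f"flux {self.id} needs one substrate and one km")
        if self.kind == "substrate_inhibited":
            if self.ki is None or self.ki <= 0:
                raise ValueError(f"flux {self.id}: substrate_inhibited needs ki > 0")
        elif self.ki is not None:
            raise ValueError(f"flux {self.id}: ki only valid for substrate_inhibited")


@dataclass(frozen=True)
class EpistasisRule:
    """Loss of function of a target flux under specific genotype pairs.

    ``loci`` is ``(signal locus, enzyme locus)``; ``null_combinations``
    lists ``(signal allele, enzyme allele)`` pairs (coded -1/+1) under
    which the target flux capacity multiplier is forced to zero.
    """

    loci: tuple[str, str]
    null_combinations: frozenset[tuple[int, int]]
    target_flux: str

    def __post_init__(self) -> None:
        for combo in self.null_combinations:
            if tuple(combo) not in {(-1, -1), (-1, 1), (1, -1), (1, 1)}:
                raise ValueError(f"invalid genotype combination {combo}")

    @property
    def label(self) -> str:
        return f"{self.loci[0]}x{self.loci[1]}"


@dataclass
class PathwayMotif:
    """A pathway architecture: species, fluxes, stoichiometry, genetics.

    ``production``/``utilization`` map each species to ``(flux id,
    stoichiometric coefficient)`` pairs.  ``genetic_loci`` maps flux id to
    the locus controlling it; each locus controls exactly one flux.  Loci
    participating only through an epistasis rule (upstream signals) are
    listed in ``signal_loci``.
    """

    name: str
    species: list[str]
    fluxes: list[FluxSpec]
    production: dict[str, list[tuple[str, float]]]
    utilization: dict[str, list[tuple[str, float]]]
    genetic_loci: dict[str, str] = field(default_factory=dict)
    signal_loci: list[str] = field(default_factory=list)
    epistasis: EpistasisRule | None = None

    def __post_init__(self) -> None:
        self._validate()
        self._compile()

    # -- structural checks ------------------------------------------------
    def _validate(self) -> None:
        flux_ids = [f.id for f in self.fluxes]
        if len(set(flux_ids)) != len(flux_ids):
            raise ValueError("duplicate flux ids")
        sp = set(self.species)
        produced_by: dict[str, int] = {s: 0 for s in self.species}
        for s, pairs in self.production.items():
            if s not in sp:
                raise ValueError(f"production references unknown species {s!r}")
            for fid, alpha in pairs:
                if fid not in flux_ids:
                    raise ValueError(f"production references unknown flux {fid!r}")
                if alpha <= 0:
                    raise ValueError("stoichiometric coefficients must be positive")
                produced_by[s] += 1
        for s, pairs in self.utilization.items():
            if s not in sp:
                raise ValueError(f"utilization references unknown species {s!r}")
            for fid, beta in pairs:
                if fid not in flux_ids:
                    raise ValueError(f"utilization references unknown flux {fid!r}")
                if beta <= 0:
                    raise ValueError("stoichiometric coefficients must be positive")
        for f in self.fluxes:
            for s in f.substrates:
                if s not in sp:
                    raise ValueError(f"flux {f.id} consumes unknown species {s!r}")
            if f.inhibitor is not None and f.inhibitor not in sp:
                raise ValueError(f"flux {f.id} inhibited by unknown species {f.inhibitor!r}")
            produces = [s for s, pairs in self.production.items() if f.id in dict(pairs)]
            if f.kind == "sink":
                if produces:
                    raise ValueError(f"sink flux {f.id} must not produce a species")
            elif f.kind == "input":
                if len(produces) != 1:
                    raise ValueError(f"input flux {f.id} must feed exactly one species")
            else:
                if len(produces) != 1:
                    raise ValueError(f"flux {f.id} must produce exactly one species")
        # closed systems (no input/sink) are allowed for conservation
        # checks; the factory-built motifs always have both
        loci = list(self.genetic_loci.values()) + list(self.signal_loci)
        if len(set(loci)) != len(loci):
            raise ValueError("each locus may control at most one flux")
        for fid in self.genetic_loci:
            if fid not in flux_ids:
                raise ValueError(f"locus assigned to unknown flux {fid!r}")
        if self.epistasis is not None:
            if self.epistasis.target_flux not in flux_ids:
                raise ValueError("epistasis target flux not in motif")
            known = set(loci)
            for locus in self.epistasis.loci:
                if locus not in known:
                    raise ValueError(f"epistasis references unknown locus {locus!r}")

    # -- compiled numeric representation ---------------------------------
    def _compile(self) -> None:
        sp_index = {s: i for i, s in enumerate(self.species)}
        n_s, n_f = len(self.species), len(self.fluxes)
        N = np.zeros((n_s, n_f))
        fid_index = {f.id: j for j, f in enumerate(self.fluxes)}
        for s, pairs in self.production.items():
            for fid, alpha in pairs:
                N[sp_index[s], fid_index[fid]] += alpha
        for s, pairs in self.utilization.items():
            for fid, beta in pairs:
                N[sp_index[s], fid_index[fid]] -= beta
        self._stoich = N
        self._species_index = sp_index
        self._flux_index = fid_index
        self._input_flux_indices = [
            j for j, f in enumerate(self.fluxes) if f.kind == "input"
        ]

    # -- public helpers ---------------------------------------------------
    @property
    def stoichiometry(self) -> np.ndarray:
        """Species x flux matrix of signed stoichiometric coefficients."""
        return self._stoich

    @property
    def input_flux_ids(self) -> list[str]:
        return [self.fluxes[j].id for j in self._input_flux_indices]

    @property
    def n_inputs(self) -> int:
        return len(self._input_flux_indices)

    @property
    def loci(self) -> list[str]:
        """All loci in a stable order: flux-controlling loci then signals."""
        ordered = [
            self.genetic_loci[f.id] for f in self.fluxes if f.id in self.genetic_loci
        ]
        return ordered + list(self.signal_loci)

    def flux_rates(self, x: np.ndarray, multipliers: np.ndarray) -> np.ndarray:
        """Evaluate all flux laws at state ``x`` (batched on leading axes).

        ``x`` has shape ``(..., n_species)`` and ``multipliers`` shape
        ``(..., n_fluxes)`` or ``(n_fluxes,)``; returns ``(..., n_fluxes)``.
        The input-flux perturbation is *not* applied here.
        """
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != len(self.species):
            raise ValueError(
                f"state has {x.shape[-1]} components, motif has {len(self.species)} species"
            )
        multipliers = np.asarray(multipliers, dtype=float)
        if multipliers.shape[-1] != len(self.fluxes):
            raise ValueError("one multiplier per flux required")
        rates = np.empty(x.shape[:-1] + (len(self.fluxes),))
        for j, f in enumerate(self.fluxes):
            if f.kind == "input":
                v = np.full(x.shape[:-1], f.vmax)
            elif f.kind == "bi_substrate":
                s1 = x[..., self._species_index[f.substrates[0]]]
                s2 = x[..., self._species_index[f.substrates[1]]]
                v = f.vmax * s1 * s2 / ((f.km[0] + s1) * (f.km[1] + s2))
            elif f.kind == "substrate_inhibited":
                s = x[..., self._species_index[f.substrates[0]]]
                inhibitor = f.inhibitor if f.inhibitor is not None else f.substrates[0]
                i = x[..., self._species_index[inhibitor]]
                v = f.vmax * s / (f.km[0] + s + s * i / f.ki)
            else:  # uni_substrate or sink
                s = x[..., self._species_index[f.substrates[0]]]
                v = f.vmax * s / (f.km[0] + s)
            rates[..., j] = v
        return rates * multipliers

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "name": self.name,
            "species": list(self.species),
            "fluxes": [
                {
                    "id": f.id,
                    "kind": f.kind,
                    "substrates": list(f.substrates),
                    "vmax": f.vmax,
                    "km": list(f.km),
                    **({"ki": f.ki} if f.ki is not None else {}),
                    **({"inhibitor": f.inhibitor} if f.inhibitor is not None else {}),
                }
                for f in self.fluxes
            ],
            "production": {s: [list(p) for p in ps] for s, ps in self.production.items()},
            "utilization": {s: [list(p) for p in ps] for s, ps in self.utilization.items()},
            "genetic_loci": dict(self.genetic_loci),
            "signal_loci": list(self.signal_loci),
        }
        if self.epistasis is not None:
            d["epistasis"] = {
                "loci": list(self.epistasis.loci),
                "null_combinations": sorted(map(list, self.epistasis.null_combinations)),
                "target_flux": self.epistasis.target_flux,
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PathwayMotif":
        fluxes = [
            FluxSpec(
                id=fd["id"],
                kind=fd["kind"],
                substrates=tuple(fd.get("substrates", ())),
                vmax=fd.get("vmax", 1.0),
                km=tuple(fd.get("km", ())),
                ki=fd.get("ki"),
                inhibitor=fd.get("inhibitor"),
            )
            for fd in d["fluxes"]
        ]
        epi = None
        if d.get("epistasis"):
            e = d["epistasis"]
            epi = EpistasisRule(
                loci=tuple(e["loci"]),
                null_combinations=frozenset(tuple(c) for c in e["null_combinations"]),
                target_flux=e["target_flux"],
            )
        return cls(
            name=d["name"],
            species=list(d["species"]),
            fluxes=fluxes,
            production={s: [tuple(p) for p in ps] for s, ps in d["production"].items()},
            utilization={s: [tuple(p) for p in ps] for s, ps in d["utilization"].items()},
            genetic_loci=dict(d.get("genetic_loci", {})),
            signal_loci=list(d.get("signal_loci", [])),
            epistasis=epi,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PathwayMotif":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PathwayMotif":
        return cls.from_dict(json.loads(text))


# ----------------------------------------------------------------------
# Mass balance
# ----------------------------------------------------------------------
def net_rate(
    motif: PathwayMotif,
    x: np.ndarray,
    multipliers: np.ndarray,
    input_perturbation: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Rate of change of each species: ``dS/dt = N @ v``.

    ``input_perturbation`` offsets the rate of the input flux(es); it may
    be a scalar (applied to every input) or an array with one entry per
    input flux, batched on leading axes.  Perturbed input rates are
    floored at zero so uptake can never run backwards.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    rates = motif.flux_rates(x, multipliers)
    pert = np.asarray(input_perturbation, dtype=float)
    idx = motif._input_flux_indices
    if pert.ndim == 0:
        rates[..., idx] = np.maximum(rates[..., idx] + pert, 0.0)
    else:
        if pert.shape[-1] != len(idx):
            raise ValueError("one perturbation per input flux required")
        rates[..., idx] = np.maximum(rates[..., idx] + pert, 0.0)
    return rates @ motif._stoich.T


# ----------------------------------------------------------------------
# Motif factory
# ----------------------------------------------------------------------
_DEFAULTS = {"vmax": 1.0, "km": 1.0, "ki": 2.0, "input_rate": 0.2}


def _params_for(flux_id: str, params: Mapping | None, key: str, fallback: float) -> float:
    if params and flux_id in params and key in params[flux_id]:
        return float(params[flux_id][key])
    if params and key in params and not isinstance(params[key], Mapping):
        return float(params[key])
    return fallback


def build_motif(name: str, params: Mapping | None = None) -> PathwayMotif:
    """Construct one of the six named architectures.

    ``params`` may override kinetic constants either globally (keys
    ``vmax``, ``km``, ``ki``, ``input_rate``) or per flux id (nested
    mapping, e.g. ``{"v1": {"vmax": 2.0}}``).

    Architectures (``->`` is a reaction, ``Q`` a controlling locus):

    - ``linear``: in -> S1 -Q1-> S2 -Q2-> S3 -Q3-> out
    - ``merge_bisubstrate``: two chains ``in -> S1 -Q1-> S2`` and
      ``in -> S3 -Q2-> S4`` whose ends combine, ``S2 + S4 -> S5 -> out``;
      neither the merge reaction nor the sink is under genetic control.
    - ``merge_independent``: ``in -> S1 -Q1-> S3`` and ``in -> S2 -Q2-> S3``
      converge on the same species, then ``S3 -Q3-> S4 -> out``.
    - ``branch``: ``in -> S1``; ``S1 -Q1-> S2 -> out`` (upper) and
      ``S1 -Q2-> S3 -> out`` (lower).
    - ``branch_inhibited``: as ``branch`` but the upper flux is inhibited
      by accumulation of its product S2.
    - ``branch_epistasis``: as ``branch`` plus an upstream signal locus Q3
      that interacts with Q1; the (-1, -1) combination abolishes the upper
      flux.
    """
    if name not in MOTIF_NAMES:
        raise ValueError(f"unknown motif {name!r}; expected one of {MOTIF_NAMES}")

    def P(fid: str, key: str, fb_key: str | None = None) -> float:
        return _params_for(fid, params, key, _DEFAULTS[fb_key or key])

    def uni(fid, sub):
        return FluxSpec(fid, "uni_substrate", (sub,), P(fid, "vmax"), (P(fid, "km"),))

    def sink(fid, sub):
        return FluxSpec(fid, "sink", (sub,), P(fid, "vmax"), (P(fid, "km"),))

    def inp(fid):
        return FluxSpec(fid, "input", (), P(fid, "vmax", "input_rate"), ())

    if name == "linear":
        species = ["S1", "S2", "S3"]
        fluxes = [inp("v0"), uni("v1", "S1"), uni("v2", "S2"), sink("v3", "S3")]
        production = {"S1": [("v0", 1.0)], "S2": [("v1", 1.0)], "S3": [("v2", 1.0)]}
        utilization = {"S1": [("v1", 1.0)], "S2": [("v2", 1.0)], "S3": [("v3", 1.0)]}
        loci = {"v1": "Q1", "v2": "Q2", "v3": "Q3"}
        return PathwayMotif(name, species, fluxes, production, utilization, loci)

    if name == "merge_bisubstrate":
        # Diamond: one stochastic source splits into two chains whose
        # products combine in an uncontrolled bi-substrate reaction.  The
        # merge flux tracks the leaner substrate (min of the two branch
        # capacities), so the merge product carries no main-effect QTL.
        species = ["S1", "S2", "S3", "S4"]
        fluxes = [
            inp("v0"),
            uni("v1", "S1"),
            uni("v2", "S1"),
            FluxSpec(
                "v3",
                "bi_substrate",
                ("S2", "S3"),
                P("v3", "vmax"),
                (P("v3", "km"), P("v3", "km")),
            ),
            sink("v4", "S4"),
        ]
        production = {
            "S1": [("v0", 1.0)],
            "S2": [("v1", 1.0)],
            "S3": [("v2", 1.0)],
            "S4": [("v3", 1.0)],
        }
        utilization = {
            "S1": [("v1", 1.0), ("v2", 1.0)],
            "S2": [("v3", 1.0)],
            "S3": [("v3", 1.0)],
            "S4": [("v4", 1.0)],
        }
        loci = {"v1": "Q1", "v2": "Q2"}
        return PathwayMotif(name, species, fluxes, production, utilization, loci)

    if name == "merge_independent":
        # Diamond with two independent uni-substrate reactions converging
        # on the same product; every reaction is genetically controlled,
        # so the QTL pattern mimics the linear chain.
        species = ["S1", "S2", "S3", "S4"]
        fluxes = [
            inp("v0"),
            uni("v1", "S1"),
            uni("v2", "S1"),
            uni("v3", "S2"),
            uni("v4", "S3"),
            sink("v5", "S4"),
        ]
        production = {
            "S1": [("v0", 1.0)],
            "S2": [("v1", 1.0)],
            "S3": [("v2", 1.0)],
            "S4": [("v3", 1.0), ("v4", 1.0)],
        }
        utilization = {
            "S1": [("v1", 1.0), ("v2", 1.0)],
            "S2": [("v3", 1.0)],
            "S3": [("v4", 1.0)],
            "S4": [("v5", 1.0)],
        }
        loci = {"v1": "Q1", "v2": "Q2", "v3": "Q3", "v4": "Q4", "v5": "Q5"}
        return PathwayMotif(name, species, fluxes, production, utilization, loci)

    # the three branch variants share a backbone
    species = ["S1", "S2", "S3"]
    production = {"S1": [("v0", 1.0)], "S2": [("v1", 1.0)], "S3": [("v2", 1.0)]}
    utilization = {
        "S1": [("v1", 1.0), ("v2", 1.0)],
        "S2": [("v3", 1.0)],
        "S3": [("v4", 1.0)],
    }
    lower = uni("v2", "S1")
    sinks = [sink("v3", "S2"), sink("v4", "S3")]
    loci = {"v1": "Q1", "v2": "Q2"}

    if name == "branch":
        fluxes = [inp("v0"), uni("v1", "S1"), lower] + sinks
        return PathwayMotif(name, species, fluxes, production, utilization, loci)

    if name == "branch_inhibited":
        # Defaults place the operating point in the inhibited regime: the
        # lower branch runs near saturation (small km, capacity below the
        # input rate) so flux balance pins the upper flux and the upper
        # locus loses most of its leverage on the endpoint concentrations.
        upper = FluxSpec(
            "v1",
            "substrate_inhibited",
            ("S1",),
            P("v1", "vmax"),
            (P("v1", "km"),),
            ki=_params_for("v1", params, "ki", 0.5),
            inhibitor="S1",
        )
        lower_sat = FluxSpec(
            "v2",
            "uni_substrate",
            ("S1",),
            _params_for("v2", params, "vmax", 0.12),
            (_params_for("v2", params, "km", 0.05),),
        )
        inp_e = FluxSpec("v0", "input", (), _params_for("v0", params, "vmax", 0.25), ())
        fluxes = [inp_e, upper, lower_sat] + sinks
        return PathwayMotif(name, species, fluxes, production, utilization, loci)

    # branch_epistasis
    fluxes = [inp("v0"), uni("v1", "S1"), lower] + sinks
    rule = EpistasisRule(
        loci=("Q3", "Q1"),
        null_combinations=frozenset({(-1, -1)}),
        target_flux="v1",
    )
    return PathwayMotif(
        name,
        species,
        fluxes,
        production,
        utilization,
        loci,
        signal_loci=["Q3"],
        epistasis=rule,
    )
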