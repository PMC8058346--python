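"""Reading and writing metabolic models, thermodynamic annotations, and lump reports.

Models are held in a lightweight container built around a sparse
stoichiometric matrix.  Two on-disk formats are supported: SBML Level 3
with the FBC extension (parsed through cobrapy) and a minimal JSON dialect
mirroring the COBRA JSON schema (ids, stoichiometry dictionaries, bounds,
objective coefficient) so that desk-scale fixtures need no XML.

Thermodynamic annotations are tab-separated tables mapping metabolite ids
to standard Gibbs free energies of formation (kJ/mol), with explicit gaps:
a metabolite absent from the table, or annotated ``NA``, has unknown
formation energy.  Reaction-level standard Gibbs energy overrides may mark
a reaction as thermodynamically determined even when a participant lacks a
formation energy.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Model",
    "ThermoData",
    "Lump",
    "LumpReport",
    "ModelFormatError",
    "ThermoFormatError",
    "read_model",
    "write_model_json",
    "read_thermo",
    "write_thermo",
    "write_lump_report",
    "read_lump_report",
]

#: coefficients below this magnitude are treated as exact zeros when
#: validating lump stoichiometries (LP solvers return floats)
ZERO_TOL = 1e-9


class ModelFormatError(ValueError):
    """Raised when a model file cannot be interpreted."""


class ThermoFormatError(ValueError):
    """Raised when a thermodynamic annotation table is malformed."""


@dataclass
class Model:
    """A stoichiometric model: S is m metabolites x n reactions.

    Bounds are in arbitrary but consistent flux units.  ``compartments``
    maps each metabolite id to its compartment.  ``split_pairs`` records
    reversible reactions that have been split into irreversible halves
    (original id -> (forward id, reverse id)); it is empty on freshly read
    models.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sp.csc_array
    lb: np.ndarray
    ub: np.ndarray
    compartments: dict[str, str]
    objective_reaction: str
    split_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = sp.csc_array(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self._met_index = {m: i for i, m in enumerate(self.metabolite_ids)}
        self._rxn_index = {r: j for j, r in enumerate(self.reaction_ids)}
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def met_index(self, met_id: str) -> int:
        return self._met_index[met_id]

    def rxn_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def reaction_stoichiometry(self, rxn_id: str) -> dict[str, float]:
        """Nonzero stoichiometry of one reaction as metabolite -> coefficient."""
        j = self.rxn_index(rxn_id)
        col = self.S[:, [j]].tocoo()
        return {self.metabolite_ids[i]: v for i, v in zip(col.row, col.data)}

    def split_base(self, rxn_id: str) -> tuple[str, int]:
        """Map a (possibly split) reaction id to (original id, direction).

        Direction is +1 for the forward half or an unsplit reaction and -1
        for the reverse half.
        """
        for orig, (fwd, rev) in self.split_pairs.items():
            if rxn_id == fwd:
                return orig, +1
            if rxn_id == rev:
                return orig, -1
        return rxn_id, +1

    def validate(self) -> None:
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ModelFormatError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise ModelFormatError("duplicate reaction ids")
        if self.S.shape != (self.n_metabolites, self.n_reactions):
            raise ModelFormatError(
                f"S has shape {self.S.shape}, expected "
                f"({self.n_metabolites}, {self.n_reactions})"
            )
        if self.objective_reaction not in self._rxn_index:
            raise ModelFormatError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )
        if self.lb.shape != (self.n_reactions,) or self.ub.shape != (self.n_reactions,):
            raise ModelFormatError("bound vectors must have one entry per reaction")
        if np.any(self.lb > self.ub):
            raise ModelFormatError("lower bound exceeds upper bound")

    def copy(self) -> "Model":
        return Model(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            compartments=dict(self.compartments),
            objective_reaction=self.objective_reaction,
            split_pairs=dict(self.split_pairs),
        )


@dataclass
class ThermoData:
    """Partial thermodynamic annotation of a model.

    ``dfG0`` maps metabolite ids to standard Gibbs free energies of
    formation (kJ/mol); metabolites absent from the map are of unknown
    formation energy.  ``dG0_override`` optionally fixes the standard
    Gibbs energy change of whole reactions, marking them determined even
    if a participant has no formation energy.
    """

    dfG0: dict[str, float] = field(default_factory=dict)
    dG0_override: dict[str, float] = field(default_factory=dict)

    def unknown_metabolites(self, model: Model) -> set[str]:
        return {m for m in model.metabolite_ids if m not in self.dfG0}

    def has_override(self, model: Model, rxn_id: str) -> bool:
        if rxn_id in self.dG0_override:
            return True
        base, _ = model.split_base(rxn_id)
        return base in self.dG0_override

    def reaction_dG0(self, model: Model, rxn_id: str) -> float | None:
        """Standard Gibbs energy change of a reaction, or None if undetermined.

        A reaction-level override wins; for the reverse half of a split
        reversible reaction the override changes sign.  Otherwise the value
        is the stoichiometry-weighted sum of formation energies, available
        only when every participant is annotated.
        """
        if rxn_id in self.dG0_override:
            return self.dG0_override[rxn_id]
        base, direction = model.split_base(rxn_id)
        if base in self.dG0_override:
            return direction * self.dG0_override[base]
        total = 0.0
        for met, coef in model.reaction_stoichiometry(rxn_id).items():
            if met not in self.dfG0:
                return None
            total += coef * self.dfG0[met]
        return total

    def unknown_reactions(self, model: Model) -> set[str]:
        """Reactions whose standard Gibbs energy change cannot be computed.

        A reaction is undetermined iff it has no override and touches at
        least one metabolite of unknown formation energy.
        """
        unknown_mets = self.unknown_metabolites(model)
        out = set()
        for rxn in model.reaction_ids:
            if self.has_override(model, rxn):
                continue
            if any(m in unknown_mets for m in model.reaction_stoichiometry(rxn)):
                out.add(rxn)
        return out


@dataclass
class Lump:
    """One lumped reaction: a nonnegative combination of model reactions."""

    lump_id: str
    composition: dict[str, float]  # primitive reaction id -> alpha
    net: dict[str, float]  # metabolite id -> net coefficient
    eliminated: list[str]  # unknown metabolites this lump eliminates
    group: int = -1  # index of the originating metabolite group
    dG0: float | None = None  # kJ/mol, when computable


@dataclass
class LumpReport:
    """Serializable result of a lumping run."""

    lumps: list[Lump] = field(default_factory=list)
    eliminated: list[str] = field(default_factory=list)
    stats: dict = field(default_factory=dict)

    def validate(self, unknown_metabolites: set[str] | None = None) -> None:
        for lump in self.lumps:
            for alpha in lump.composition.values():
                if alpha < -ZERO_TOL:
                    raise ValueError(f"{lump.lump_id}: negative coefficient {alpha}")
            if unknown_metabolites is not None:
                for met, coef in lump.net.items():
                    if met in unknown_metabolites and abs(coef) > ZERO_TOL:
                        raise ValueError(
                            f"{lump.lump_id}: unknown metabolite {met} has "
                            f"nonzero net coefficient {coef}"
                        )


# ---------------------------------------------------------------------------
# model reading
# ---------------------------------------------------------------------------

def read_model(path: str | Path, format: str = "json") -> Model:
    """Read a metabolic model from ``path`` in the named format.

    ``format`` is ``"json"`` for the minimal COBRA-style JSON dialect or
    ``"sbml"`` for SBML L3/FBC.  The objective (biomass) reaction must be
    flagged explicitly; a model without one is rejected rather than
    silently defaulting.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json":
        return _read_model_json(path)
    if format == "sbml":
        return _read_model_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def _read_model_json(path: Path) -> Model:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON: {exc}") from exc
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelFormatError(f"{path}: missing top-level key {key!r}")
    met_ids, compartments = [], {}
    for entry in doc["metabolites"]:
        if "id" not in entry:
            raise ModelFormatError(f"{path}: metabolite without id: {entry}")
        met_ids.append(entry["id"])
        compartments[entry["id"]] = entry.get(
            "compartment", _compartment_from_id(entry["id"])
        )
    met_index = {m: i for i, m in enumerate(met_ids)}
    rxn_ids, lb, ub = [], [], []
    rows, cols, data = [], [], []
    objective = None
    for j, entry in enumerate(doc["reactions"]):
        if "id" not in entry:
            raise ModelFormatError(f"{path}: reaction without id: {entry}")
        rid = entry["id"]
        rxn_ids.append(rid)
        lb.append(float(entry.get("lower_bound", 0.0)))
        ub.append(float(entry.get("upper_bound", 1000.0)))
        for met, coef in entry.get("metabolites", {}).items():
            if met not in met_index:
                raise ModelFormatError(
                    f"{path}: reaction {rid} references unknown metabolite {met!r}"
                )
            rows.append(met_index[met])
            cols.append(j)
            data.append(float(coef))
        if entry.get("objective_coefficient", 0):
            objective = rid
    if objective is None:
        raise ModelFormatError(
            f"{path}: no reaction carries a nonzero objective_coefficient"
        )
    S = sp.csc_array(
        (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids)), dtype=float
    )
    return Model(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        compartments=compartments,
        objective_reaction=objective,
    )


def _read_model_sbml(path: Path) -> Model:
    import cobra.io

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise ModelFormatError(f"{path}: SBML parse failure: {exc}") from exc
    met_ids = [m.id for m in cmodel.metabolites]
    compartments = {m.id: (m.compartment or _compartment_from_id(m.id))
                    for m in cmodel.metabolites}
    met_index = {m: i for i, m in enumerate(met_ids)}
    rxn_ids, lb, ub = [], [], []
    rows, cols, data = [], [], []
    objective = None
    for j, rxn in enumerate(cmodel.reactions):
        rxn_ids.append(rxn.id)
        lb.append(rxn.lower_bound)
        ub.append(rxn.upper_bound)
        if rxn.objective_coefficient:
            objective = rxn.id
        for met, coef in rxn.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            data.append(float(coef))
    if objective is None:
        raise ModelFormatError(f"{path}: SBML model declares no FBC objective")
    S = sp.csc_array(
        (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids)), dtype=float
    )
    return Model(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lb=np.array(lb),
        ub=np.array(ub),
        compartments=compartments,
        objective_reaction=objective,
    )


def _compartment_from_id(met_id: str) -> str:
    # BiGG convention: trailing "_<compartment>" suffix
    if "_" in met_id:
        return met_id.rsplit("_", 1)[1]
    return ""


def write_model_json(model: Model, path: str | Path) -> None:
    """Write a model in the JSON dialect understood by :func:`read_model`."""
    doc = {
        "metabolites": [
            {"id": m, "compartment": model.compartments.get(m, "")}
            for m in model.metabolite_ids
        ],
        "reactions": [],
    }
    for rid in model.reaction_ids:
        j = model.rxn_index(rid)
        doc["reactions"].append(
            {
                "id": rid,
                "metabolites": model.reaction_stoichiometry(rid),
                "lower_bound": model.lb[j],
                "upper_bound": model.ub[j],
                "objective_coefficient": 1.0 if rid == model.objective_reaction else 0.0,
            }
        )
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# thermodynamic annotations
# ---------------------------------------------------------------------------

def read_thermo(path: str | Path, model: Model | None = None) -> ThermoData:
    """Read a TSV of formation energies (and optional reaction overrides).

    Expected columns: ``metabolite_id`` and ``dfG0_kJ_per_mol``; an empty
    cell or ``NA`` marks the value unknown.  Rows whose first column is
    ``reaction:<id>`` are interpreted as reaction-level standard Gibbs
    energy overrides.  Ids that do not occur in ``model`` produce warnings,
    not errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dfG0: dict[str, float] = {}
    overrides: dict[str, float] = {}
    seen: set[str] = set()
    with path.open() as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:2] != ["metabolite_id", "dfG0_kJ_per_mol"]:
            raise ThermoFormatError(
                f"{path}: expected header 'metabolite_id\\tdfG0_kJ_per_mol', "
                f"got {header!r}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            key = parts[0]
            raw = parts[1].strip() if len(parts) > 1 else ""
            if key in seen:
                raise ThermoFormatError(f"{path}:{lineno}: duplicate id {key!r}")
            seen.add(key)
            if raw in ("", "NA", "NaN", "nan"):
                continue
            try:
                value = float(raw)
            except ValueError as exc:
                raise ThermoFormatError(
                    f"{path}:{lineno}: malformed numeric value {raw!r}"
                ) from exc
            if math.isnan(value):
                continue
            if key.startswith("reaction:"):
                overrides[key[len("reaction:"):]] = value
            else:
                dfG0[key] = value
    thermo = ThermoData(dfG0=dfG0, dG0_override=overrides)
    if model is not None:
        stray_mets = set(dfG0) - set(model.metabolite_ids)
        stray_rxns = set(overrides) - set(model.reaction_ids)
        if stray_mets:
            warnings.warn(
                f"{path}: {len(stray_mets)} annotated metabolites not in model: "
                f"{sorted(stray_mets)[:5]}...",
                stacklevel=2,
            )
        if stray_rxns:
            warnings.warn(
                f"{path}: {len(stray_rxns)} reaction overrides not in model",
                stacklevel=2,
            )
    return thermo


def write_thermo(thermo: ThermoData, path: str | Path) -> None:
    lines = ["metabolite_id\tdfG0_kJ_per_mol"]
    for met, val in thermo.dfG0.items():
        lines.append(f"{met}\t{val!r}")
    for rxn, val in thermo.dG0_override.items():
        lines.append(f"reaction:{rxn}\t{val!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# lump reports
# ---------------------------------------------------------------------------

def write_lump_report(report: LumpReport, out_dir: str | Path) -> None:
    """Write a lump report as two TSVs plus a JSON stats block.

    ``lump_composition.tsv`` holds one row per (lump, member reaction,
    alpha); ``lump_stoichiometry.tsv`` one row per (lump, metabolite, net
    coefficient); ``lump_stats.json`` carries run statistics, eliminated
    metabolites, group provenance and lump standard Gibbs energies.  The
    triple round-trips losslessly through :func:`read_lump_report`.
    """
    report.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comp_lines = ["lump_id\treaction_id\talpha"]
    stoich_lines = ["lump_id\tmetabolite_id\tcoefficient"]
    meta = {}
    for lump in report.lumps:
        for rxn, alpha in sorted(lump.composition.items()):
            comp_lines.append(f"{lump.lump_id}\t{rxn}\t{alpha!r}")
        for met, coef in sorted(lump.net.items()):
            stoich_lines.append(f"{lump.lump_id}\t{met}\t{coef!r}")
        meta[lump.lump_id] = {
            "eliminated": lump.eliminated,
            "group": lump.group,
            "dG0": lump.dG0,
        }
    (out_dir / "lump_composition.tsv").write_text("\n".join(comp_lines) + "\n")
    (out_dir / "lump_stoichiometry.tsv").write_text("\n".join(stoich_lines) + "\n")
    stats = {"stats": report.stats, "eliminated": sorted(report.eliminated),
             "lumps": meta}
    (out_dir / "lump_stats.json").write_text(json.dumps(stats, indent=1, sort_keys=True))


def read_lump_report(out_dir: str | Path) -> LumpReport:
    """Inverse of :func:`write_lump_report`."""
    out_dir = Path(out_dir)
    comp: dict[str, dict[str, float]] = {}
    for line in (out_dir / "lump_composition.tsv").read_text().splitlines()[1:]:
        if not line:
            continue
        lump_id, rxn, alpha = line.split("\t")
        comp.setdefault(lump_id, {})[rxn] = float(alpha)
    net: dict[str, dict[str, float]] = {}
    for line in (out_dir / "lump_stoichiometry.tsv").read_text().splitlines()[1:]:
        if not line:
            continue
        lump_id, met, coef = line.split("\t")
        net.setdefault(lump_id, {})[met] = float(coef)
    stats = json.loads((out_dir / "lump_stats.json").read_text())
    lumps = []
    for lump_id in sorted(set(comp) | set(net) | set(stats["lumps"])):
        meta = stats["lumps"].get(lump_id, {})
        lumps.append(
            Lump(
                lump_id=lump_id,
                composition=comp.get(lump_id, {}),
                net=net.get(lump_id, {}),
                eliminated=meta.get("eliminated", []),
                group=meta.get("group", -1),
                dG0=meta.get("dG0"),
            )
        )
    return LumpReport(lumps=lumps, eliminated=stats["eliminated"], stats=stats["stats"])
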