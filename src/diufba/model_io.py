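"""Model and configuration I/O.

Reads and writes stoichiometric models in SBML Level 3 + FBC, COBRA-style
JSON, and a minimal TSV reaction-table dialect, and diurnal configurations
in YAML/JSON.  The in-memory representation is :class:`MetabolicNetwork`,
a thin validated wrapper around a sparse stoichiometric matrix; SBML and
JSON serialization is delegated to cobrapy.

Sign convention throughout: consumed < 0, produced > 0; reversibility is
encoded purely by the sign of the lower bound.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import yaml


class ModelFormatError(ValueError):
    """A file could not be parsed under the named standard."""


class ModelValidationError(ValueError):
    """A parsed model violates a structural invariant."""


class ConfigError(ValueError):
    """A diurnal configuration is malformed or inconsistent with the model."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MetabolicNetwork:
    """A stoichiometric network: species x reactions matrix plus flux bounds.

    Parameters
    ----------
    species_ids, reaction_ids
        Ordered unique identifiers.  All matrix indices in the package refer
        to these orders, which are preserved exactly as read.
    stoich
        Sparse ``s x r`` matrix of stoichiometric coefficients.
    lb, ub
        Per-reaction flux bounds (mmol/gDCW/h, or M/h for the toy model).
    objective_coeffs
        Per-reaction objective weights for single-phase FBA.
    species_meta
        Optional per-species metadata: ``{"compartment": ..., "name": ...}``.
    placeholder_reactions
        Reaction ids explicitly allowed to have all-zero columns.
    """

    species_ids: list[str]
    reaction_ids: list[str]
    stoich: sp.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    objective_coeffs: np.ndarray
    species_meta: dict[str, dict] = field(default_factory=dict)
    placeholder_reactions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.stoich = sp.csc_matrix(self.stoich, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.objective_coeffs = np.asarray(self.objective_coeffs, dtype=float)
        self.validate()

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def species_index(self, species_id: str) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise KeyError(f"unknown species id {species_id!r}") from None

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    def validate(self) -> None:
        s, r = self.stoich.shape
        if len(self.species_ids) != s:
            raise ModelValidationError(
                f"{len(self.species_ids)} species ids but {s} matrix rows")
        if len(self.reaction_ids) != r:
            raise ModelValidationError(
                f"{len(self.reaction_ids)} reaction ids but {r} matrix columns")
        if len(set(self.species_ids)) != s:
            raise ModelValidationError("duplicate species identifiers")
        if len(set(self.reaction_ids)) != r:
            raise ModelValidationError("duplicate reaction identifiers")
        if self.lb.shape != (r,) or self.ub.shape != (r,):
            raise ModelValidationError("bound vectors must have one entry per reaction")
        if self.objective_coeffs.shape != (r,):
            raise ModelValidationError("objective vector must have one entry per reaction")
        bad = np.nonzero(self.lb > self.ub)[0]
        if bad.size:
            rid = self.reaction_ids[bad[0]]
            raise ModelValidationError(
                f"lb > ub for reaction {rid!r} ({self.lb[bad[0]]} > {self.ub[bad[0]]})")
        col_nnz = np.diff(self.stoich.indptr)
        for j in np.nonzero(col_nnz == 0)[0]:
            if self.reaction_ids[j] not in self.placeholder_reactions:
                raise ModelValidationError(
                    f"reaction {self.reaction_ids[j]!r} has an all-zero column "
                    "and is not flagged as a placeholder")

    def equation(self, reaction_id: str) -> str:
        """Human-readable equation string in the TSV dialect."""
        j = self.reaction_index(reaction_id)
        col = self.stoich.getcol(j).tocoo()
        lhs, rhs = [], []
        for i, coeff in sorted(zip(col.row, col.data)):
            term = self.species_ids[i]
            mag = abs(coeff)
            if not math.isclose(mag, 1.0, rel_tol=0, abs_tol=0):
                term = f"{_fmt(mag)} {term}"
            (lhs if coeff < 0 else rhs).append(term)
        arrow = "<=>" if self.lb[j] < 0 else "->"
        return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


@dataclass
class Phase:
    """One quasi-steady-state interval of the diurnal cycle."""

    name: str
    duration: float  # hours
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class DiurnalConfig:
    """Diurnal cycle specification: phases, carry-over and export species.

    ``carryover_species`` get a transfer column linking the two phase
    blocks; ``exportable_species`` (a subset) additionally get an export
    column that removes the species from the final phase, modelling
    accumulation beyond the cycle.  ``objective`` maps
    ``(phase_name, reaction_id)`` or ``("export", species_id)`` to a weight.
    ``transfer_bounds`` optionally bounds individual transfer amounts
    (species_id -> (lb, ub)); the default is unbounded reversible.
    """

    phases: list[Phase]
    carryover_species: list[str] = field(default_factory=list)
    exportable_species: list[str] = field(default_factory=list)
    objective: dict[tuple[str, str], float] = field(default_factory=dict)
    transfer_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.phases:
            raise ConfigError("at least one phase is required")
        names = [p.name for p in self.phases]
        if len(set(names)) != len(names):
            raise ConfigError("phase names must be unique")
        for p in self.phases:
            if not p.duration > 0:
                raise ConfigError(f"phase {p.name!r} has nonpositive duration {p.duration}")
        extra = set(self.exportable_species) - set(self.carryover_species)
        if extra:
            raise ConfigError(
                f"exportable species must be carry-over species; offending: {sorted(extra)}")
        extra = set(self.transfer_bounds) - set(self.carryover_species)
        if extra:
            raise ConfigError(
                f"transfer bounds given for non-carry-over species: {sorted(extra)}")

    def validate_against(self, network: MetabolicNetwork) -> None:
        known = set(network.species_ids)
        for sid in self.carryover_species:
            if sid not in known:
                raise ConfigError(f"carry-over species {sid!r} not in the model")
        rxns = set(network.reaction_ids)
        for p in self.phases:
            for rid in p.bound_overrides:
                if rid not in rxns:
                    raise ConfigError(
                        f"bound override for unknown reaction {rid!r} in phase {p.name!r}")
        for (kind, target), _w in self.objective.items():
            if kind == "export":
                if target not in self.exportable_species:
                    raise ConfigError(
                        f"objective on export of {target!r}, which is not exportable")
            elif kind == "transfer":
                if target not in self.carryover_species:
                    raise ConfigError(
                        f"objective on transfer of {target!r}, which is not carry-over")
            else:
                if kind not in {p.name for p in self.phases}:
                    raise ConfigError(f"objective references unknown phase {kind!r}")
                if target not in rxns:
                    raise ConfigError(f"objective references unknown reaction {target!r}")


# ---------------------------------------------------------------------------
# TSV reaction-table dialect
# ---------------------------------------------------------------------------
#
# Columns: reaction_id <TAB> equation <TAB> lb <TAB> ub <TAB> objective.
# Equations use " + "-separated terms, "->" (irreversible) or "<=>"
# (reversible), with an optional numeric coefficient prefix (default 1).
# An empty side denotes an exchange with the environment.

_TSV_HEADER = ["reaction_id", "equation", "lb", "ub", "objective"]


def _fmt(x: float) -> str:
    """Serialize a coefficient with enough digits for a lossless round-trip."""
    x = float(x)
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def _parse_side(side: str, line_no: int) -> list[tuple[str, float]]:
    side = side.strip()
    if not side:
        return []
    out = []
    for term in side.split(" + "):
        parts = term.strip().split()
        if len(parts) == 1:
            out.append((parts[0], 1.0))
        elif len(parts) == 2:
            try:
                coeff = float(parts[0])
            except ValueError:
                raise ModelFormatError(
                    f"line {line_no}: bad coefficient {parts[0]!r} in term {term!r}") from None
            out.append((parts[1], coeff))
        else:
            raise ModelFormatError(f"line {line_no}: cannot parse term {term!r}")
    return out


def parse_equation(equation: str, line_no: int = 0) -> tuple[dict[str, float], bool]:
    """Parse an equation string into ``{species: coefficient}`` + reversibility."""
    if "<=>" in equation:
        arrow, reversible = "<=>", True
    elif "->" in equation:
        arrow, reversible = "->", False
    else:
        raise ModelFormatError(f"line {line_no}: no '->' or '<=>' arrow in {equation!r}")
    lhs_s, rhs_s = equation.split(arrow, 1)
    coeffs: dict[str, float] = {}
    for sid, c in _parse_side(lhs_s, line_no):
        coeffs[sid] = coeffs.get(sid, 0.0) - c
    for sid, c in _parse_side(rhs_s, line_no):
        coeffs[sid] = coeffs.get(sid, 0.0) + c
    coeffs = {sid: c for sid, c in coeffs.items() if c != 0.0}
    return coeffs, reversible


def _read_tsv(path: Path) -> MetabolicNetwork:
    lines = path.read_text().splitlines()
    # optional "# species: A B C" comment pins the row order; otherwise
    # rows follow first appearance in the equations
    declared_order: list[str] | None = None
    body = []
    for raw in lines:
        if raw.startswith("#"):
            stripped = raw.lstrip("#").strip()
            if stripped.startswith("species:"):
                declared_order = stripped[len("species:"):].split()
            continue
        body.append(raw)
    lines = body
    if not lines:
        raise ModelFormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if [h.strip() for h in header] != _TSV_HEADER:
        raise ModelFormatError(
            f"{path}: line 1: expected header {_TSV_HEADER}, got {header}")
    species: list[str] = list(declared_order or [])
    seen_species: set[str] = set(species)
    if len(seen_species) != len(species):
        raise ModelValidationError(f"{path}: duplicate ids in species comment")
    reaction_ids, lbs, ubs, objs = [], [], [], []
    entries: list[dict[str, float]] = []
    for ln, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 5:
            raise ModelFormatError(f"{path}: line {ln}: expected 5 columns, got {len(fields)}")
        rid, eqn, lb_s, ub_s, obj_s = (f.strip() for f in fields)
        if rid in reaction_ids:
            raise ModelValidationError(f"{path}: line {ln}: duplicate reaction id {rid!r}")
        coeffs, _rev = parse_equation(eqn, ln)
        try:
            lb, ub, obj = float(lb_s), float(ub_s), float(obj_s)
        except ValueError:
            raise ModelFormatError(f"{path}: line {ln}: non-numeric bound/objective") from None
        for sid in coeffs:
            if sid not in seen_species:
                seen_species.add(sid)
                species.append(sid)
        reaction_ids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        objs.append(obj)
        entries.append(coeffs)
    mat = sp.dok_matrix((len(species), len(reaction_ids)), dtype=float)
    sidx = {sid: i for i, sid in enumerate(species)}
    for j, coeffs in enumerate(entries):
        for sid, c in coeffs.items():
            mat[sidx[sid], j] = c
    return MetabolicNetwork(
        species_ids=species, reaction_ids=reaction_ids, stoich=mat.tocsc(),
        lb=np.array(lbs), ub=np.array(ubs), objective_coeffs=np.array(objs))


def _write_tsv(network: MetabolicNetwork, path: Path) -> None:
    rows = ["# species: " + " ".join(network.species_ids),
            "\t".join(_TSV_HEADER)]
    for j, rid in enumerate(network.reaction_ids):
        rows.append("\t".join([
            rid,
            network.equation(rid),
            _fmt(network.lb[j]),
            _fmt(network.ub[j]),
            _fmt(network.objective_coeffs[j]),
        ]))
    path.write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# cobra bridge (SBML-FBC and COBRA-JSON)
# ---------------------------------------------------------------------------

def _from_cobra(model) -> MetabolicNetwork:
    species_ids = [m.id for m in model.metabolites]
    reaction_ids = [r.id for r in model.reactions]
    sidx = {sid: i for i, sid in enumerate(species_ids)}
    mat = sp.dok_matrix((len(species_ids), len(reaction_ids)), dtype=float)
    lbs, ubs, objs = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.metabolites.items():
            mat[sidx[met.id], j] = float(coeff)
        lbs.append(rxn.lower_bound)
        ubs.append(rxn.upper_bound)
        objs.append(rxn.objective_coefficient)
    meta = {m.id: {"compartment": m.compartment or "", "name": m.name or ""}
            for m in model.metabolites}
    return MetabolicNetwork(
        species_ids=species_ids, reaction_ids=reaction_ids, stoich=mat.tocsc(),
        lb=np.array(lbs), ub=np.array(ubs), objective_coeffs=np.array(objs),
        species_meta=meta)


def _to_cobra(network: MetabolicNetwork):
    import cobra

    model = cobra.Model("diufba_model")
    mets = []
    for sid in network.species_ids:
        meta = network.species_meta.get(sid, {})
        m = cobra.Metabolite(sid, name=meta.get("name", sid),
                             compartment=meta.get("compartment") or "c")
        mets.append(m)
    model.add_metabolites(mets)
    rxns = []
    for j, rid in enumerate(network.reaction_ids):
        # plain Python floats: libsbml rejects numpy scalars
        r = cobra.Reaction(rid, lower_bound=float(network.lb[j]),
                           upper_bound=float(network.ub[j]))
        rxns.append(r)
    model.add_reactions(rxns)
    for j, rid in enumerate(network.reaction_ids):
        col = network.stoich.getcol(j).tocoo()
        model.reactions.get_by_id(rid).add_metabolites(
            {mets[i]: c for i, c in zip(col.row, col.data)})
    objective = {}
    for j, rid in enumerate(network.reaction_ids):
        if network.objective_coeffs[j] != 0:
            objective[model.reactions.get_by_id(rid)] = network.objective_coeffs[j]
    if objective:
        model.objective = {r: w for r, w in objective.items()}
    return model


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in {"sbml-fbc", "json", "tsv"}:
            raise ValueError(f"unknown model format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".xml", ".sbml"}:
        return "sbml-fbc"
    if suffix == ".json":
        return "json"
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    raise ValueError(f"cannot infer model format from {path.name!r}; pass format=")


def read_model(path: str | Path, format: str | None = None) -> MetabolicNetwork:
    """Read a stoichiometric model from SBML-FBC, COBRA-JSON, or TSV.

    The format is inferred from the file extension when not given.
    Species and reaction order is preserved as read; all matrix indices in
    the package refer to these orders.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        return _read_tsv(path)
    import cobra.io

    try:
        if fmt == "sbml-fbc":
            model = cobra.io.read_sbml_model(str(path))
        else:
            model = cobra.io.load_json_model(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # cobra raises various parser exceptions
        raise ModelFormatError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    return _from_cobra(model)


def write_model(network: MetabolicNetwork, path: str | Path,
                format: str | None = None) -> None:
    """Write a model so that :func:`read_model` round-trips it losslessly."""
    network.validate()
    if network.n_reactions == 0 or network.n_species == 0:
        raise ModelValidationError("refusing to write an empty network")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        _write_tsv(network, path)
        return
    import cobra.io

    model = _to_cobra(network)
    if fmt == "sbml-fbc":
        cobra.io.write_sbml_model(model, str(path))
    else:
        cobra.io.save_json_model(model, str(path))


# ---------------------------------------------------------------------------
# Diurnal configuration (YAML / JSON)
# ---------------------------------------------------------------------------

def _parse_objective_key(key: str) -> tuple[str, str]:
    if ":" not in key:
        raise ConfigError(
            f"objective key {key!r} must be '<phase>:<reaction>', "
            "'transfer:<species>' or 'export:<species>'")
    kind, target = key.split(":", 1)
    return kind.strip(), target.strip()


def read_diurnal_config(path: str | Path,
                        network: MetabolicNetwork | None = None) -> DiurnalConfig:
    """Read a diurnal configuration (YAML or JSON).

    Schema::

        phases:
          - {name: light, duration: 1.0, bounds: {EX_sub: [0, 1]}}
          - {name: dark,  duration: 1.0, bounds: {EX_sub: [0, 0]}}
        carryover_species: [STO, BIO]
        exportable_species: [BIO]
        objective: {"export:BIO": 1.0}
        transfer_bounds: {STO: [0, 0.05]}     # optional

    If ``network`` is given, species and reaction references are checked
    against it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    try:
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: cannot parse: {exc}") from exc
    if not isinstance(data, dict) or "phases" not in data:
        raise ConfigError(f"{path}: missing required key 'phases'")
    phases = []
    for entry in data["phases"]:
        try:
            name = entry["name"]
            duration = float(entry["duration"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: malformed phase entry {entry!r}") from exc
        overrides = {rid: (float(b[0]), float(b[1]))
                     for rid, b in (entry.get("bounds") or {}).items()}
        phases.append(Phase(name=name, duration=duration, bound_overrides=overrides))
    objective = {_parse_objective_key(k): float(w)
                 for k, w in (data.get("objective") or {}).items()}
    transfer_bounds = {sid: (float(b[0]), float(b[1]))
                       for sid, b in (data.get("transfer_bounds") or {}).items()}
    config = DiurnalConfig(
        phases=phases,
        carryover_species=list(data.get("carryover_species") or []),
        exportable_species=list(data.get("exportable_species") or []),
        objective=objective,
        transfer_bounds=transfer_bounds,
    )
    if network is not None:
        config.validate_against(network)
    return config


def write_diurnal_config(config: DiurnalConfig, path: str | Path) -> None:
    """Write a configuration in the YAML schema of :func:`read_diurnal_config`."""
    data = {
        "phases": [
            {"name": p.name, "duration": p.duration,
             "bounds": {rid: list(b) for rid, b in p.bound_overrides.items()}}
            for p in config.phases
        ],
        "carryover_species": list(config.carryover_species),
        "exportable_species": list(config.exportable_species),
        "objective": {f"{k}:{t}": w for (k, t), w in config.objective.items()},
        "transfer_bounds": {sid: list(b) for sid, b in config.transfer_bounds.items()},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
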