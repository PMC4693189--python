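"""Construction of the extended diurnal stoichiometric problem.

The diurnal cycle is split into two quasi-steady-state phases (light and
dark).  The base stoichiometric matrix ``S`` (s x r) is replicated once per
phase along the block diagonal of an extended matrix, and the two blocks
are coupled by

* a transfer matrix ``T`` (2s x p): one column per carry-over species,
  moving an amount out of the light-phase balance (-1) and into the
  dark-phase balance (+1); transfer reactions are reversible, so storage
  can in principle flow in either direction, and

* an export matrix (2s x q): one column per exportable species, removing
  an amount from the dark-phase balance (-1) to model accumulation beyond
  the diurnal cycle (long-term storage, biomass growth).

All variables of the extended problem are time-integrated concentration
changes (mmol/gDCW per phase), not rates: a flux bound ``v`` over a phase
of duration ``dt`` becomes a concentration-change bound ``v * dt``.
Per-phase fluxes are recovered by dividing by the phase duration.

Column order: light reactions (r), transfers (p), dark reactions (r),
exports (q) — total 2r + p + q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .model_io import ConfigError, DiurnalConfig, MetabolicNetwork


class UnsupportedConfigurationError(ConfigError):
    """Raised for configurations outside the validated two-phase path."""


# column-map entry kinds
PHASE = "phase"
TRANSFER = "transfer"
EXPORT = "export"


@dataclass
class ExtendedProblem:
    """The assembled diurnal LP data.

    ``col_map`` maps every column index to ``(PHASE, phase_index,
    reaction_id)``, ``(TRANSFER, species_id)`` or ``(EXPORT, species_id)``.
    Row ``k*s + i`` is species ``i`` in phase ``k``.
    """

    S_ext: sp.csc_matrix
    v_lb: np.ndarray
    v_ub: np.ndarray
    w: np.ndarray
    col_map: list[tuple]
    phase_names: list[str]
    phase_durations: list[float]
    network: MetabolicNetwork = field(repr=False)
    config: DiurnalConfig = field(repr=False)

    @property
    def n_cols(self) -> int:
        return self.S_ext.shape[1]

    def column_name(self, j: int) -> str:
        """Readable column identifier, e.g. ``light:R_bio`` or ``transfer:STO``."""
        entry = self.col_map[j]
        if entry[0] == PHASE:
            return f"{self.phase_names[entry[1]]}:{entry[2]}"
        return f"{entry[0]}:{entry[1]}"

    def column_index(self, name: str) -> int:
        """Inverse of :meth:`column_name`; raises ``KeyError`` if absent."""
        for j in range(self.n_cols):
            if self.column_name(j) == name:
                return j
        raise KeyError(f"no extended-problem column named {name!r}")


def build_transfer_matrix(network: MetabolicNetwork,
                          config: DiurnalConfig) -> sp.csc_matrix:
    """Transfer matrix T (2s x p): -1 in the light row, +1 in the dark row
    of each carry-over species.  An empty carry-over list yields a 2s x 0
    matrix (the phases then decouple completely)."""
    config.validate_against(network)
    s = network.n_species
    p = len(config.carryover_species)
    mat = sp.dok_matrix((2 * s, p), dtype=float)
    for j, sid in enumerate(config.carryover_species):
        i = network.species_index(sid)
        mat[i, j] = -1.0
        mat[s + i, j] = 1.0
    return mat.tocsc()


def build_export_matrix(network: MetabolicNetwork,
                        config: DiurnalConfig) -> sp.csc_matrix:
    """Export matrix (2s x q): -1 in the dark row of each exportable
    species.  Export amounts are nonnegative — accumulation leaves the
    system, it does not enter it."""
    config.validate_against(network)
    s = network.n_species
    q = len(config.exportable_species)
    mat = sp.dok_matrix((2 * s, q), dtype=float)
    for j, sid in enumerate(config.exportable_species):
        i = network.species_index(sid)
        mat[s + i, j] = -1.0
    return mat.tocsc()


def _phase_bounds(network: MetabolicNetwork, overrides: dict,
                  dt: float) -> tuple[np.ndarray, np.ndarray]:
    lb = network.lb.copy()
    ub = network.ub.copy()
    for rid, (lo, hi) in overrides.items():
        j = network.reaction_index(rid)
        if lo > hi:
            raise ConfigError(f"override lb > ub for reaction {rid!r}")
        lb[j], ub[j] = lo, hi
    # flux -> concentration change; equalities (lb == ub) stay equalities
    return lb * dt, ub * dt


def build_extended_problem(network: MetabolicNetwork,
                           config: DiurnalConfig) -> ExtendedProblem:
    """Assemble the extended matrix, concentration-change bounds and
    objective for a two-phase diurnal cycle.

    Layout: ``[S 0 | T | export]`` with columns ordered light reactions,
    transfers, dark reactions, exports.  Reaction-block bounds are the
    phase-specific flux bounds (after overrides) multiplied by the phase
    duration, so every variable is a concentration change.
    """
    config.validate_against(network)
    if len(config.phases) != 2:
        raise UnsupportedConfigurationError(
            f"the validated path supports exactly 2 phases, got {len(config.phases)}")
    s, r = network.n_species, network.n_reactions
    p = len(config.carryover_species)
    q = len(config.exportable_species)

    T = build_transfer_matrix(network, config)
    E = build_export_matrix(network, config)
    zero = sp.csc_matrix((s, r))
    light_block = sp.vstack([network.stoich, zero])
    dark_block = sp.vstack([zero, network.stoich])
    S_ext = sp.hstack([light_block, T, dark_block, E], format="csc")

    light, dark = config.phases
    lb_l, ub_l = _phase_bounds(network, light.bound_overrides, light.duration)
    lb_d, ub_d = _phase_bounds(network, dark.bound_overrides, dark.duration)

    t_lb = np.full(p, -np.inf)
    t_ub = np.full(p, np.inf)
    for j, sid in enumerate(config.carryover_species):
        if sid in config.transfer_bounds:
            t_lb[j], t_ub[j] = config.transfer_bounds[sid]
    e_lb = np.zeros(q)
    e_ub = np.full(q, np.inf)

    v_lb = np.concatenate([lb_l, t_lb, lb_d, e_lb])
    v_ub = np.concatenate([ub_l, t_ub, ub_d, e_ub])

    col_map: list[tuple] = []
    col_map += [(PHASE, 0, rid) for rid in network.reaction_ids]
    col_map += [(TRANSFER, sid) for sid in config.carryover_species]
    col_map += [(PHASE, 1, rid) for rid in network.reaction_ids]
    col_map += [(EXPORT, sid) for sid in config.exportable_species]

    w = np.zeros(2 * r + p + q)
    if config.objective:
        phase_names = [ph.name for ph in config.phases]
        for (kind, target), weight in config.objective.items():
            if kind == "export":
                j = 2 * r + p + config.exportable_species.index(target)
            elif kind == "transfer":
                j = r + config.carryover_species.index(target)
            else:
                k = phase_names.index(kind)
                j = k * (r + p) + network.reaction_index(target)
            w[j] += weight
    else:
        # default: maximize total export (long-term accumulation)
        w[2 * r + p:] = 1.0

    return ExtendedProblem(
        S_ext=S_ext, v_lb=v_lb, v_ub=v_ub, w=w, col_map=col_map,
        phase_names=[light.name, dark.name],
        phase_durations=[light.duration, dark.duration],
        network=network, config=config)


def phase_fluxes(solution_vector: np.ndarray,
                 problem: ExtendedProblem) -> dict[str, np.ndarray]:
    """Recover per-phase flux vectors from a concentration-change solution.

    Reaction-block entries are divided by their phase's duration; transfer
    and export entries are amounts, not rates, and are not returned here.
    """
    v = np.asarray(solution_vector, dtype=float)
    if v.shape != (problem.n_cols,):
        raise ValueError(
            f"solution vector length {v.shape} does not match problem "
            f"({problem.n_cols} columns)")
    r = problem.network.n_reactions
    out: dict[str, np.ndarray] = {}
    for k, name in enumerate(problem.phase_names):
        cols = [j for j, entry in enumerate(problem.col_map)
                if entry[0] == PHASE and entry[1] == k]
        assert len(cols) == r
        out[name] = v[cols] / problem.phase_durations[k]
    return out


def save_problem(problem: ExtendedProblem, prefix: str | Path) -> tuple[Path, Path]:
    """Serialize the extended matrix to Matrix Market plus a TSV column map
    (for inspection and external-solver debugging).  Returns the two paths."""
    from scipy.io import mmwrite

    prefix = Path(prefix)
    mtx_path = prefix.with_suffix(".mtx")
    map_path = prefix.with_suffix(".columns.tsv")
    mmwrite(str(mtx_path), problem.S_ext.tocoo())
    lines = ["column\tname\tlb\tub\tobjective"]
    for j in range(problem.n_cols):
        lines.append(f"{j}\t{problem.column_name(j)}\t{problem.v_lb[j]}"
                     f"\t{problem.v_ub[j]}\t{problem.w[j]}")
    map_path.write_text("\n".join(lines) + "\n")
    return mtx_path, map_path
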