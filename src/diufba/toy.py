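"""The minimal worked-example model and its analytical oracle.

The example network has four species — a substrate ``SUB`` (photons in a
photosynthetic reading), a storage metabolite ``STO``, functional biomass
``BIO`` and a maintenance pseudo-species ``MNT`` — and eight reactions.
Substrate is supplied only during the light phase; a fixed maintenance
demand must be met in every phase.  Maintenance (and growth) can be fed
from substrate at full efficiency, from storage at efficiency ``e_sto``,
or — starvation — from biomass itself at efficiency ``e_bio``, with
``e_bio < e_sto < 1``.

Three solution paths are provided:

* the diurnal LP (via :mod:`diufba.diurnal_core` / :mod:`diufba.lp_solve`),
* a sequential two-step comparator in the spirit of the dynamic-FBA static
  optimization approach (:func:`dfba_soa`): the light phase is optimized
  greedily with no lookahead, end-of-phase pools are carried into the dark
  phase as bounded sources, and
* a closed-form resource-accounting optimum (:func:`toy_oracle`) used as
  an independent check on the LP.

Efficiencies default to ``e_bio = 0.5`` and ``e_sto = 0.8``; with 1 M of
substrate over a 1 h light phase and a 0.1 M/h maintenance demand these
give the reference behaviour: greedy optimization yields 0.9 M biomass
that shrinks to 0.7 M overnight, while the diurnal optimum sets aside
0.125 M of storage and retains 0.775 M of biomass.  Biomass is expressed
in molar precursor units throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .diurnal_core import build_extended_problem
from .lp_solve import DiuSolution, fba_single_phase, solve_diufba
from .model_io import DiurnalConfig, MetabolicNetwork, Phase

SPECIES = ["SUB", "STO", "BIO", "MNT"]

TOY_LABELS = {"BIO": "functional", "STO": "storage"}


@dataclass
class ToyScenario:
    """Parameters of the worked example.

    ``substrate_supply`` is the total substrate made available over the
    light phase (M); ``maintenance_rate`` is the fixed demand (M/h) active
    in both phases.  ``e_sto`` and ``e_bio`` are the conversion
    efficiencies of storage and biomass into maintenance/growth
    equivalents.
    """

    light_duration: float = 1.0   # h
    dark_duration: float = 1.0    # h
    substrate_supply: float = 1.0  # M per light phase
    maintenance_rate: float = 0.1  # M/h
    e_sto: float = 0.8
    e_bio: float = 0.5

    def __post_init__(self) -> None:
        for name in ("light_duration", "dark_duration", "substrate_supply",
                     "maintenance_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.e_bio < self.e_sto < 1:
            raise ValueError(
                f"efficiencies must satisfy 0 < e_bio < e_sto < 1, "
                f"got e_bio={self.e_bio}, e_sto={self.e_sto}")


def scenario(number: int) -> ToyScenario:
    """The two reference scenarios: 1 h light with 1 M substrate, then
    1 h (scenario 1) or 2 h (scenario 2) of starvation."""
    if number == 1:
        return ToyScenario(dark_duration=1.0)
    if number == 2:
        return ToyScenario(dark_duration=2.0)
    raise ValueError(f"scenario must be 1 or 2, got {number}")


def build_toy_model(scn: ToyScenario) -> tuple[MetabolicNetwork, DiurnalConfig]:
    """Construct the example network and its diurnal configuration.

    Reactions (flux units M/h):

    ========  =======================  ==============================
    id        equation                 bounds
    ========  =======================  ==============================
    EX_sub    -> SUB                   [0, supply/dt_light]; 0 in dark
    R_bio     SUB -> BIO               [0, inf)
    R_sto     SUB -> STO               [0, inf)
    R_m_sub   SUB -> MNT               [0, inf)
    R_m_sto   STO -> e_sto MNT         [0, inf)
    R_g_sto   STO -> e_sto BIO         [0, inf)
    R_m_bio   BIO -> e_bio MNT         [0, inf)
    DM_mnt    MNT ->                   lb = ub = maintenance_rate
    ========  =======================  ==============================

    Carry-over species are {STO, BIO} (functional biomass must persist
    through the night exactly like storage); only BIO is exportable, and
    the objective is its export — the biomass surviving the full cycle.
    """
    supply_flux = scn.substrate_supply / scn.light_duration
    reactions = [
        # (id, {species: coeff}, lb, ub)
        ("EX_sub", {"SUB": 1.0}, 0.0, supply_flux),
        ("R_bio", {"SUB": -1.0, "BIO": 1.0}, 0.0, np.inf),
        ("R_sto", {"SUB": -1.0, "STO": 1.0}, 0.0, np.inf),
        ("R_m_sub", {"SUB": -1.0, "MNT": 1.0}, 0.0, np.inf),
        ("R_m_sto", {"STO": -1.0, "MNT": scn.e_sto}, 0.0, np.inf),
        ("R_g_sto", {"STO": -1.0, "BIO": scn.e_sto}, 0.0, np.inf),
        ("R_m_bio", {"BIO": -1.0, "MNT": scn.e_bio}, 0.0, np.inf),
        ("DM_mnt", {"MNT": -1.0}, scn.maintenance_rate, scn.maintenance_rate),
    ]
    sidx = {sid: i for i, sid in enumerate(SPECIES)}
    mat = sp.dok_matrix((len(SPECIES), len(reactions)), dtype=float)
    lbs, ubs, rids = [], [], []
    for j, (rid, coeffs, lo, hi) in enumerate(reactions):
        for sid, c in coeffs.items():
            mat[sidx[sid], j] = c
        rids.append(rid)
        lbs.append(lo)
        ubs.append(hi)
    network = MetabolicNetwork(
        species_ids=list(SPECIES), reaction_ids=rids, stoich=mat.tocsc(),
        lb=np.array(lbs), ub=np.array(ubs),
        objective_coeffs=np.zeros(len(reactions)),
        species_meta={sid: {"compartment": "c", "name": sid} for sid in SPECIES})
    config = DiurnalConfig(
        phases=[
            Phase("light", scn.light_duration),
            Phase("dark", scn.dark_duration, {"EX_sub": (0.0, 0.0)}),
        ],
        carryover_species=["STO", "BIO"],
        exportable_species=["BIO"],
        objective={("export", "BIO"): 1.0},
    )
    return network, config


def solve_toy(scn: ToyScenario, secondary: str = "none") -> DiuSolution:
    """Build and solve the diurnal LP for a scenario."""
    network, config = build_toy_model(scn)
    return solve_diufba(build_extended_problem(network, config), secondary=secondary)


# ---------------------------------------------------------------------------
# Sequential (myopic) comparator
# ---------------------------------------------------------------------------

@dataclass
class DfbaTrajectory:
    """Result of the two-step sequential optimization.

    ``pools`` holds the carry-over species amounts after each phase (the
    pool named by the objective species is the biomass); ``status`` is
    ``"ok"`` or ``"starvation-collapse"`` when the dark phase cannot meet
    maintenance from the carried pools.
    """

    phase_names: list[str]
    pools: list[dict[str, float]]
    status: str

    @property
    def final_biomass(self) -> float | None:
        if self.status != "ok":
            return None
        return self.pools[-1].get("BIO")


def _with_pool_columns(network: MetabolicNetwork, pool_species: list[str],
                       sources: dict[str, float] | None,
                       dt: float, overrides: dict) -> tuple[MetabolicNetwork, dict]:
    """Clone the network with a sink per pool species (accumulation) and,
    if ``sources`` is given, a bounded source per pool species drawing on
    the carried amount.  Bounds are in flux units; pool amounts divide by
    the phase duration."""
    s = network.n_species
    cols = [network.stoich]
    rids = list(network.reaction_ids)
    lbs = list(network.lb)
    ubs = list(network.ub)
    for sid in pool_species:
        i = network.species_index(sid)
        col = sp.dok_matrix((s, 1), dtype=float)
        col[i, 0] = -1.0
        cols.append(col.tocsc())
        rids.append(f"SINK_{sid}")
        lbs.append(0.0)
        ubs.append(np.inf)
    if sources is not None:
        for sid in pool_species:
            i = network.species_index(sid)
            col = sp.dok_matrix((s, 1), dtype=float)
            col[i, 0] = 1.0
            cols.append(col.tocsc())
            rids.append(f"SRC_{sid}")
            lbs.append(0.0)
            ubs.append(sources.get(sid, 0.0) / dt)
    extended = MetabolicNetwork(
        species_ids=list(network.species_ids), reaction_ids=rids,
        stoich=sp.hstack(cols, format="csc"),
        lb=np.array(lbs), ub=np.array(ubs),
        objective_coeffs=np.zeros(len(rids)))
    return extended, dict(overrides)


def dfba_soa(network: MetabolicNetwork, config: DiurnalConfig) -> DfbaTrajectory:
    """Two-step sequential optimization with no lookahead.

    Phase 1 greedily maximizes accumulation of the objective (exportable)
    species; end-of-phase pool amounts of every carry-over species become
    bounded source reactions for phase 2, which maximizes the final pool
    of the objective species (untouched pool plus anything re-produced,
    minus what starvation consumes).
    """
    if len(config.phases) != 2:
        raise ValueError("the sequential comparator supports exactly 2 phases")
    config.validate_against(network)
    pool_species = list(config.carryover_species)
    if len(config.exportable_species) != 1:
        raise ValueError("the comparator needs exactly one objective (exportable) species")
    target = config.exportable_species[0]

    light, dark = config.phases
    # phase 1: maximize target accumulation
    net1, ov1 = _with_pool_columns(network, pool_species, None,
                                   light.duration, light.bound_overrides)
    flux1, _obj1, status1 = fba_single_phase(
        net1, bound_overrides=ov1, objective={f"SINK_{target}": 1.0})
    if status1 != "optimal":
        return DfbaTrajectory([light.name, dark.name], [], "starvation-collapse")
    pools1 = {sid: float(flux1[net1.reaction_index(f"SINK_{sid}")]) * light.duration
              for sid in pool_species}

    # phase 2: draw on the carried pools; maximize what is left of the target
    net2, ov2 = _with_pool_columns(network, pool_species, pools1,
                                   dark.duration, dark.bound_overrides)
    objective = {f"SINK_{target}": 1.0, f"SRC_{target}": -1.0}
    flux2, obj2, status2 = fba_single_phase(net2, bound_overrides=ov2,
                                            objective=objective)
    if status2 != "optimal":
        return DfbaTrajectory([light.name, dark.name], [pools1], "starvation-collapse")
    pools2 = {}
    for sid in pool_species:
        drawn = float(flux2[net2.reaction_index(f"SRC_{sid}")]) * dark.duration
        returned = float(flux2[net2.reaction_index(f"SINK_{sid}")]) * dark.duration
        pools2[sid] = pools1[sid] - drawn + returned
    return DfbaTrajectory([light.name, dark.name], [pools1, pools2], "ok")


# ---------------------------------------------------------------------------
# Closed-form oracle
# ---------------------------------------------------------------------------

@dataclass
class ToyOptimum:
    """Closed-form diurnal optimum by direct resource accounting."""

    feasible: bool
    biomass: float
    storage: float
    objective: float
    functional_fraction: float = field(default=float("nan"))
    storage_fraction: float = field(default=float("nan"))


def toy_oracle(scn: ToyScenario) -> ToyOptimum:
    """Analytical optimum of the example model, independent of the LP path.

    Reasoning: light-phase maintenance is cheapest straight from substrate
    (efficiency 1), costing ``m * dt_light``.  Dark-phase maintenance must
    come from a carried pool; storage dominates biomass because
    ``e_sto > e_bio``, so the optimal reserve is
    ``m * dt_dark / e_sto``.  Everything else becomes functional biomass.
    A negative biomass residual means the scenario cannot sustain the
    cycle (``feasible=False``).
    """
    storage = scn.maintenance_rate * scn.dark_duration / scn.e_sto
    biomass = (scn.substrate_supply
               - scn.maintenance_rate * scn.light_duration
               - storage)
    if biomass < 0:
        return ToyOptimum(False, biomass, storage, float("nan"))
    total = biomass + storage
    return ToyOptimum(True, biomass, storage, biomass,
                      functional_fraction=biomass / total,
                      storage_fraction=storage / total)
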