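"""Scenario assembly, genotype composition, and the per-step engine loop.

A :class:`ScenarioConfig` names a genotype (wild type, ft-, ds-, ft-ds-,
fj-, uniform overexpression variants, domain truncations, morphogen
variants), a front mode and optionally a concentric clone; it composes
deterministically into field, kinetic, growth and mechanics parameters.
The engine advances in fixed stages each step:

  1. field evaluation per cell          7. polarity metrics (mature
  2. expression + phosphorylation          neighbours, from step 100)
  3. free-protein degradation           8. adaptation update
  4. dephosphorylation                  9. growth applied to radii
  5. bond dissolution                  10. division draws + divide_cell
  6. partition + bond formation        11. mechanics integration
     on all pruned interfaces         12. adjacency rebuild + prune

The stage order is a fixed contract so identical (config, seed) pairs
produce bit-identical trajectories.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import adjacency as adj_mod
from . import fields as fields_mod
from . import geometry, kinetics, polarity
from .geometry import Disc, MechanicsParams
from .kinetics import BondTable, KineticParams, ProteinPools
from .polarity import GrowthParams

logger = logging.getLogger("discsim")

GENOTYPES = (
    "wildtype", "ft_null", "ds_null", "ft_ds_null", "fj_null",
    "uniform_fj", "uniform_ds", "uniform_fj_ds",
    "ft_no_icd", "ft_no_ecd", "no_morphogen", "uniform_morphogen",
)

POLARITY_START_STEP = 100

__all__ = [
    "ScenarioConfig", "CloneSpec", "RunConfig", "Scenario", "SimState",
    "build_scenario", "apply_clone", "init_state", "step", "run",
    "run_replicates", "GENOTYPES", "ConfigurationError",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class CloneSpec:
    """Circular clone concentric with the disc, induced at one step."""

    kind: str                      # morphogen_elevated | fj_overexpress | ds_overexpress
    induction_step: int = 200
    radius_fraction: float = 0.4   # of the disc radius at induction
    override_level: float | None = None  # rate or concentration, kind-specific

    def __post_init__(self):
        if self.kind not in ("morphogen_elevated", "fj_overexpress",
                             "ds_overexpress"):
            raise ConfigurationError(f"unknown clone kind {self.kind!r}")
        if not (0 < self.radius_fraction <= 1):
            raise ConfigurationError("radius_fraction must be in (0, 1]")

    def level(self) -> float:
        if self.override_level is not None:
            return self.override_level
        return {"morphogen_elevated": float(np.e),
                "fj_overexpress": 10.0,
                "ds_overexpress": 200.0}[self.kind]


@dataclass
class ScenarioConfig:
    genotype: str = "wildtype"
    front_mode: str = "moving"     # moving | stationary
    clone: CloneSpec | None = None
    overrides: dict = field(default_factory=dict)  # e.g. {"kinetics": {"k_dissoc": 0.8}}


@dataclass
class GenotypeFlags:
    """How a genotype alters the machinery beyond field parameters."""

    ft_binds: bool = True        # False: Ft has no extracellular domain
    count_bonds: bool = True     # False: Ft has no intracellular domain
    ft_free_penalty: bool = True # False with no ICD: free Ft exempt from U
    zero_initial_ft: bool = False
    zero_initial_ds: bool = False


@dataclass
class Scenario:
    """Fully parameterised model: the output of :func:`build_scenario`."""

    config: ScenarioConfig
    morphogen: fields_mod.MorphogenField
    fj: fields_mod.FjProfile
    ds_rule: fields_mod.DsExpressionRule
    kinetics: KineticParams
    growth: GrowthParams
    mechanics: MechanicsParams
    flags: GenotypeFlags
    grace_period: int = adj_mod.DEFAULT_GRACE_PERIOD
    cutoff_factor: float = adj_mod.DEFAULT_CUTOFF_FACTOR


def _apply_overrides(obj, section: dict, name: str):
    known = {f.name for f in dataclasses.fields(obj)}
    unknown = set(section) - known
    if unknown:
        raise ConfigurationError(f"unknown {name} override(s): {sorted(unknown)}")
    return replace(obj, **section)


def build_scenario(config: ScenarioConfig) -> Scenario:
    """Deterministic genotype -> parameter mapping."""
    if config.genotype not in GENOTYPES:
        raise ConfigurationError(f"unknown genotype {config.genotype!r}")
    if config.front_mode not in ("moving", "stationary"):
        raise ConfigurationError(f"unknown front mode {config.front_mode!r}")

    morphogen = fields_mod.MorphogenField()
    fj = fields_mod.FjProfile()
    ds_rule = fields_mod.DsExpressionRule(front_mode=config.front_mode)
    kin = KineticParams()
    growth = GrowthParams()
    mech = MechanicsParams()
    flags = GenotypeFlags()

    g = config.genotype
    if g in ("ft_null", "ft_ds_null"):
        kin = replace(kin, ft_rate=0.0)
        flags.zero_initial_ft = True
    if g in ("ds_null", "ft_ds_null"):
        ds_rule = replace(ds_rule, rate_high=1e-12, rate_low=0.0,
                          uniform_rate=0.0)
        flags.zero_initial_ds = True
    if g == "fj_null":
        fj = replace(fj, mode="absent")
    if g in ("uniform_fj", "uniform_fj_ds"):
        fj = replace(fj, mode="uniform")
    if g in ("uniform_ds", "uniform_fj_ds"):
        ds_rule = replace(ds_rule, uniform_rate=ds_rule.rate_high)
    if g == "ft_no_icd":
        flags.count_bonds = False
        flags.ft_free_penalty = False
    if g == "ft_no_ecd":
        flags.ft_binds = False
    if g == "no_morphogen":
        morphogen = replace(morphogen, mode="none")
    if g == "uniform_morphogen":
        morphogen = replace(morphogen, mode="uniform")

    ov = dict(config.overrides or {})
    sections = {"morphogen": morphogen, "fj": fj, "ds": ds_rule,
                "kinetics": kin, "growth": growth, "mechanics": mech}
    scalar = {"grace_period": adj_mod.DEFAULT_GRACE_PERIOD,
              "cutoff_factor": adj_mod.DEFAULT_CUTOFF_FACTOR}
    for key, section in ov.items():
        if key in sections:
            if not isinstance(section, dict):
                raise ConfigurationError(f"override section {key!r} must be a mapping")
            sections[key] = _apply_overrides(sections[key], section, key)
        elif key in scalar:
            scalar[key] = section
        else:
            raise ConfigurationError(f"unknown override section {key!r}")

    return Scenario(config=config, morphogen=sections["morphogen"],
                    fj=sections["fj"], ds_rule=sections["ds"],
                    kinetics=sections["kinetics"], growth=sections["growth"],
                    mechanics=sections["mechanics"], flags=flags,
                    grace_period=int(scalar["grace_period"]),
                    cutoff_factor=float(scalar["cutoff_factor"]))


# ---------------------------------------------------------------------------
# engine state
# ---------------------------------------------------------------------------

@dataclass
class SimState:
    disc: Disc
    graph: adj_mod.NeighborGraph
    bonds: BondTable
    scenario: Scenario
    rng: np.random.Generator
    clone_active: bool = False
    collect_diagnostics: bool = False
    diagnostics: list = field(default_factory=list)

    @property
    def pools(self) -> ProteinPools:
        d = self.disc
        return ProteinPools(d.ft_u, d.ft_p, d.ds_u, d.ds_p)


def init_state(scenario: Scenario, n_cells: int = 1000,
               target_radius: float = 40.0, seed=None, dt: float = 1.0,
               collect_diagnostics: bool = False) -> SimState:
    """Relaxed initial disc with steady-state free pools.

    Initial free Ds and Fj-driven phosphorylation follow the t = 0 field
    profiles; the initial free-pool sizes are the birth-death steady state
    (expression rate / degradation rate).  Initial Ft is identical for
    every cell.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_init, s_run = ss.spawn(2)
    disc = geometry.init_disc(n_cells, target_radius, seed=s_init,
                              params=scenario.mechanics, dt=dt)
    rng = np.random.default_rng(s_run)
    R = geometry.disc_radius(disc)
    r = disc.radial_positions()
    kin = scenario.kinetics
    fj0 = np.broadcast_to(np.asarray(
        fields_mod.fj_level_at(r, 0.0, R, scenario.fj), float), r.shape)
    p_phos = np.where(fj0 + kin.phos_K > 0, fj0 / (fj0 + kin.phos_K), 0.0)
    if not scenario.flags.zero_initial_ft and kin.k_deg_ft > 0:
        ft0 = np.full(disc.n_cells, round(kin.ft_rate / kin.k_deg_ft))
        disc.ft_p[:] = np.rint(ft0 * p_phos).astype(np.int64)
        disc.ft_u[:] = ft0 - disc.ft_p
    if not scenario.flags.zero_initial_ds and kin.k_deg_ds > 0:
        ds_rate0 = np.broadcast_to(np.asarray(fields_mod.ds_rate_at(
            r, 0.0, R, scenario.morphogen, scenario.ds_rule), float), r.shape)
        ds0 = np.rint(ds_rate0 / kin.k_deg_ds).astype(np.int64)
        disc.ds_p[:] = np.rint(ds0 * p_phos).astype(np.int64)
        disc.ds_u[:] = ds0 - disc.ds_p
    graph = adj_mod.NeighborGraph.build(disc.pos, disc.radius, step=0,
                                        cutoff_factor=scenario.cutoff_factor,
                                        jitter=disc.jitter)
    return SimState(disc=disc, graph=graph, bonds=BondTable(),
                    scenario=scenario, rng=rng,
                    collect_diagnostics=collect_diagnostics)


def apply_clone(disc: Disc, clone: CloneSpec, R: float) -> int:
    """Label all cells within radius_fraction * R as clone; returns count.
    Labels are heritable (daughters copy the mother's region label)."""
    r = disc.radial_positions()
    mask = r <= clone.radius_fraction * R
    disc.region[mask] = 1
    return int(mask.sum())


# ---------------------------------------------------------------------------
# the per-step loop
# ---------------------------------------------------------------------------

def _per_cell_fields(state: SimState, R: float):
    """Stage 1: morphogen, Fj and Ds-rate arrays, with clone overrides."""
    sc = state.scenario
    disc = state.disc
    r = disc.radial_positions()
    t = disc.step * disc.dt
    M = np.broadcast_to(np.asarray(
        fields_mod.morphogen_at(r, t, R, sc.morphogen), float), r.shape).copy()
    fj = np.broadcast_to(np.asarray(
        fields_mod.fj_level_at(r, t, R, sc.fj), float), r.shape).copy()
    ds_rate = np.broadcast_to(np.asarray(fields_mod.ds_rate_at(
        r, t, R, sc.morphogen, sc.ds_rule), float), r.shape).copy()
    clone = sc.config.clone
    if clone is not None and state.clone_active:
        in_clone = disc.region == 1
        if clone.kind == "morphogen_elevated":
            M[in_clone] = clone.level()
            # Ds expression inside the clone responds to the elevated level
            if sc.ds_rule.uniform_rate is None and sc.ds_rule.front_mode == "moving":
                rl, rh = sc.ds_rule.rate_low, sc.ds_rule.rate_high
                hn, mh = sc.ds_rule.hill_n, sc.ds_rule.M_half
                ds_rate[in_clone] = rl + (rh - rl) * mh ** hn / (
                    mh ** hn + clone.level() ** hn)
        elif clone.kind == "fj_overexpress":
            fj[in_clone] = clone.level()
        elif clone.kind == "ds_overexpress":
            ds_rate[in_clone] = clone.level()
    return M, fj, ds_rate


def step(state: SimState) -> SimState:
    """Advance the simulation by one step (stage order is the contract)."""
    disc, graph, bonds = state.disc, state.graph, state.bonds
    sc = state.scenario
    rng = state.rng
    dt = disc.dt
    kin = sc.kinetics
    n = disc.n_cells

    # (1) fields
    R = geometry.disc_radius(disc)
    M, fj, ds_rate = _per_cell_fields(state, R)

    if state.collect_diagnostics:
        ft_before = disc.ft_u + disc.ft_p + bonds.bound_ft_per_cell(n)
        ds_before = disc.ds_u + disc.ds_p + bonds.bound_ds_per_cell(n)

    # (2) expression + phosphorylation of new protein
    pools = state.pools
    before_ft = pools.total_ft().sum()
    before_ds = pools.total_ds().sum()
    kinetics.express_proteins(pools, fj, ds_rate, kin, dt, rng)
    produced_ft = int(pools.total_ft().sum() - before_ft)
    produced_ds = int(pools.total_ds().sum() - before_ds)

    # (3) degradation of free protein.  Degradation precedes dissolution so
    # that protein released from a bond always gets one binding pass before
    # it is ever exposed to degradation: binding is fast compared to
    # turnover, and racing degradation against re-binding within the same
    # step would roughly double the decay rate of the bond-distribution
    # memory that polarity retention rests on.
    free_before_ft = int(pools.total_ft().sum())
    free_before_ds = int(pools.total_ds().sum())
    kinetics.degrade_free(pools, kin.k_deg_ft, kin.k_deg_ds, dt, rng)
    degraded_ft = free_before_ft - int(pools.total_ft().sum())
    degraded_ds = free_before_ds - int(pools.total_ds().sum())

    # (4) dephosphorylation of free protein
    kinetics.dephosphorylate(pools, kin.k_dephos, dt, rng)

    # (5) bond dissolution (released protein re-enters the free pools and
    # takes part in this step's partitioning)
    bonds_before = bonds.total()
    dissolved = 0
    if len(bonds):
        # draw in canonical (i, j) order so the trajectory does not depend
        # on ledger storage order (which changes across save/load)
        order = np.lexsort((bonds.pairs[:, 1], bonds.pairs[:, 0]))
        remaining, released = kinetics.dissolve_bonds(bonds.counts[order],
                                                      kin.k_dissoc, dt, rng)
        bonds.counts[order] = remaining
        pairs_o = bonds.pairs[order]
        np.add.at(disc.ft_u, pairs_o[:, 0], released[:, 0] + released[:, 2])
        np.add.at(disc.ft_p, pairs_o[:, 0], released[:, 1] + released[:, 3])
        np.add.at(disc.ds_u, pairs_o[:, 1], released[:, 0] + released[:, 1])
        np.add.at(disc.ds_p, pairs_o[:, 1], released[:, 2] + released[:, 3])
        dissolved = int(released.sum())

    # (6) even partitioning + weighted bond formation on pruned interfaces
    edges = graph.edges
    if sc.flags.ft_binds and edges.shape[0] > 0:
        E = edges.shape[0]
        own = np.concatenate([edges[:, 0], edges[:, 1]])
        nbr = np.concatenate([edges[:, 1], edges[:, 0]])
        D = 2 * E
        partner = (np.arange(D) + E) % D
        a_ftu = kinetics.partition_free_all(disc.ft_u, own, n, rng)
        a_ftp = kinetics.partition_free_all(disc.ft_p, own, n, rng)
        a_dsu = kinetics.partition_free_all(disc.ds_u, own, n, rng)[partner]
        a_dsp = kinetics.partition_free_all(disc.ds_p, own, n, rng)[partner]
        new = kinetics.pair_and_bind(a_ftu, a_ftp, a_dsu, a_dsp, kin.w, rng)
        np.add.at(disc.ft_u, own, -(new[:, 0] + new[:, 2]))
        np.add.at(disc.ft_p, own, -(new[:, 1] + new[:, 3]))
        np.add.at(disc.ds_u, nbr, -(new[:, 0] + new[:, 1]))
        np.add.at(disc.ds_p, nbr, -(new[:, 2] + new[:, 3]))
        bonds.add_many(np.column_stack([own, nbr]), new)

    # (7) polarity metrics over mature neighbours
    if disc.step >= POLARITY_START_STEP:
        polarity.compute_polarity(disc, graph, bonds, sc.grace_period, rng,
                                  count_bonds=sc.flags.count_bonds)

    # (8) integral-feedback adaptation
    gp = sc.growth
    xm_raw = M / (M + gp.K_M)
    x_m, disc.y_m = polarity.adapt(xm_raw, disc.y_m, gp.tau_adapt, dt)
    x_ft, disc.y_ft = polarity.adapt(disc.x_ft_raw, disc.y_ft, gp.tau_adapt, dt)
    x_ds, disc.y_ds = polarity.adapt(disc.x_ds_raw, disc.y_ds, gp.tau_adapt, dt)

    # (9) growth
    free = disc.ds_u + disc.ds_p
    if sc.flags.ft_free_penalty:
        free = free + disc.ft_u + disc.ft_p
    U = gp.u_scale * free
    ratio = polarity.growth_ratio(x_m, x_ft, x_ds, U, gp)
    disc.radius = np.minimum(disc.radius * ratio, sc.mechanics.r_max)

    # (10) division
    p_div = polarity.division_probability(disc.radius, gp)
    dividing = np.flatnonzero(rng.random(n) < p_div)
    for m in dividing:
        polarity.divide_cell(disc, graph, bonds, int(m), rng,
                             orientation_mode="random")

    # (11) mechanics
    geometry.integrate_motion(disc, graph.edges, sc.mechanics, dt=dt)

    # (12) adjacency rebuild + prune (edge ages persist)
    state.graph = adj_mod.NeighborGraph.build(
        disc.pos, disc.radius, step=disc.step,
        cutoff_factor=sc.cutoff_factor, prev=graph, jitter=disc.jitter)

    if state.collect_diagnostics:
        nn = disc.n_cells
        ft_after = disc.ft_u + disc.ft_p + bonds.bound_ft_per_cell(nn)
        ds_after = disc.ds_u + disc.ds_p + bonds.bound_ds_per_cell(nn)
        state.diagnostics.append({
            "step": disc.step,
            "ft_total_delta": int(ft_after.sum() - ft_before.sum()),
            "ds_total_delta": int(ds_after.sum() - ds_before.sum()),
            "produced_ft": produced_ft, "produced_ds": produced_ds,
            "degraded_ft": degraded_ft, "degraded_ds": degraded_ds,
            "free_ft_before_deg": free_before_ft,
            "free_ds_before_deg": free_before_ds,
            "bonds_before_dissolution": bonds_before,
            "dissolved": dissolved,
            "n_divisions": int(dividing.size),
        })

    if disc.step % 500 == 0:
        bonds.compact()
    disc.step += 1
    return state


# ---------------------------------------------------------------------------
# run management
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    n_steps: int = 2880
    dt: float = 1.0            # minutes per step
    seed: int = 0
    n_cells: int = 1000
    target_radius: float = 40.0
    record_start: int = 100
    record_every: int = 10
    n_replicates: int = 1
    record_tables: str = "all"  # all | last | none


def run(run_config: RunConfig, scenario: Scenario | ScenarioConfig,
        state: SimState | None = None):
    """Execute a run and return its :class:`~discsim.analysis.RunRecord`.

    If ``state`` is given, recording continues from its current step
    (used by resume); otherwise a fresh disc is initialised from the seed.
    """
    from .analysis import RunRecord, snapshot_tables, summarize_snapshot

    if isinstance(scenario, ScenarioConfig):
        scenario = build_scenario(scenario)
    clone = scenario.config.clone
    if clone is not None and clone.induction_step >= run_config.n_steps:
        raise ConfigurationError("clone induction after end of run")
    if state is None:
        state = init_state(scenario, n_cells=run_config.n_cells,
                           target_radius=run_config.target_radius,
                           seed=run_config.seed, dt=run_config.dt)
    record = RunRecord(run_config=run_config, scenario=scenario)

    def _maybe_record():
        s = state.disc.step
        cadence = (s >= run_config.record_start
                   and (s - run_config.record_start) % run_config.record_every == 0)
        if cadence or s == run_config.n_steps:
            summary = summarize_snapshot(state)
            record.summaries.append(summary)
            if run_config.record_tables == "all" or (
                    run_config.record_tables == "last"
                    and s == run_config.n_steps):
                record.snapshots[s] = snapshot_tables(state)

    while state.disc.step < run_config.n_steps:
        if clone is not None and not state.clone_active \
                and state.disc.step == clone.induction_step:
            R = geometry.disc_radius(state.disc)
            n_lab = apply_clone(state.disc, clone, R)
            state.clone_active = True
            logger.info("step %d: clone induced (%d cells)",
                        state.disc.step, n_lab)
        _maybe_record()
        step(state)
        if state.disc.step % 1000 == 0:
            logger.info(
                "step %d: %d cells, mean |Dachs| %.3f",
                state.disc.step, state.disc.n_cells,
                float(state.disc.dachs_mag.mean()))
    _maybe_record()
    record.final_state = state
    return record


def run_replicates(run_config: RunConfig, scenario: Scenario | ScenarioConfig):
    """Run ``n_replicates`` runs with seeds derived deterministically from
    the base seed; returns a list of RunRecords."""
    if isinstance(scenario, ScenarioConfig):
        scenario = build_scenario(scenario)
    records = []
    children = np.random.SeedSequence(run_config.seed).spawn(
        run_config.n_replicates)
    for k, child in enumerate(children):
        cfg = replace(run_config, n_replicates=1)
        state = init_state(scenario, n_cells=cfg.n_cells,
                           target_radius=cfg.target_radius,
                           seed=child, dt=cfg.dt)
        records.append(run(cfg, scenario, state=state))
    return records


def resume(snapshot_path, run_config: RunConfig):
    """Continue a saved run to ``run_config.n_steps``; the continuation is
    bit-identical to the uninterrupted run with the same seed."""
    from .analysis import read_snapshot

    state = read_snapshot(snapshot_path)
    return run(run_config, state.scenario, state=state)
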