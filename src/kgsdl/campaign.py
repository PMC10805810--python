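"""End-to-end campaign orchestration.

Wires the agents over one shared graph and derivation engine, runs the
goal-driven loop (control gate -> goal iterations -> progress evaluation) to
termination, and exports provenance (Turtle), results and the event log (CSV).
A campaign is fully determined by its configuration plus the master seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import doe as doe_mod
from . import goals as goals_mod
from . import physsim, postproc, scheduler
from .derivation import DerivationEngine, DerivationStatus, TaskType
from .kg_store import (C, CONDITION_FIELDS, ChemicalAmount, ExperimentStatus,
                       Graph, Iri, IriMinter, KG, Literal, P, RDF_TYPE,
                       PerformanceIndicator, ReactionCondition,
                       ReactionExperiment, Triple, read_experiment,
                       write_experiment)
from .physsim import (FAULT_IS_PEAK_SHIFT, FAULT_MODES, FAULT_NONE,
                      FeedFixture, KineticModel)


# -- configuration -----------------------------------------------------------


class HplcConfig(BaseModel):
    method_runtime: float
    internal_standard: str
    internal_standard_conc: float      # mol/L in the benzaldehyde feed
    retention_windows: dict
    response_factors: dict
    detection_limit: float = 1e-4
    area_noise_sigma: float = 0.01
    impurity_retention_time: float = 0.25


class LabConfig(BaseModel):
    name: str
    reactor_volume: float = 10.0                     # mL
    temperature_range: tuple = (20.0, 80.0)          # degC
    residence_time_range: tuple = (1.0, 20.0)        # min
    pump_flow_range: dict = Field(default_factory=lambda: {
        "A": (0.01, 5.0), "B": (0.01, 5.0), "C": (0.01, 5.0)})
    fill_levels: dict = Field(default_factory=lambda: {
        "A": 5000.0, "B": 5000.0, "C": 5000.0})     # mL
    feed_densities: dict = Field(default_factory=lambda: {
        "A": 0.85, "B": 0.83, "C": 0.82})           # g/mL
    injection_volume: float = 2.0                    # mL benzaldehyde slug per run
    hplc: HplcConfig


class FeedsConfig(BaseModel):
    """Nominal feed concentrations (mol/L) and purity derating factors."""

    benzaldehyde_conc: float = 0.5
    acetone_conc: float = 6.73
    naoh_conc: float = 0.1
    purity_liquid: float = 0.99
    purity_naoh: float = 0.97

    @property
    def effective(self) -> dict:
        return {"benzaldehyde": self.benzaldehyde_conc * self.purity_liquid,
                "acetone": self.acetone_conc * self.purity_liquid,
                "naoh": self.naoh_conc * self.purity_naoh}


class KineticsConfig(BaseModel):
    k1_ref: float = 1.7
    k2_ref: float = 0.15
    ea1: float = 70_000.0
    ea2: float = 90_000.0
    t_ref: float = 323.15

    def build(self) -> KineticModel:
        return KineticModel(self.k1_ref, self.k2_ref, self.ea1, self.ea2, self.t_ref)


class EconomicsConfig(BaseModel):
    prices: dict = Field(default_factory=lambda: {
        "benzaldehyde": 1.5, "acetone": 0.08, "naoh": 0.05,
        "biphenyl": 2.5, "naphthalene": 3.0})
    solvent_price_per_l: float = 0.0
    basis_moles: float = 0.0025


class OptimiserConfig(BaseModel):
    n_init: int = doe_mod.DEFAULT_N_INIT
    n_spectral: int = doe_mod.DEFAULT_N_SPECTRAL
    nsga_pop: int = doe_mod.DEFAULT_NSGA_POP
    nsga_gen: int = doe_mod.DEFAULT_NSGA_GEN
    gp_restarts: int = doe_mod.DEFAULT_GP_RESTARTS
    abnormal_yield_threshold: float = 105.0


class FaultConfig(BaseModel):
    lab: str
    run_index: int                                   # 1-based campaign run on that rig
    mode: str

    @model_validator(mode="after")
    def _check(self):
        if self.run_index < 1:
            raise ValueError("fault run indices are 1-based")
        if self.mode not in FAULT_MODES:
            raise ValueError(f"unknown fault mode {self.mode!r}")
        return self


class ControlConfig(BaseModel):
    enabled: bool = True
    conditions: list = Field(default_factory=lambda: [
        {"equiv_acetone": 15.0, "equiv_naoh": 0.2, "residence_time": 5.0,
         "temperature": 50.0},
        {"equiv_acetone": 30.0, "equiv_naoh": 0.1, "residence_time": 6.0,
         "temperature": 60.0}])
    tolerance: float = 5.0                           # yield percentage points


class GoalRequestConfig(BaseModel):
    objectives: list = Field(default_factory=lambda: [
        {"objective": "yield", "direction": "maximise", "threshold": 90.0},
        {"objective": "run_material_cost", "direction": "minimise", "threshold": 2.5}])
    search_space: dict = Field(default_factory=lambda: {
        "equiv_acetone": (5.0, 50.0), "equiv_naoh": (0.05, 0.5),
        "residence_time": (2.0, 10.0), "temperature": (30.0, 70.0)})
    labs: list = Field(default_factory=lambda: ["cambridge", "singapore"])
    cycle_allowance: int = 20
    deadline: int = 100_000                          # logical-tick budget


class CampaignConfig(BaseModel):
    goal_request: GoalRequestConfig = Field(default_factory=GoalRequestConfig)
    labs: list = Field(default_factory=list)         # list[LabConfig]
    feeds: FeedsConfig = Field(default_factory=FeedsConfig)
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)
    economics: EconomicsConfig = Field(default_factory=EconomicsConfig)
    optimiser: OptimiserConfig = Field(default_factory=OptimiserConfig)
    faults: list = Field(default_factory=list)       # list[FaultConfig]
    control: ControlConfig = Field(default_factory=ControlConfig)
    seed: int = 0
    max_ticks: int = 200_000

    @model_validator(mode="after")
    def _check(self):
        self.labs = [LabConfig.model_validate(l) for l in self.labs]
        self.faults = [FaultConfig.model_validate(f) for f in self.faults]
        names = [l.name for l in self.labs]
        if len(set(names)) != len(names):
            raise ValueError("lab names must be unique")
        for lab in self.goal_request.labs:
            if lab not in names:
                raise ValueError(f"goal request references unknown lab {lab!r}")
        return self


def _default_hplc(style: str) -> HplcConfig:
    if style == "cambridge":
        return HplcConfig(
            method_runtime=17.0, internal_standard="biphenyl",
            internal_standard_conc=0.06,
            retention_windows={"benzaldehyde": (4.0, 4.6),
                               "benzylideneacetone": (8.0, 8.8),
                               "biphenyl": (12.0, 12.8),
                               "dibenzylideneacetone": (14.0, 14.8)},
            response_factors={"benzaldehyde": 8000.0, "benzylideneacetone": 12000.0,
                              "biphenyl": 10000.0, "dibenzylideneacetone": 9000.0},
            impurity_retention_time=1.0)
    return HplcConfig(
        method_runtime=8.0, internal_standard="naphthalene",
        internal_standard_conc=0.05,
        retention_windows={"benzaldehyde": (2.0, 2.4),
                           "benzylideneacetone": (4.0, 4.4),
                           "naphthalene": (5.6, 6.0),
                           "dibenzylideneacetone": (6.8, 7.2)},
        response_factors={"benzaldehyde": 7000.0, "benzylideneacetone": 11000.0,
                          "naphthalene": 9500.0, "dibenzylideneacetone": 8500.0},
        impurity_retention_time=0.5)


def default_config(**overrides) -> CampaignConfig:
    """Two-lab fixture campaign mirroring the two rigs' feed set-up."""
    cfg = CampaignConfig(
        labs=[LabConfig(name="cambridge", hplc=_default_hplc("cambridge")),
              LabConfig(name="singapore", hplc=_default_hplc("singapore"))])
    return cfg.model_copy(update=overrides) if overrides else cfg


# -- runtime context ---------------------------------------------------------


def lab_iri(name: str) -> Iri:
    return Iri(KG + "Lab/" + name)


@dataclass
class CampaignResult:
    rows: list
    decisions: list
    hv_trace: list
    reference_point: tuple
    graph: Graph
    engine: DerivationEngine
    notifications: list
    control: Optional[scheduler.ControlGateResult]
    goalset: goals_mod.GoalSet
    executed: int
    deadlocked: list = field(default_factory=list)
    final_fill_levels: dict = field(default_factory=dict)  # lab -> pump -> mL

    @property
    def experiments(self) -> list:
        return [r for r in self.rows if not r["is_control"]]


class _Context:
    """Mutable campaign state shared by the agent handlers."""

    def __init__(self, config: CampaignConfig):
        self.config = config
        self.graph = Graph()
        self.minter = IriMinter(config.seed)
        self.engine = DerivationEngine(self.graph, self.minter)
        seq = np.random.SeedSequence(config.seed)
        kids = seq.spawn(4)
        self.rng_design = np.random.default_rng(kids[0])
        self.rng_noise = np.random.default_rng(kids[1])
        self.rng_gp = np.random.default_rng(kids[2])
        self.rng_tsemo = np.random.default_rng(kids[3])

        eff = config.feeds.effective
        impure = (config.feeds.purity_liquid < 1.0
                  or config.feeds.purity_naoh < 1.0)
        self.rigs: dict[str, scheduler.VapourtecRig] = {}
        self.quant: dict[str, postproc.QuantMethod] = {}
        for lab_cfg in config.labs:
            liri = lab_iri(lab_cfg.name)
            hc = lab_cfg.hplc
            hplc = scheduler.HplcUnit(
                iri=Iri(liri.value + "/hplc"), lab=liri,
                method_runtime=hc.method_runtime,
                retention_windows={k: tuple(v) for k, v in hc.retention_windows.items()},
                internal_standard=hc.internal_standard,
                response_factors=dict(hc.response_factors),
                detection_limit=hc.detection_limit,
                area_noise_sigma=hc.area_noise_sigma,
                impurity_retention_time=hc.impurity_retention_time)
            pumps = {
                "A": ChemicalAmount(Iri(liri.value + "/pumpA"),
                                    [("benzaldehyde", eff["benzaldehyde"]),
                                     (hc.internal_standard, hc.internal_standard_conc)],
                                    lab_cfg.fill_levels["A"], impure),
                "B": ChemicalAmount(Iri(liri.value + "/pumpB"),
                                    [("acetone", eff["acetone"])],
                                    lab_cfg.fill_levels["B"], impure),
                "C": ChemicalAmount(Iri(liri.value + "/pumpC"),
                                    [("naoh", eff["naoh"])],
                                    lab_cfg.fill_levels["C"], impure),
            }
            self.rigs[liri.value] = scheduler.VapourtecRig(
                iri=Iri(liri.value + "/rig"), lab=liri,
                reactor_volume=lab_cfg.reactor_volume,
                temperature_range=tuple(lab_cfg.temperature_range),
                residence_time_range=tuple(lab_cfg.residence_time_range),
                pump_flow_range={k: tuple(v) for k, v in lab_cfg.pump_flow_range.items()},
                pumps=pumps, hplc=hplc,
                feed_densities=dict(lab_cfg.feed_densities),
                injection_volume=lab_cfg.injection_volume)
            self.quant[liri.value] = postproc.QuantMethod.from_hplc(
                hplc, config.optimiser.abnormal_yield_threshold)

        first_is = config.labs[0].hplc
        self.feed_fixture = FeedFixture(
            benzaldehyde=eff["benzaldehyde"], acetone=eff["acetone"],
            naoh=eff["naoh"], internal_standard=first_is.internal_standard_conc,
            internal_standard_species=first_is.internal_standard)
        self.economics = postproc.Economics(
            prices=dict(config.economics.prices), feeds=self.feed_fixture,
            basis_moles=config.economics.basis_moles,
            solvent_price_per_l=config.economics.solvent_price_per_l)
        self.kinetics = config.kinetics.build()
        self.impure = impure

        self.faults: dict[tuple, str] = {
            (lab_iri(f.lab).value, f.run_index): f.mode for f in config.faults}
        self.settings: dict[str, scheduler.EquipmentSettings] = {}
        self.assignment_exp: dict[str, Iri] = {}
        self.chromatograms: dict[str, physsim.Chromatogram] = {}
        self.exp_context: dict[str, dict] = {}
        self.executed = 0
        self.reservations = 0
        self.stop = False
        self.notifications: list = []
        self.rows: list = []
        self.decisions: list = []
        self.hv_trace: list = []
        self.lhs_points: list = []
        self.lhs_cursor = 0
        self.goalset: Optional[goals_mod.GoalSet] = None
        self.reference_point: tuple = (0.0, 1.0)

    # -- helpers -----------------------------------------------------------

    def is_control(self, exp_iri: Iri) -> bool:
        v = self.graph.pyvalue(exp_iri, P.isControlRun)
        return bool(v)

    def rig_for_lab(self, lab: Iri) -> scheduler.VapourtecRig:
        return self.rigs[lab.value]

    def lab_operational(self, lab: Iri) -> bool:
        rig = self.rig_for_lab(lab)
        return (rig.state != scheduler.STATE_OUT_OF_SERVICE
                and rig.hplc.state == scheduler.STATE_OK)

    def next_design_point(self, space: doe_mod.SearchSpace) -> ReactionCondition:
        if self.lhs_cursor < len(self.lhs_points):
            cond = self.lhs_points[self.lhs_cursor]
            self.lhs_cursor += 1
            return cond
        return doe_mod.propose_random(space, self.rng_design)

    def remaining_allowance(self) -> int:
        return (self.goalset.restriction.cycle_allowance
                - self.executed - self.reservations)

    def current_points(self):
        pts, iris = [], []
        for exp in doe_mod.gather_history(self.graph, is_control=self.is_control).experiments:
            pts.append((exp.indicators.yield_pct, exp.indicators.run_material_cost))
            iris.append(exp.iri)
        return pts, iris


# -- the physical execute+analyse path (shared by control gate and agents) ---


def _execute_physical(ctx: _Context, rig: scheduler.VapourtecRig,
                      settings: scheduler.EquipmentSettings,
                      fault_mode: str = FAULT_NONE):
    outlet = physsim.simulate_reactor(settings, rig.pumps, ctx.kinetics,
                                      settings.reactor_temperature)
    chrom = physsim.synthesize_chromatogram(
        outlet, rig.hplc, ctx.rng_noise, fault_mode=fault_mode,
        unidentified_component=ctx.impure)
    return outlet, chrom


def _quantify(ctx: _Context, lab: Iri, chrom, outlet,
              condition: ReactionCondition, rig: scheduler.VapourtecRig,
              settings: scheduler.EquipmentSettings):
    """Full post-processing for one run; returns (indicator, assigned, is_failed)."""
    method = ctx.quant[lab.value]
    assigned = postproc.assign_peaks(chrom, method)
    is_conc = outlet.concentrations.get(rig.hplc.internal_standard, 0.0)
    basis_conc = outlet.inlet_benzaldehyde
    is_failed = False
    try:
        yield_pct = postproc.compute_yield(assigned, method, is_conc, basis_conc)
    except postproc.QuantificationError:
        yield_pct = float("nan")
        is_failed = True
    abnormal = postproc.flag_abnormal(yield_pct, method, is_failed)
    if not abnormal and yield_pct > 100.0:
        yield_pct = 100.0  # saturate within the noise band; >threshold stays raw
    cost = postproc.compute_cost(condition, ctx.economics)
    e_factor, sty = None, None
    if not abnormal:
        product_conc = yield_pct / 100.0 * basis_conc
        e_factor, sty = postproc.compute_efactor_sty(
            product_conc, settings, rig.reactor_volume, rig.feed_densities,
            benzaldehyde_pump=rig.benzaldehyde_pump)
    indicator = PerformanceIndicator(
        yield_pct=yield_pct, run_material_cost=cost, abnormal_flag=abnormal,
        e_factor=e_factor, space_time_yield=sty)
    return indicator, assigned, is_failed


def _write_chromatogram(ctx: _Context, chrom_iri: Iri, chrom) -> None:
    g = ctx.graph
    triples = [Triple(chrom_iri, RDF_TYPE, C.Chromatogram),
               Triple(chrom_iri, P.faultAnnotation, Literal.of(chrom.fault_annotation))]
    for i, pt in enumerate(chrom.points):
        p_iri = Iri(chrom_iri.value + f"/point/{i}")
        triples += [Triple(p_iri, RDF_TYPE, C.ChromatogramPoint),
                    Triple(p_iri, P.retentionTime, Literal.of(float(pt.retention_time))),
                    Triple(p_iri, P.peakArea, Literal.of(float(pt.area)))]
        if pt.assignment is not None:
            triples.append(Triple(p_iri, P.peakAssignment, Literal.of(pt.assignment)))
    g.add_triples(triples)


def _record_row(ctx: _Context, exp: ReactionExperiment, is_control: bool,
                verdict: str = "") -> None:
    cond = exp.condition
    ind = exp.indicators
    pts, _ = ctx.current_points()
    hv = doe_mod.hypervolume(doe_mod.pareto_front(
        pts, reference_point=ctx.reference_point).points,
        ctx.reference_point) if pts else 0.0
    if not is_control:
        ctx.hv_trace.append(hv)
    ctx.rows.append({
        "experiment": exp.iri.value,
        "lab": exp.assigned_lab.value if exp.assigned_lab else "",
        "is_control": is_control,
        "equiv_acetone": cond.equiv_acetone,
        "equiv_naoh": cond.equiv_naoh,
        "residence_time": cond.residence_time,
        "temperature": cond.temperature,
        "yield_pct": ind.yield_pct,
        "run_material_cost": ind.run_material_cost,
        "e_factor": ind.e_factor,
        "space_time_yield": ind.space_time_yield,
        "abnormal_flag": ind.abnormal_flag,
        "hypervolume": hv,
        "verdict": verdict,
    })


# -- agent handlers ----------------------------------------------------------


def _make_handlers(ctx: _Context) -> dict:
    cfg = ctx.config

    def releases_reservation(fn: Callable) -> Callable:
        # pre-execution stages hold one allowance unit; an Error there must
        # hand it back so the other labs can still spend the full budget
        def wrapped(engine, d):
            try:
                fn(engine, d)
            except Exception:
                ctx.reservations -= 1
                raise
        return wrapped

    def rogi_handler(engine: DerivationEngine, d) -> None:
        goalset_iri, lab = d.inputs[0], d.inputs[1]
        iteration = d.outputs[0]
        goals_mod.rogi_plan_iteration(engine, ctx.goalset, lab, iteration)

    def doe_handler(engine: DerivationEngine, d) -> None:
        lab = d.inputs[1]
        exp_iri = d.outputs[0]
        space = ctx.goalset.search_space
        history = doe_mod.gather_history(ctx.graph, is_control=ctx.is_control)
        if len(history) < cfg.optimiser.n_init:
            condition = ctx.next_design_point(space)
        else:
            surrogates = doe_mod.fit_surrogates(
                history, space, ctx.rng_gp, n_init=cfg.optimiser.n_init,
                restarts=cfg.optimiser.gp_restarts)
            x, y = history.arrays()
            front = doe_mod.pareto_front(y, reference_point=ctx.reference_point)
            condition = doe_mod.propose_tsemo(
                surrogates, space, front, ctx.rng_tsemo,
                n_spectral=cfg.optimiser.n_spectral,
                nsga_pop=cfg.optimiser.nsga_pop, nsga_gen=cfg.optimiser.nsga_gen)
        exp = ReactionExperiment(iri=exp_iri, condition=condition)
        write_experiment(ctx.graph, exp)
        triples = [Triple(exp_iri, P.proposedBy, d.agent)]
        for h in history.experiments:
            triples.append(Triple(d.iri, P.usedHistory, h.iri))
        ctx.graph.add_triples(triples)

    def schedule_handler(engine: DerivationEngine, d) -> None:
        exp_iri = d.inputs[0]
        exp = read_experiment(ctx.graph, exp_iri)
        iteration = ctx.graph.value(d.iri, P.partOfIteration)
        lab = ctx.graph.value(iteration, P.hasLab)
        rig, settings = scheduler.select_equipment(
            [ctx.rig_for_lab(lab)], exp.condition, [lab], tick=ctx.graph.clock)
        try:
            scheduler.consume_stock(rig, settings)
        except scheduler.InsufficientStockError:
            scheduler.set_equipment_state(rig, scheduler.STATE_IDLE)
            raise
        for pump_id, amount in rig.pumps.items():
            ctx.graph.set_value(amount.container, P.hasFillLevel,
                                float(amount.fill_level))
        exp.status = ExperimentStatus.Assigned
        exp.assigned_lab = lab
        exp.assigned_equipment = rig.iri
        write_experiment(ctx.graph, exp)
        assignment = d.outputs[0]
        ctx.graph.add_triples([Triple(assignment, P.hasExperiment, exp_iri)])
        ctx.settings[exp_iri.value] = settings
        ctx.assignment_exp[assignment.value] = exp_iri

    def execution_handler(engine: DerivationEngine, d) -> None:
        assignment = d.inputs[0]
        exp_iri = ctx.assignment_exp[assignment.value]
        exp = read_experiment(ctx.graph, exp_iri)
        rig = ctx.rig_for_lab(exp.assigned_lab)
        settings = ctx.settings[exp_iri.value]
        rig.run_count += 1
        fault = ctx.faults.get((exp.assigned_lab.value, rig.run_count), FAULT_NONE)
        outlet, chrom = _execute_physical(ctx, rig, settings, fault)
        chrom_iri = d.outputs[0]
        _write_chromatogram(ctx, chrom_iri, chrom)
        ctx.chromatograms[chrom_iri.value] = chrom
        ctx.exp_context[exp_iri.value] = {"outlet": outlet, "rig": rig,
                                          "settings": settings, "fault": fault}
        exp.status = ExperimentStatus.Executed
        exp.chromatogram_ref = chrom_iri
        write_experiment(ctx.graph, exp)
        scheduler.set_equipment_state(rig, scheduler.STATE_IDLE)
        rig.last_used_tick = ctx.graph.clock
        ctx.executed += 1
        ctx.reservations -= 1

    def analysis_handler(engine: DerivationEngine, d) -> None:
        chrom_iri = d.inputs[0]
        matches = ctx.graph.query(None, P.hasChromatogram, chrom_iri)
        exp_iri = matches[0].subject
        exp = read_experiment(ctx.graph, exp_iri)
        run = ctx.exp_context[exp_iri.value]
        indicator, assigned, is_failed = _quantify(
            ctx, exp.assigned_lab, ctx.chromatograms[chrom_iri.value],
            run["outlet"], exp.condition, run["rig"], run["settings"])
        exp.status = ExperimentStatus.Analysed
        exp.indicators = indicator
        write_experiment(ctx.graph, exp)
        if indicator.abnormal_flag and run["fault"] == FAULT_IS_PEAK_SHIFT:
            # mirrors the real HPLC failure: maintenance notification, hardware
            # leaves the campaign, the other lab continues
            rig = run["rig"]
            scheduler.set_equipment_state(
                rig.hplc, scheduler.STATE_OUT_OF_SERVICE,
                reason=f"internal-standard peak shift on {exp_iri.value}",
                notifications=ctx.notifications)
            scheduler.set_equipment_state(
                rig, scheduler.STATE_OUT_OF_SERVICE,
                reason="attached HPLC out of service",
                notifications=ctx.notifications)
        _record_row(ctx, exp, is_control=False)

    def progress_handler(engine: DerivationEngine, d) -> None:
        lab = d.inputs[2]
        decision = goals_mod.evaluate_progress(
            ctx.graph, ctx.goalset, executed=ctx.executed,
            remaining_allowance=ctx.remaining_allowance(),
            tick=ctx.graph.clock, minter=ctx.minter, is_control=ctx.is_control)
        ctx.decisions.append({"lab": lab.value, "verdict": decision.verdict.value,
                              "rationale": decision.rationale})
        if ctx.rows:
            ctx.rows[-1]["verdict"] = ctx.rows[-1]["verdict"] or decision.verdict.value
        if decision.verdict is goals_mod.Verdict.StopGoalsMet:
            ctx.stop = True
        if (decision.verdict is goals_mod.Verdict.Continue and not ctx.stop
                and ctx.remaining_allowance() > 0 and ctx.lab_operational(lab)):
            ctx.reservations += 1
            goals_mod.spawn_goal_iterations(engine, ctx.goalset, labs=[lab])

    return {TaskType.GoalIteration: releases_reservation(rogi_handler),
            TaskType.DoE: releases_reservation(doe_handler),
            TaskType.Schedule: releases_reservation(schedule_handler),
            TaskType.Execution: releases_reservation(execution_handler),
            TaskType.Analysis: analysis_handler,
            TaskType.ProgressEvaluation: progress_handler}


# -- control gate ------------------------------------------------------------


def _run_control_gate(ctx: _Context) -> Optional[scheduler.ControlGateResult]:
    cfg = ctx.config.control
    if not cfg.enabled:
        return None
    conditions = [ReactionCondition(**c) for c in cfg.conditions]

    def run_fn(lab: Iri, condition: ReactionCondition) -> float:
        rig = ctx.rig_for_lab(lab)
        settings = scheduler.to_equipment_settings(condition, rig)
        scheduler.consume_stock(rig, settings)
        for pump_id, amount in rig.pumps.items():
            ctx.graph.set_value(amount.container, P.hasFillLevel,
                                float(amount.fill_level))
        outlet, chrom = _execute_physical(ctx, rig, settings)
        indicator, _, _ = _quantify(ctx, lab, chrom, outlet, condition, rig, settings)
        exp_iri = ctx.minter.mint("ReactionExperiment")
        exp = ReactionExperiment(
            iri=exp_iri, condition=condition, status=ExperimentStatus.Analysed,
            assigned_lab=lab, assigned_equipment=rig.iri, indicators=indicator)
        write_experiment(ctx.graph, exp)
        ctx.graph.add(exp_iri, P.isControlRun, True)
        _record_row(ctx, exp, is_control=True, verdict="control")
        return indicator.yield_pct

    return scheduler.verify_control_conditions(
        list(ctx.goalset.labs), conditions, cfg.tolerance, run_fn)


# -- campaign entry points ---------------------------------------------------


AGENT_ROLES = {
    TaskType.GoalIteration: Iri(KG + "Agent/rogi"),
    TaskType.DoE: Iri(KG + "Agent/doe"),
    TaskType.Schedule: Iri(KG + "Agent/schedule"),
    TaskType.Execution: Iri(KG + "Agent/executor"),
    TaskType.Analysis: Iri(KG + "Agent/postprocessing"),
    TaskType.ProgressEvaluation: Iri(KG + "Agent/rog"),
}


def run_campaign(config: CampaignConfig) -> CampaignResult:
    """Execute a full goal-driven campaign; deterministic in (config, seed)."""
    ctx = _Context(config)
    g = ctx.graph

    for lab_cfg in config.labs:
        liri = lab_iri(lab_cfg.name)
        rig = ctx.rigs[liri.value]
        triples = [Triple(liri, RDF_TYPE, C.Lab),
                   Triple(liri, P.hasName, Literal.of(lab_cfg.name)),
                   Triple(rig.iri, RDF_TYPE, C.VapourtecRig),
                   Triple(rig.iri, P.hasLab, liri),
                   Triple(rig.hplc.iri, RDF_TYPE, C.HplcUnit),
                   Triple(rig.hplc.iri, P.hasLab, liri)]
        for pump_id, amount in rig.pumps.items():
            triples += [Triple(amount.container, RDF_TYPE, C.ChemicalAmount),
                        Triple(amount.container, P.hasFillLevel,
                               Literal.of(float(amount.fill_level))),
                        Triple(amount.container, P.containsUnidentifiedComponent,
                               Literal.of(amount.contains_unidentified_component))]
        g.add_triples(triples)

    handlers = _make_handlers(ctx)
    for task_type, agent in AGENT_ROLES.items():
        ctx.engine.register_agent(agent, task_type, handlers[task_type])

    request = {"objectives": config.goal_request.objectives,
               "search_space": config.goal_request.search_space,
               "labs": [lab_iri(n) for n in config.goal_request.labs],
               "cycle_allowance": config.goal_request.cycle_allowance,
               "deadline": config.goal_request.deadline}
    ctx.goalset = goals_mod.parse_goal_request(g, ctx.minter, request)

    space = ctx.goalset.search_space
    e_hi = space.bounds["equiv_acetone"][1]
    f_hi = space.bounds["equiv_naoh"][1]
    worst_cost = float(ctx.economics.cost_per_basis(e_hi, f_hi))
    ctx.reference_point = (0.0, worst_cost * (1.0 + doe_mod.DEFAULT_REF_MARGIN))
    ctx.lhs_points = doe_mod.lhs_batch(space, config.optimiser.n_init, ctx.rng_design)

    control = _run_control_gate(ctx)
    active = list(ctx.goalset.labs)
    if control is not None and not control.skipped:
        active = [lab for lab in active if control.passed.get(lab.value, False)]

    allowance = ctx.goalset.restriction.cycle_allowance
    for lab in active[:allowance]:
        ctx.reservations += 1
        goals_mod.spawn_goal_iterations(ctx.engine, ctx.goalset, labs=[lab])
    if allowance == 0 or not active:
        decision = goals_mod.evaluate_progress(
            g, ctx.goalset, executed=0, remaining_allowance=allowance,
            tick=g.clock, minter=ctx.minter, is_control=ctx.is_control)
        ctx.decisions.append({"lab": "", "verdict": decision.verdict.value,
                              "rationale": decision.rationale})

    run = ctx.engine.run_until_quiescent(max_ticks=config.max_ticks)

    final_fill = {lab: {p: a.fill_level for p, a in rig.pumps.items()}
                  for lab, rig in ctx.rigs.items()}
    return CampaignResult(
        rows=ctx.rows, decisions=ctx.decisions, hv_trace=ctx.hv_trace,
        reference_point=ctx.reference_point, graph=g, engine=ctx.engine,
        notifications=ctx.notifications, control=control, goalset=ctx.goalset,
        executed=ctx.executed, deadlocked=run.deadlocked,
        final_fill_levels=final_fill)


# -- lineage -----------------------------------------------------------------


@dataclass
class LineageAnswer:
    experiments: list            # (experiment IRI, lab IRI or None) pairs
    notice: str = ""


def lineage_query(graph: Graph, experiment: Iri) -> LineageAnswer:
    """Which experiments informed the DoE that proposed this experiment?

    Returns exactly the recorded HistoricalData inputs of the proposing DoE
    derivation, with lab attribution.  Control runs and seed/random proposals
    have an empty lineage.
    """
    if not graph.query(experiment, RDF_TYPE, C.ReactionExperiment):
        raise KeyError(f"no such experiment: {experiment.value}")
    doe_derivation = None
    for t in graph.query(None, P.hasOutput, experiment):
        if graph.pyvalue(t.subject, P.hasTaskType) == TaskType.DoE.value:
            doe_derivation = t.subject
            break
    if doe_derivation is None:
        return LineageAnswer([], notice="no DoE ancestor (control or seed run)")
    pairs = []
    for t in graph.query(doe_derivation, P.usedHistory, None):
        pairs.append((t.object, graph.value(t.object, P.isAssignedTo)))
    pairs.sort(key=lambda p: p[0].value)
    if not pairs:
        return LineageAnswer([], notice="DoE ran on empty history (random phase)")
    return LineageAnswer(pairs)


# -- export ------------------------------------------------------------------

RESULT_COLUMNS = ["experiment", "lab", "is_control", "equiv_acetone", "equiv_naoh",
                  "residence_time", "temperature", "yield_pct", "run_material_cost",
                  "e_factor", "space_time_yield", "abnormal_flag", "hypervolume",
                  "verdict"]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def export_results(result: CampaignResult, out_dir) -> dict:
    """Write results.csv, events.csv and provenance.ttl; returns the paths."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    paths = {"results": os.path.join(out_dir, "results.csv"),
             "events": os.path.join(out_dir, "events.csv"),
             "provenance": os.path.join(out_dir, "provenance.ttl")}
    with open(paths["results"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(RESULT_COLUMNS)
        for row in result.rows:
            writer.writerow([_fmt(row[c]) for c in RESULT_COLUMNS])
    with open(paths["events"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["tick", "agent", "derivation", "transition"])
        for e in result.engine.events_table():
            writer.writerow([e["tick"], e["agent"], e["derivation"], e["transition"]])
    result.graph.serialize_turtle(paths["provenance"])
    return paths
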