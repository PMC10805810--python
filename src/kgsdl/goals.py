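"""Goal request translation, per-lab iteration spawning, and progress evaluation.

A scientist's request becomes a GoalSet (objective thresholds, search-space
bounds, participating labs, resource restriction) in the graph.  For every
participating lab a GoalIteration derivation is created; executing it wires one
full DMTA chain (DoE -> Schedule -> Execution -> Analysis) plus a progress
evaluation that decides whether the lab continues, the goals are met, or the
resources are depleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .derivation import Derivation, DerivationEngine, TaskType
from .doe import SearchSpace, pareto_front
from .kg_store import (C, CONDITION_FIELDS, Graph, Iri, IriMinter, Literal, P,
                       RDF_TYPE, Triple, analysed_experiments)


class Direction(str, Enum):
    maximise = "maximise"
    minimise = "minimise"


class Verdict(str, Enum):
    Continue = "Continue"
    StopGoalsMet = "StopGoalsMet"
    StopResourcesExhausted = "StopResourcesExhausted"


_DEFAULT_DIRECTIONS = {"yield": Direction.maximise,
                       "run_material_cost": Direction.minimise}


@dataclass(frozen=True)
class Goal:
    objective: str               # "yield" | "run_material_cost"
    direction: Direction
    threshold: float

    def __post_init__(self) -> None:
        if self.objective not in _DEFAULT_DIRECTIONS:
            raise ValueError(f"unknown objective {self.objective!r}")
        if not abs(self.threshold) < float("inf"):
            raise ValueError("threshold must be finite")

    def satisfied_by(self, yield_pct: float, cost: float) -> bool:
        value = yield_pct if self.objective == "yield" else cost
        if self.direction is Direction.maximise:
            return value >= self.threshold
        return value <= self.threshold


@dataclass
class Restriction:
    cycle_allowance: int         # max experiments campaign-wide
    deadline: int                # logical-tick budget

    def __post_init__(self) -> None:
        # allowance 0 is legal (degenerate campaign that stops immediately)
        if self.cycle_allowance < 0 or self.deadline <= 0:
            raise ValueError("cycle_allowance must be >= 0 and deadline > 0")


@dataclass
class GoalSet:
    iri: Iri
    goals: list
    restriction: Restriction
    labs: list                   # lab IRIs
    reaction: Iri
    search_space: SearchSpace

    def __post_init__(self) -> None:
        if not self.labs:
            raise ValueError("a goal set needs at least one participating lab")


@dataclass
class GoalDecision:
    verdict: Verdict
    rationale: str
    pareto_snapshot: list        # (yield, cost) tuples

    def __post_init__(self) -> None:
        if self.verdict is Verdict.StopGoalsMet and not self.pareto_snapshot:
            raise ValueError("StopGoalsMet requires a non-empty Pareto snapshot")


class GoalRequestError(ValueError):
    pass


def parse_goal_request(graph: Graph, minter: IriMinter, config: dict) -> GoalSet:
    """Translate a request config into GoalSet triples plus a typed view.

    Required keys: ``objectives`` (list of {objective, threshold[, direction]}),
    ``search_space`` (the four variables -> [lower, upper]), ``labs``,
    ``cycle_allowance``, ``deadline``.  Labs must already exist in the graph.
    """
    missing = [k for k in ("objectives", "search_space", "labs",
                           "cycle_allowance", "deadline") if k not in config]
    if missing:
        raise GoalRequestError(f"goal request missing fields: {missing}")
    space = SearchSpace(bounds={k: tuple(v) for k, v in config["search_space"].items()})
    goals = []
    for spec in config["objectives"]:
        if "objective" not in spec or "threshold" not in spec:
            raise GoalRequestError(f"objective entry missing fields: {spec}")
        direction = Direction(spec.get(
            "direction", _DEFAULT_DIRECTIONS[spec["objective"]].value))
        goals.append(Goal(spec["objective"], direction, float(spec["threshold"])))
    labs = [lab if isinstance(lab, Iri) else Iri(lab) for lab in config["labs"]]
    for lab in labs:
        if not graph.query(lab, RDF_TYPE, C.Lab):
            raise GoalRequestError(f"unknown lab IRI: {lab.value}")
    restriction = Restriction(int(config["cycle_allowance"]), int(config["deadline"]))

    gs_iri = minter.mint("GoalSet")
    reaction = Iri(config.get("reaction", gs_iri.value + "/reaction"))
    triples = [Triple(gs_iri, RDF_TYPE, C.GoalSet),
               Triple(gs_iri, P.forReaction, reaction)]
    for goal in goals:
        g_iri = minter.mint("Goal")
        triples += [Triple(gs_iri, P.hasGoal, g_iri),
                    Triple(g_iri, RDF_TYPE, C.Goal),
                    Triple(g_iri, P.hasObjective, Literal.of(goal.objective)),
                    Triple(g_iri, P.hasDirection, Literal.of(goal.direction.value)),
                    Triple(g_iri, P.hasThreshold, Literal.of(goal.threshold))]
    r_iri = minter.mint("Restriction")
    triples += [Triple(gs_iri, P.hasRestriction, r_iri),
                Triple(r_iri, RDF_TYPE, C.Restriction),
                Triple(r_iri, P.hasCycleAllowance, Literal.of(restriction.cycle_allowance)),
                Triple(r_iri, P.hasDeadline, Literal.of(restriction.deadline))]
    for lab in labs:
        triples.append(Triple(gs_iri, P.hasLab, lab))
    for name in CONDITION_FIELDS:
        lo, hi = space.bounds[name]
        b_iri = Iri(gs_iri.value + "/bounds/" + name)
        triples += [Triple(gs_iri, P.hasSearchSpace, b_iri),
                    Triple(b_iri, P.boundsVariable, Literal.of(name)),
                    Triple(b_iri, P.hasLowerBound, Literal.of(float(lo))),
                    Triple(b_iri, P.hasUpperBound, Literal.of(float(hi)))]
    graph.add_triples(triples)
    return GoalSet(iri=gs_iri, goals=goals, restriction=restriction, labs=labs,
                   reaction=reaction, search_space=space)


def spawn_goal_iterations(engine: DerivationEngine, goalset: GoalSet,
                          labs: Optional[list] = None) -> list:
    """One GoalIteration derivation per participating lab (ROGI agent)."""
    rogi = engine.agent_for(TaskType.GoalIteration)
    out = []
    for lab in (labs if labs is not None else goalset.labs):
        d = engine.create_derivation(rogi, [goalset.iri, lab], TaskType.GoalIteration,
                                     output_class="GoalIteration")
        out.append(d)
    return out


def rogi_plan_iteration(engine: DerivationEngine, goalset: GoalSet, lab: Iri,
                        iteration: Iri) -> dict:
    """Wire one DMTA chain with placeholder outputs feeding stage to stage.

    Raises LookupError when a required agent is unregistered — the caller's
    GoalIteration derivation then lands in Error without touching other labs.
    """
    doe_d = engine.create_derivation(
        engine.agent_for(TaskType.DoE), [goalset.iri, lab], TaskType.DoE,
        output_class="ReactionExperiment")
    sched_d = engine.create_derivation(
        engine.agent_for(TaskType.Schedule), [doe_d.outputs[0]], TaskType.Schedule,
        output_class="EquipmentAssignment")
    exec_d = engine.create_derivation(
        engine.agent_for(TaskType.Execution), [sched_d.outputs[0]], TaskType.Execution,
        output_class="Chromatogram")
    ana_d = engine.create_derivation(
        engine.agent_for(TaskType.Analysis), [exec_d.outputs[0]], TaskType.Analysis,
        output_class="PerformanceIndicator")
    eval_d = engine.create_derivation(
        engine.agent_for(TaskType.ProgressEvaluation),
        [ana_d.outputs[0], goalset.iri, lab], TaskType.ProgressEvaluation,
        output_class="GoalDecision")
    chain = {"doe": doe_d, "schedule": sched_d, "execution": exec_d,
             "analysis": ana_d, "evaluation": eval_d}
    triples = [Triple(iteration, RDF_TYPE, C.GoalIteration),
               Triple(iteration, P.hasLab, lab)]
    for d in chain.values():
        triples.append(Triple(d.iri, P.partOfIteration, iteration))
    engine.graph.add_triples(triples)
    return chain


def evaluate_progress(graph: Graph, goalset: GoalSet, *, executed: int,
                      remaining_allowance: int, tick: int, minter: IriMinter,
                      is_control=None) -> GoalDecision:
    """Check the Pareto front against the goal thresholds and the resources.

    StopGoalsMet requires a single front point satisfying every goal jointly.
    Resource checks: campaign-wide allowance and the logical-tick deadline.
    The decision is written to the graph.
    """
    points = []
    for exp in analysed_experiments(graph, include_abnormal=False):
        if is_control is not None and is_control(exp.iri):
            continue
        points.append((exp.indicators.yield_pct, exp.indicators.run_material_cost))
    front = pareto_front(points) if points else None
    snapshot = [tuple(p) for p in front.points] if front is not None else []

    goals_met = any(all(goal.satisfied_by(y, c) for goal in goalset.goals)
                    for (y, c) in snapshot)
    if goals_met:
        decision = GoalDecision(Verdict.StopGoalsMet,
                                f"a Pareto point satisfies all {len(goalset.goals)} "
                                "goal thresholds jointly", snapshot)
    elif remaining_allowance <= 0:
        decision = GoalDecision(Verdict.StopResourcesExhausted,
                                f"cycle allowance exhausted after {executed} "
                                "experiments", snapshot)
    elif tick >= goalset.restriction.deadline:
        decision = GoalDecision(Verdict.StopResourcesExhausted,
                                f"deadline of {goalset.restriction.deadline} logical "
                                f"ticks exceeded (now {tick})", snapshot)
    else:
        decision = GoalDecision(Verdict.Continue,
                                "goals unmet and resources remain", snapshot)
    d_iri = minter.mint("GoalDecision")
    graph.add_triples([
        Triple(d_iri, RDF_TYPE, C.GoalDecision),
        Triple(goalset.iri, P.hasDecision, d_iri),
        Triple(d_iri, P.hasVerdict, Literal.of(decision.verdict.value)),
        Triple(d_iri, P.hasRationale, Literal.of(decision.rationale)),
    ])
    return decision
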