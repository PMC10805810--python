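"""Knowledge-graph-native asynchronous workflow engine.

A *derivation* is one unit of agent work: typed inputs, pre-minted placeholder
outputs, a status, and the logical-clock tick at which it finished.  Agents
register for a task type and are polled round-robin; a derivation executes only
once all of its inputs exist and every upstream derivation producing them has
finished.  Handler failures mark the derivation ``Error`` without blocking
independent branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Optional

from .kg_store import C, Graph, Iri, IriMinter, Literal, P, RDF_TYPE, Triple


class TaskType(str, Enum):
    GoalIteration = "GoalIteration"
    DoE = "DoE"
    Schedule = "Schedule"
    Execution = "Execution"
    Analysis = "Analysis"
    ProgressEvaluation = "ProgressEvaluation"


class DerivationStatus(str, Enum):
    Requested = "Requested"
    InProgress = "InProgress"
    Finished = "Finished"
    Error = "Error"


@dataclass(frozen=True)
class AgentRegistration:
    agent_iri: Iri
    task_type: TaskType
    poll_interval: int = 1

    def __post_init__(self) -> None:
        if self.poll_interval < 1:
            raise ValueError("poll_interval must be >= 1 logical tick")


@dataclass
class Derivation:
    iri: Iri
    agent: Iri
    task_type: TaskType
    inputs: list[Iri]
    outputs: list[Iri]          # placeholder IRIs minted at creation
    status: DerivationStatus = DerivationStatus.Requested
    timestamp: int = 0          # store clock at the last status change
    error_message: Optional[str] = None


@dataclass(frozen=True)
class Event:
    tick: int
    agent: Iri
    derivation: Iri
    transition: str             # e.g. "Requested->InProgress"


@dataclass
class RunResult:
    events: list[Event]
    deadlocked: list[Iri]       # requested derivations with no satisfiable upstream
    stalled: list[Iri]          # requested derivations blocked by an upstream Error

    @property
    def deadlock(self) -> bool:
        return bool(self.deadlocked)


Handler = Callable[["DerivationEngine", Derivation], None]


class DerivationEngine:
    """Manages derivations over a :class:`Graph` with deterministic round-robin polling."""

    def __init__(self, graph: Graph, minter: Optional[IriMinter] = None):
        self.graph = graph
        self.minter = minter or IriMinter(0)
        self.registrations: list[AgentRegistration] = []
        self.handlers: dict[tuple[Iri, TaskType], Handler] = {}
        self.derivations: dict[Iri, Derivation] = {}
        self._order: list[Iri] = []                 # creation order, oldest first
        self.producer_of: dict[Iri, Iri] = {}       # output IRI -> derivation IRI
        self.events: list[Event] = []
        self._tick = 0

    # -- registration ------------------------------------------------------

    def register_agent(self, agent_iri: Iri, task_type: TaskType,
                       handler: Optional[Handler] = None, poll_interval: int = 1) -> AgentRegistration:
        if any(r.agent_iri == agent_iri and r.task_type == task_type
               for r in self.registrations):
            raise ValueError(f"duplicate registration: {agent_iri} / {task_type.value}")
        reg = AgentRegistration(agent_iri, task_type, poll_interval)
        self.registrations.append(reg)
        if handler is not None:
            self.handlers[(agent_iri, task_type)] = handler
        self.graph.add_triples([
            Triple(agent_iri, RDF_TYPE, C.Agent),
            Triple(agent_iri, P.hasTaskType, Literal.of(task_type.value)),
        ])
        return reg

    def agent_for(self, task_type: TaskType) -> Iri:
        for reg in self.registrations:
            if reg.task_type == task_type:
                return reg.agent_iri
        raise LookupError(f"no agent registered for task type {task_type.value}")

    # -- creation ----------------------------------------------------------

    def create_derivation(self, agent: Iri, inputs: Iterable[Iri], task_type: TaskType,
                          n_outputs: int = 1, output_class: str = "Entity",
                          require_inputs_exist: bool = True) -> Derivation:
        """Create a ``Requested`` derivation with pre-minted placeholder outputs.

        ``require_inputs_exist=False`` lets tests wire pathological graphs
        (e.g. cycles) that the engine must detect rather than execute.
        """
        if (agent, task_type) not in self.handlers and not any(
                r.agent_iri == agent and r.task_type == task_type for r in self.registrations):
            raise ValueError(f"agent {agent} not registered for {task_type.value}")
        inputs = list(inputs)
        if require_inputs_exist:
            for i in inputs:
                if not (self.graph.has_subject(i) or i in self.producer_of):
                    raise ValueError(f"derivation input does not exist: {i}")
        iri = self.minter.mint("Derivation")
        outputs = [self.minter.mint(output_class) for _ in range(n_outputs)]
        d = Derivation(iri=iri, agent=agent, task_type=task_type, inputs=inputs,
                       outputs=outputs, timestamp=self.graph.clock)
        self.derivations[iri] = d
        self._order.append(iri)
        for o in outputs:
            self.producer_of[o] = iri
        triples = [Triple(iri, RDF_TYPE, C.Derivation),
                   Triple(iri, P.hasAgent, agent),
                   Triple(iri, P.hasTaskType, Literal.of(task_type.value))]
        triples += [Triple(iri, P.hasInput, i) for i in inputs]
        triples += [Triple(iri, P.hasOutput, o) for o in outputs]
        self.graph.add_triples(triples)
        self.graph.set_value(iri, P.hasStatus, DerivationStatus.Requested.value)
        return d

    # -- status ------------------------------------------------------------

    def is_outdated(self, derivation: Derivation) -> bool:
        """True iff any input was written after the derivation finished."""
        if derivation.iri not in self.derivations:
            raise KeyError(f"unknown derivation {derivation.iri}")
        return any(self.graph.last_write(i) > derivation.timestamp
                   for i in derivation.inputs)

    def mark_outdated(self, derivation: Derivation) -> None:
        derivation.status = DerivationStatus.Requested
        derivation.error_message = None
        self.graph.set_value(derivation.iri, P.hasStatus, DerivationStatus.Requested.value)

    def upstream(self, derivation: Derivation) -> list[Derivation]:
        seen = []
        for i in derivation.inputs:
            prod = self.producer_of.get(i)
            if prod is not None and prod != derivation.iri:
                seen.append(self.derivations[prod])
        return seen

    def _executable(self, d: Derivation) -> bool:
        if d.status is not DerivationStatus.Requested:
            return False
        for i in d.inputs:
            prod = self.producer_of.get(i)
            if prod is not None and prod != d.iri:
                if self.derivations[prod].status is not DerivationStatus.Finished:
                    return False
            elif not self.graph.has_subject(i):
                return False
        return True

    # -- execution ---------------------------------------------------------

    def _transition(self, d: Derivation, status: DerivationStatus) -> None:
        old = d.status
        d.status = status
        d.timestamp = self.graph.clock
        self.graph.set_value(d.iri, P.hasStatus, status.value)
        self.graph.set_value(d.iri, P.hasTimestamp, self.graph.clock)
        d.timestamp = self.graph.clock
        self.events.append(Event(self._tick, d.agent, d.iri,
                                 f"{old.value}->{status.value}"))

    def poll_and_execute(self, agent: Iri, task_type: Optional[TaskType] = None,
                         handler: Optional[Handler] = None) -> list[Derivation]:
        """Execute every currently-executable Requested derivation of this agent.

        Oldest request first.  Output triples, the Finished status and the new
        timestamp land in the same logical write sequence; a handler exception
        records Error plus the message and writes no outputs.
        """
        executed = []
        for iri in list(self._order):
            d = self.derivations[iri]
            if d.agent != agent:
                continue
            if task_type is not None and d.task_type != task_type:
                continue
            if not self._executable(d):
                continue
            h = handler or self.handlers.get((agent, d.task_type))
            if h is None:
                raise LookupError(f"no handler for {agent} / {d.task_type.value}")
            self._transition(d, DerivationStatus.InProgress)
            try:
                h(self, d)
            except Exception as exc:  # noqa: BLE001 - agent errors are terminal data
                d.error_message = f"{type(exc).__name__}: {exc}"
                self.graph.set_value(d.iri, P.hasErrorMessage, d.error_message)
                self._transition(d, DerivationStatus.Error)
                continue
            self._transition(d, DerivationStatus.Finished)
            executed.append(d)
        return executed

    def run_until_quiescent(self, max_ticks: int = 10_000) -> RunResult:
        """Round-robin agent polling until nothing is executable or the budget ends."""
        if max_ticks <= 0:
            raise ValueError("max_ticks must be > 0")
        start = len(self.events)
        while self._tick < max_ticks:
            progressed = False
            for reg in list(self.registrations):
                self._tick += 1
                if self._tick % reg.poll_interval != 0 and reg.poll_interval > 1:
                    continue
                if self.poll_and_execute(reg.agent_iri, reg.task_type):
                    progressed = True
                if self._tick >= max_ticks:
                    break
            if not progressed:
                break
        deadlocked, stalled = [], []
        for iri in self._order:
            d = self.derivations[iri]
            if d.status is not DerivationStatus.Requested:
                continue
            if self._blocked_by_error(d):
                stalled.append(iri)
            else:
                deadlocked.append(iri)
        return RunResult(events=self.events[start:], deadlocked=deadlocked, stalled=stalled)

    def _blocked_by_error(self, d: Derivation, _seen: Optional[set] = None) -> bool:
        seen = _seen or set()
        if d.iri in seen:
            return False  # cycle, not an error stall
        seen.add(d.iri)
        for up in self.upstream(d):
            if up.status is DerivationStatus.Error:
                return True
            if up.status is DerivationStatus.Requested and self._blocked_by_error(up, seen):
                return True
        return False

    # -- export ------------------------------------------------------------

    def events_table(self) -> list[dict]:
        return [{"tick": e.tick, "agent": e.agent.value, "derivation": e.derivation.value,
                 "transition": e.transition} for e in self.events]
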