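"""In-memory triple store with a Turtle subset reader/writer and the domain vocabulary.

Every other module reads and writes campaign state through :class:`Graph` so the
whole run is expressible as subject--predicate--object statements and can be
exported as provenance.  The store keeps an integer logical clock that advances
on every write batch; per-subject last-write ticks back the staleness checks of
the derivation engine.
"""

from __future__ import annotations

import re
import uuid
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Union

KG = "https://example.org/kgsdl/"
XSD = "http://www.w3.org/2001/XMLSchema#"
RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"

PREFIXES = {"kg": KG, "xsd": XSD, "rdf": RDF}

XSD_STRING = XSD + "string"
XSD_DOUBLE = XSD + "double"
XSD_INTEGER = XSD + "integer"
XSD_BOOLEAN = XSD + "boolean"


@dataclass(frozen=True, order=True)
class Iri:
    """A namespaced identifier.  Must be non-empty and contain a scheme/prefix."""

    value: str

    def __post_init__(self) -> None:
        if not self.value or ":" not in self.value:
            raise ValueError(f"malformed IRI: {self.value!r}")

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return self.value


@dataclass(frozen=True, order=True)
class Literal:
    """A typed literal: lexical form plus explicit datatype IRI."""

    lexical: str
    datatype: str = XSD_STRING

    @staticmethod
    def of(value: Union[str, int, float, bool]) -> "Literal":
        if isinstance(value, bool):
            return Literal("true" if value else "false", XSD_BOOLEAN)
        if isinstance(value, int):
            return Literal(str(value), XSD_INTEGER)
        if isinstance(value, float):
            return Literal(repr(value), XSD_DOUBLE)
        if isinstance(value, str):
            return Literal(value, XSD_STRING)
        raise TypeError(f"unsupported literal value: {value!r}")

    def to_python(self) -> Union[str, int, float, bool]:
        if self.datatype == XSD_INTEGER:
            return int(self.lexical)
        if self.datatype == XSD_DOUBLE:
            return float(self.lexical)
        if self.datatype == XSD_BOOLEAN:
            return self.lexical == "true"
        return self.lexical


Node = Union[Iri, Literal]


@dataclass(frozen=True)
class Triple:
    subject: Iri
    predicate: Iri
    object: Node

    def __post_init__(self) -> None:
        if not isinstance(self.subject, Iri):
            raise ValueError(f"triple subject must be an IRI (no blank nodes): {self!r}")
        if not isinstance(self.predicate, Iri):
            raise ValueError(f"triple predicate must be an IRI: {self!r}")
        if not isinstance(self.object, (Iri, Literal)):
            raise ValueError(f"triple object must be an IRI or typed literal: {self!r}")

    def sort_key(self) -> tuple:
        o = self.object
        okey = (0, o.value, "") if isinstance(o, Iri) else (1, o.lexical, o.datatype)
        return (self.subject.value, self.predicate.value, okey)


class TurtleParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class Graph:
    """Set of triples with pattern queries, logical clock and Turtle round trip."""

    def __init__(self) -> None:
        self._triples: set[Triple] = set()
        self._by_subject: dict[Iri, set[Triple]] = defaultdict(set)
        self.clock: int = 0
        self._last_write: dict[Iri, int] = {}

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._triples

    def __iter__(self) -> Iterator[Triple]:
        return iter(sorted(self._triples, key=Triple.sort_key))

    # -- writes ------------------------------------------------------------

    def add_triples(self, triples: Iterable[Triple]) -> "Graph":
        """Add a batch of triples; idempotent for duplicates.

        Advances the store-wide logical clock once per batch and records the
        new tick as the last-write time of every touched subject.
        """
        batch = list(triples)
        for t in batch:
            if not isinstance(t, Triple):
                raise ValueError(f"not a triple: {t!r}")
        if not batch:
            return self
        self.clock += 1
        for t in batch:
            self._triples.add(t)
            self._by_subject[t.subject].add(t)
            self._last_write[t.subject] = self.clock
        return self

    def add(self, subject: Iri, predicate: Iri, obj: Union[Node, str, int, float, bool]) -> "Graph":
        if not isinstance(obj, (Iri, Literal)):
            obj = Literal.of(obj)
        return self.add_triples([Triple(subject, predicate, obj)])

    def remove_triples(self, triples: Iterable[Triple]) -> "Graph":
        batch = [t for t in triples if t in self._triples]
        if not batch:
            return self
        self.clock += 1
        for t in batch:
            self._triples.discard(t)
            self._by_subject[t.subject].discard(t)
            self._last_write[t.subject] = self.clock
        return self

    def set_value(self, subject: Iri, predicate: Iri, obj: Union[Node, str, int, float, bool]) -> "Graph":
        """Functional-property write: replace any existing (s, p, *) statement."""
        self.remove_triples(self.query(subject, predicate, None))
        return self.add(subject, predicate, obj)

    def last_write(self, subject: Iri) -> int:
        return self._last_write.get(subject, 0)

    def has_subject(self, subject: Iri) -> bool:
        return bool(self._by_subject.get(subject))

    # -- queries -----------------------------------------------------------

    def query(self, s: Optional[Iri] = None, p: Optional[Iri] = None,
              o: Optional[Node] = None) -> list[Triple]:
        """Match a (s, p, o) pattern; ``None`` is a wildcard.  Sorted output."""
        if s is not None:
            candidates: Iterable[Triple] = self._by_subject.get(s, ())
        else:
            candidates = self._triples
        out = [t for t in candidates
               if (p is None or t.predicate == p) and (o is None or t.object == o)]
        out.sort(key=Triple.sort_key)
        return out

    def value(self, s: Iri, p: Iri) -> Optional[Node]:
        matches = self.query(s, p, None)
        return matches[0].object if matches else None

    def pyvalue(self, s: Iri, p: Iri):
        v = self.value(s, p)
        if isinstance(v, Literal):
            return v.to_python()
        return v

    def subjects_of_type(self, cls: Iri) -> list[Iri]:
        return [t.subject for t in self.query(None, RDF_TYPE, cls)]

    # -- Turtle ------------------------------------------------------------

    def to_turtle(self) -> str:
        lines = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(PREFIXES.items())]
        lines.append("")
        for t in self:
            lines.append(f"{_fmt_iri(t.subject)} {_fmt_iri(t.predicate)} {_fmt_node(t.object)} .")
        return "\n".join(lines) + "\n"

    def serialize_turtle(self, path) -> None:
        text = self.to_turtle()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)

    @classmethod
    def from_turtle(cls, text: str) -> "Graph":
        g = cls()
        prefixes = dict(PREFIXES)
        triples = []
        # split on \n only: unicode line separators may occur inside literals
        for lineno, raw in enumerate(text.split("\n"), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@prefix"):
                m = re.match(r"@prefix\s+([A-Za-z][\w-]*)?:\s+<([^>]*)>\s*\.\s*$", line)
                if not m:
                    raise TurtleParseError(f"malformed @prefix directive: {line!r}", lineno)
                prefixes[m.group(1) or ""] = m.group(2)
                continue
            triples.append(_parse_triple_line(line, prefixes, lineno))
        g.add_triples(triples)
        return g

    @classmethod
    def parse_turtle(cls, path) -> "Graph":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_turtle(fh.read())


_IRIREF = r"<([^<>\"{}|^`\\\x00-\x20]*)>"
_PNAME = r"([A-Za-z][\w-]*)?:([A-Za-z_][\w.-]*)?"
_STRING = r'"((?:[^"\\]|\\.)*)"'
_TOKEN = re.compile(
    rf"\s*(?:{_IRIREF}|{_STRING}(?:\^\^(?:{_IRIREF}|{_PNAME}))?|{_PNAME}|(\.))"
)

_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}
_UNESCAPES = {"\\\\": "\\", '\\"': '"', "\\n": "\n", "\\r": "\r", "\\t": "\t"}
_LOCAL_SAFE = re.compile(r"^[A-Za-z_][\w-]*$")


def _fmt_iri(iri: Iri) -> str:
    for prefix, ns in PREFIXES.items():
        if iri.value.startswith(ns):
            local = iri.value[len(ns):]
            if _LOCAL_SAFE.match(local):
                return f"{prefix}:{local}"
    return f"<{iri.value}>"


def _fmt_node(node: Node) -> str:
    if isinstance(node, Iri):
        return _fmt_iri(node)
    escaped = "".join(_ESCAPES.get(c, c) for c in node.lexical)
    if node.datatype == XSD_STRING:
        return f'"{escaped}"'
    return f'"{escaped}"^^{_fmt_iri(Iri(node.datatype))}'


def _unescape(s: str) -> str:
    return re.sub(r"\\.", lambda m: _UNESCAPES.get(m.group(0), m.group(0)[1]), s)


def _parse_triple_line(line: str, prefixes: dict, lineno: int) -> Triple:
    pos, nodes = 0, []
    while pos < len(line):
        m = _TOKEN.match(line, pos)
        if not m:
            raise TurtleParseError(f"unrecognised token at column {pos}: {line[pos:]!r}", lineno)
        pos = m.end()
        iriref, string, dt_iri, dt_prefix, dt_local, prefix, local, dot = m.groups()
        if dot:
            break
        if iriref is not None:
            nodes.append(Iri(iriref))
        elif string is not None:
            if dt_iri is not None:
                datatype = dt_iri
            elif dt_prefix is not None or dt_local is not None:
                datatype = _expand(dt_prefix, dt_local, prefixes, lineno)
            else:
                datatype = XSD_STRING
            nodes.append(Literal(_unescape(string), datatype))
        else:
            nodes.append(Iri(_expand(prefix, local, prefixes, lineno)))
    else:
        raise TurtleParseError("statement not terminated by '.'", lineno)
    if len(nodes) != 3:
        raise TurtleParseError(f"expected 3 terms, found {len(nodes)}", lineno)
    s, p, o = nodes
    if not isinstance(s, Iri) or not isinstance(p, Iri):
        raise TurtleParseError("subject and predicate must be IRIs", lineno)
    return Triple(s, p, o)


def _expand(prefix: Optional[str], local: Optional[str], prefixes: dict, lineno: int) -> str:
    ns = prefixes.get(prefix or "")
    if ns is None:
        raise TurtleParseError(f"unknown prefix {prefix!r}", lineno)
    return ns + (local or "")


class IriMinter:
    """Deterministic IRI factory: uuid5 over (seed, class, counter).

    Two campaigns with the same seed mint identical IRI sequences, so the
    Turtle provenance export is reproducible byte for byte.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self._counts: dict[str, int] = defaultdict(int)

    def mint(self, cls: str) -> Iri:
        n = self._counts[cls]
        self._counts[cls] += 1
        u = uuid.uuid5(uuid.NAMESPACE_URL, f"{KG}{self.seed}/{cls}/{n}")
        return Iri(f"{KG}{cls}/{u}")


# -- vocabulary ------------------------------------------------------------

RDF_TYPE = Iri(RDF + "type")


def _kg(name: str) -> Iri:
    return Iri(KG + name)


class C:
    """Class IRIs of the simplified domain ontology."""

    GoalSet = _kg("GoalSet")
    Goal = _kg("Goal")
    Restriction = _kg("Restriction")
    GoalDecision = _kg("GoalDecision")
    Lab = _kg("Lab")
    ChemicalSpecies = _kg("ChemicalSpecies")
    ChemicalAmount = _kg("ChemicalAmount")
    ReactionExperiment = _kg("ReactionExperiment")
    ReactionCondition = _kg("ReactionCondition")
    PerformanceIndicator = _kg("PerformanceIndicator")
    HistoricalData = _kg("HistoricalData")
    Derivation = _kg("Derivation")
    Agent = _kg("Agent")
    VapourtecRig = _kg("VapourtecRig")
    HplcUnit = _kg("HplcUnit")
    Chromatogram = _kg("Chromatogram")
    ChromatogramPoint = _kg("ChromatogramPoint")
    GoalIteration = _kg("GoalIteration")
    Campaign = _kg("Campaign")


class P:
    """Predicate IRIs (flat vocabulary, no OWL axioms)."""

    hasGoal = _kg("hasGoal")
    hasRestriction = _kg("hasRestriction")
    hasObjective = _kg("hasObjective")
    hasDirection = _kg("hasDirection")
    hasThreshold = _kg("hasThreshold")
    hasCycleAllowance = _kg("hasCycleAllowance")
    hasDeadline = _kg("hasDeadline")
    hasLab = _kg("hasLab")
    forReaction = _kg("forReaction")
    hasLowerBound = _kg("hasLowerBound")
    hasUpperBound = _kg("hasUpperBound")
    boundsVariable = _kg("boundsVariable")
    hasSearchSpace = _kg("hasSearchSpace")
    hasUnit = _kg("hasUnit")

    hasCondition = _kg("hasCondition")
    equivAcetone = _kg("equivAcetone")
    equivNaOH = _kg("equivNaOH")
    residenceTime = _kg("residenceTime")
    reactionTemperature = _kg("reactionTemperature")

    proposedBy = _kg("proposedBy")
    isAssignedTo = _kg("isAssignedTo")
    assignedEquipment = _kg("assignedEquipment")
    hasStatus = _kg("hasStatus")
    hasChromatogram = _kg("hasChromatogram")
    hasPerformanceIndicator = _kg("hasPerformanceIndicator")
    hasYield = _kg("hasYield")
    hasRunMaterialCost = _kg("hasRunMaterialCost")
    hasEFactor = _kg("hasEFactor")
    hasSpaceTimeYield = _kg("hasSpaceTimeYield")
    abnormalFlag = _kg("abnormalFlag")
    basisConcentration = _kg("basisConcentration")
    internalStandardConcentration = _kg("internalStandardConcentration")

    hasAgent = _kg("hasAgent")
    hasTaskType = _kg("hasTaskType")
    hasInput = _kg("hasInput")
    hasOutput = _kg("hasOutput")
    usedHistory = _kg("usedHistory")
    hasTimestamp = _kg("hasTimestamp")
    hasErrorMessage = _kg("hasErrorMessage")
    partOfIteration = _kg("partOfIteration")
    wasDerivedFrom = _kg("wasDerivedFrom")

    hasState = _kg("hasState")
    hasFillLevel = _kg("hasFillLevel")
    containsUnidentifiedComponent = _kg("containsUnidentifiedComponent")
    hasName = _kg("hasName")
    retentionTime = _kg("retentionTime")
    peakArea = _kg("peakArea")
    peakAssignment = _kg("peakAssignment")
    unidentified = _kg("unidentified")
    faultAnnotation = _kg("faultAnnotation")

    isControlRun = _kg("isControlRun")
    hasVerdict = _kg("hasVerdict")
    hasRationale = _kg("hasRationale")
    hasDecision = _kg("hasDecision")
    hasExperiment = _kg("hasExperiment")


class ExperimentStatus(str, Enum):
    Proposed = "Proposed"
    Assigned = "Assigned"
    Executed = "Executed"
    Analysed = "Analysed"


_STATUS_ORDER = {s: i for i, s in enumerate(ExperimentStatus)}


@dataclass(frozen=True)
class ChemicalSpecies:
    identifier: Iri
    name: str
    molar_mass: float                 # g / mol
    density: Optional[float] = None   # g / mL, liquids only
    retention_time: Optional[float] = None  # min, per HPLC method
    price: Optional[float] = None     # currency / mol

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be > 0 for {self.name}")
        if self.retention_time is not None and self.retention_time < 0:
            raise ValueError(f"retention_time must be >= 0 for {self.name}")


@dataclass
class ChemicalAmount:
    container: Iri
    composition: list  # list of (species name, concentration mol/L)
    fill_level: float  # mL
    contains_unidentified_component: bool = False

    def __post_init__(self) -> None:
        if self.fill_level < 0:
            raise ValueError("fill_level must be >= 0")
        for species, conc in self.composition:
            if conc < 0:
                raise ValueError(f"negative concentration for {species}")

    def concentration(self, species: str) -> float:
        for name, conc in self.composition:
            if name == species:
                return conc
        return 0.0


@dataclass(frozen=True)
class ReactionCondition:
    equiv_acetone: float
    equiv_naoh: float
    residence_time: float   # min
    temperature: float      # deg C

    def __post_init__(self) -> None:
        if self.equiv_acetone <= 0 or self.equiv_naoh <= 0:
            raise ValueError("molar equivalents must be > 0")
        if self.residence_time <= 0:
            raise ValueError("residence_time must be > 0")

    def as_array(self):
        import numpy as np
        return np.array([self.equiv_acetone, self.equiv_naoh,
                         self.residence_time, self.temperature])

    @staticmethod
    def from_array(x) -> "ReactionCondition":
        return ReactionCondition(float(x[0]), float(x[1]), float(x[2]), float(x[3]))


@dataclass(frozen=True)
class PerformanceIndicator:
    yield_pct: float
    run_material_cost: float
    abnormal_flag: bool = False
    e_factor: Optional[float] = None
    space_time_yield: Optional[float] = None  # g / L / h

    def __post_init__(self) -> None:
        if self.run_material_cost < 0:
            raise ValueError("cost must be >= 0")
        if not self.abnormal_flag and not (0.0 <= self.yield_pct <= 100.0):
            raise ValueError(
                f"non-abnormal yield must lie in [0, 100]: {self.yield_pct}")


@dataclass
class ReactionExperiment:
    iri: Iri
    condition: ReactionCondition
    status: ExperimentStatus = ExperimentStatus.Proposed
    assigned_lab: Optional[Iri] = None
    assigned_equipment: Optional[Iri] = None
    chromatogram_ref: Optional[Iri] = None
    indicators: Optional[PerformanceIndicator] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if (self.indicators is not None) != (self.status == ExperimentStatus.Analysed):
            raise ValueError(
                f"{self.iri}: indicators present iff status=Analysed "
                f"(status={self.status.value})")
        if _STATUS_ORDER[self.status] >= _STATUS_ORDER[ExperimentStatus.Assigned]:
            if self.assigned_lab is None or self.assigned_equipment is None:
                raise ValueError(f"{self.iri}: assignment fields required at "
                                 f"status {self.status.value}")


CONDITION_FIELDS = ("equiv_acetone", "equiv_naoh", "residence_time", "temperature")

_COND_PREDICATES = {
    "equiv_acetone": P.equivAcetone,
    "equiv_naoh": P.equivNaOH,
    "residence_time": P.residenceTime,
    "temperature": P.reactionTemperature,
}

CONDITION_UNITS = {
    "equiv_acetone": "dimensionless",
    "equiv_naoh": "dimensionless",
    "residence_time": "min",
    "temperature": "degC",
}


def condition_iri(experiment: Iri) -> Iri:
    return Iri(experiment.value + "/condition")


def indicator_iri(experiment: Iri) -> Iri:
    return Iri(experiment.value + "/indicator")


def write_experiment(g: Graph, exp: ReactionExperiment) -> None:
    """Write or refresh the full triple representation of an experiment."""
    exp.validate()
    triples = [Triple(exp.iri, RDF_TYPE, C.ReactionExperiment)]
    cond = condition_iri(exp.iri)
    triples.append(Triple(exp.iri, P.hasCondition, cond))
    triples.append(Triple(cond, RDF_TYPE, C.ReactionCondition))
    for name in CONDITION_FIELDS:
        pred = _COND_PREDICATES[name]
        triples.append(Triple(cond, pred, Literal.of(float(getattr(exp.condition, name)))))
        triples.append(Triple(Iri(cond.value + "/" + name), P.hasUnit,
                              Literal.of(CONDITION_UNITS[name])))
    g.add_triples(triples)
    g.set_value(exp.iri, P.hasStatus, exp.status.value)
    if exp.assigned_lab is not None:
        g.set_value(exp.iri, P.isAssignedTo, exp.assigned_lab)
    if exp.assigned_equipment is not None:
        g.set_value(exp.iri, P.assignedEquipment, exp.assigned_equipment)
    if exp.chromatogram_ref is not None:
        g.set_value(exp.iri, P.hasChromatogram, exp.chromatogram_ref)
    if exp.indicators is not None:
        ind = indicator_iri(exp.iri)
        g.set_value(exp.iri, P.hasPerformanceIndicator, ind)
        g.add(ind, RDF_TYPE, C.PerformanceIndicator)
        g.set_value(ind, P.hasYield, float(exp.indicators.yield_pct))
        g.set_value(ind, P.hasRunMaterialCost, float(exp.indicators.run_material_cost))
        g.set_value(ind, P.abnormalFlag, bool(exp.indicators.abnormal_flag))
        if exp.indicators.e_factor is not None:
            g.set_value(ind, P.hasEFactor, float(exp.indicators.e_factor))
        if exp.indicators.space_time_yield is not None:
            g.set_value(ind, P.hasSpaceTimeYield, float(exp.indicators.space_time_yield))


def read_experiment(g: Graph, iri: Iri) -> ReactionExperiment:
    if not g.query(iri, RDF_TYPE, C.ReactionExperiment):
        raise KeyError(f"no ReactionExperiment at {iri}")
    cond_iri = g.value(iri, P.hasCondition)
    cond = ReactionCondition(
        equiv_acetone=g.pyvalue(cond_iri, P.equivAcetone),
        equiv_naoh=g.pyvalue(cond_iri, P.equivNaOH),
        residence_time=g.pyvalue(cond_iri, P.residenceTime),
        temperature=g.pyvalue(cond_iri, P.reactionTemperature),
    )
    status = ExperimentStatus(g.pyvalue(iri, P.hasStatus))
    indicators = None
    ind = g.value(iri, P.hasPerformanceIndicator)
    if ind is not None:
        indicators = PerformanceIndicator(
            yield_pct=g.pyvalue(ind, P.hasYield),
            run_material_cost=g.pyvalue(ind, P.hasRunMaterialCost),
            abnormal_flag=bool(g.pyvalue(ind, P.abnormalFlag)),
            e_factor=g.pyvalue(ind, P.hasEFactor),
            space_time_yield=g.pyvalue(ind, P.hasSpaceTimeYield),
        )
    return ReactionExperiment(
        iri=iri,
        condition=cond,
        status=status,
        assigned_lab=g.value(iri, P.isAssignedTo),
        assigned_equipment=g.value(iri, P.assignedEquipment),
        chromatogram_ref=g.value(iri, P.hasChromatogram),
        indicators=indicators,
    )


def analysed_experiments(g: Graph, include_abnormal: bool = True) -> list[ReactionExperiment]:
    out = []
    for iri in g.subjects_of_type(C.ReactionExperiment):
        exp = read_experiment(g, iri)
        if exp.status is not ExperimentStatus.Analysed:
            continue
        if not include_abnormal and exp.indicators.abnormal_flag:
            continue
        out.append(exp)
    out.sort(key=lambda e: e.iri.value)
    return out


def validate_campaign_graph(g: Graph) -> list[str]:
    """Check the experiment status invariant over the whole graph."""
    errors = []
    for iri in g.subjects_of_type(C.ReactionExperiment):
        try:
            read_experiment(g, iri)
        except (ValueError, KeyError) as exc:
            errors.append(str(exc))
    return errors
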