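"""Schedule agent and equipment digital twins.

Feasibility-checks a proposed condition against rig ranges and stock, converts
molar equivalents to pump flow rates, depletes feed stock per run, tracks
equipment state (Idle/Busy/OutOfService) and runs the control-condition
onboarding gate for new labs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

from .kg_store import ChemicalAmount, Iri, ReactionCondition

STATE_IDLE = "Idle"
STATE_BUSY = "Busy"
STATE_OUT_OF_SERVICE = "OutOfService"
STATE_OK = "Ok"
STATE_FAULTY = "Faulty"

_RIG_TRANSITIONS = {
    (STATE_IDLE, STATE_BUSY), (STATE_BUSY, STATE_IDLE),
    (STATE_IDLE, STATE_OUT_OF_SERVICE), (STATE_BUSY, STATE_OUT_OF_SERVICE),
}
_HPLC_TRANSITIONS = {
    (STATE_OK, STATE_FAULTY), (STATE_FAULTY, STATE_OK),
    (STATE_OK, STATE_OUT_OF_SERVICE), (STATE_FAULTY, STATE_OUT_OF_SERVICE),
}


class InfeasibleError(ValueError):
    """Condition cannot be realised on the given equipment."""


class InsufficientStockError(InfeasibleError):
    pass


@dataclass
class HplcUnit:
    iri: Iri
    lab: Iri
    method_runtime: float                 # min
    retention_windows: dict               # species -> (lo, hi) min
    internal_standard: str
    response_factors: dict                # species -> area per mol/L
    state: str = STATE_OK
    detection_limit: float = 1e-4         # mol/L
    area_noise_sigma: float = 0.01
    impurity_retention_time: float = 0.25

    def __post_init__(self) -> None:
        if self.internal_standard not in self.retention_windows:
            raise ValueError("internal standard must have a retention window")
        if self.internal_standard not in self.response_factors:
            raise ValueError("internal standard must have a response factor")
        windows = sorted(self.retention_windows.values())
        for (lo1, hi1), (lo2, hi2) in zip(windows, windows[1:]):
            if hi1 > lo2:
                raise ValueError("retention windows must not overlap")
        for species, (lo, hi) in self.retention_windows.items():
            if not (0 <= lo < hi <= self.method_runtime):
                raise ValueError(f"bad retention window for {species}")


@dataclass
class VapourtecRig:
    iri: Iri
    lab: Iri
    reactor_volume: float                 # mL
    temperature_range: tuple              # (lo, hi) degC
    residence_time_range: tuple           # (lo, hi) min
    pump_flow_range: dict                 # pump id -> (lo, hi) mL/min
    pumps: dict                           # pump id -> ChemicalAmount (effective concs)
    hplc: HplcUnit
    feed_densities: dict = field(default_factory=dict)  # pump id -> g/mL
    injection_volume: float = 2.0         # mL benzaldehyde basis per run
    benzaldehyde_pump: str = "A"
    state: str = STATE_IDLE
    last_used_tick: int = 0
    run_count: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("temperature", self.temperature_range),
                               ("residence_time", self.residence_time_range)):
            if not lo < hi:
                raise ValueError(f"{name} range must be well ordered")
        for pump, (lo, hi) in self.pump_flow_range.items():
            if not 0 <= lo < hi:
                raise ValueError(f"pump {pump} flow range must be well ordered")
        if self.benzaldehyde_pump not in self.pumps:
            raise ValueError("benzaldehyde pump missing from pump map")
        if not self.feed_densities:
            self.feed_densities = {p: 0.85 for p in self.pumps}


@dataclass(frozen=True)
class EquipmentSettings:
    rig: Iri
    pump_flow_rates: dict                 # pump id -> mL/min
    reactor_temperature: float            # degC
    residence_time: float                 # min


def to_equipment_settings(condition: ReactionCondition, rig: VapourtecRig) -> EquipmentSettings:
    """Translate molar equivalents into pump flow rates.

    Q_total = reactor_volume / residence_time, and for each co-feed p the
    molar flow ratio Q_p C_p / (Q_A C_A) equals the requested equivalent,
    which gives a closed-form split of Q_total.
    """
    q_total = rig.reactor_volume / condition.residence_time
    c_b = rig.pumps["A"].concentration("benzaldehyde")
    c_ac = rig.pumps["B"].concentration("acetone")
    c_oh = rig.pumps["C"].concentration("naoh")
    if min(c_b, c_ac, c_oh) <= 0:
        raise InfeasibleError("feed concentrations must be positive on pumps A/B/C")
    ratio_b = condition.equiv_acetone * c_b / c_ac
    ratio_c = condition.equiv_naoh * c_b / c_oh
    q_a = q_total / (1.0 + ratio_b + ratio_c)
    flows = {"A": q_a, "B": ratio_b * q_a, "C": ratio_c * q_a}
    for pump, q in flows.items():
        lo, hi = rig.pump_flow_range[pump]
        if not (lo <= q <= hi):
            raise InfeasibleError(
                f"pump {pump} needs {q:.4f} mL/min, outside [{lo}, {hi}] "
                f"(rig {rig.iri.value})")
    return EquipmentSettings(rig=rig.iri, pump_flow_rates=flows,
                             reactor_temperature=condition.temperature,
                             residence_time=condition.residence_time)


def equivalents_from_settings(settings: EquipmentSettings, rig: VapourtecRig) -> tuple:
    """Inverse of :func:`to_equipment_settings`; used by the round-trip invariant."""
    q = settings.pump_flow_rates
    c_b = rig.pumps["A"].concentration("benzaldehyde")
    molar_a = q["A"] * c_b
    return (q["B"] * rig.pumps["B"].concentration("acetone") / molar_a,
            q["C"] * rig.pumps["C"].concentration("naoh") / molar_a)


def dispense_volumes(settings: EquipmentSettings, rig: VapourtecRig) -> dict:
    """Per-pump volume (mL) for one run: a slug of ``injection_volume`` of
    benzaldehyde feed plus proportional co-feed volumes."""
    q_a = settings.pump_flow_rates[rig.benzaldehyde_pump]
    duration = rig.injection_volume / q_a
    return {p: q * duration for p, q in settings.pump_flow_rates.items()}


def has_sufficient_stock(rig: VapourtecRig, settings: EquipmentSettings) -> bool:
    volumes = dispense_volumes(settings, rig)
    return all(rig.pumps[p].fill_level >= v - 1e-12 for p, v in volumes.items())


def consume_stock(rig: VapourtecRig, settings: EquipmentSettings) -> dict:
    """Atomically deplete feed stock for one run; refuse before any depletion."""
    volumes = dispense_volumes(settings, rig)
    for pump, vol in volumes.items():
        if rig.pumps[pump].fill_level < vol - 1e-12:
            raise InsufficientStockError(
                f"pump {pump} holds {rig.pumps[pump].fill_level:.2f} mL, "
                f"needs {vol:.2f} mL")
    for pump, vol in volumes.items():
        amount = rig.pumps[pump]
        amount.fill_level = max(amount.fill_level - vol, 0.0)
    return volumes


def select_equipment(rigs: list, condition: ReactionCondition, goalset_labs: list,
                     tick: int = 0) -> tuple:
    """Pick the most appropriate idle rig: feasibility filter, then
    longest-idle-first (stable tie-break on IRI).  Marks the rig Busy."""
    feasible = []
    for rig in rigs:
        if rig.lab not in goalset_labs:
            continue
        if rig.state != STATE_IDLE or rig.hplc.state != STATE_OK:
            continue
        lo, hi = rig.temperature_range
        if not (lo <= condition.temperature <= hi):
            continue
        lo, hi = rig.residence_time_range
        if not (lo <= condition.residence_time <= hi):
            continue
        try:
            settings = to_equipment_settings(condition, rig)
        except InfeasibleError:
            continue
        if not has_sufficient_stock(rig, settings):
            continue
        feasible.append((rig.last_used_tick, rig.iri.value, rig, settings))
    if not feasible:
        raise InfeasibleError("no feasible equipment for condition "
                              f"{condition!r} in labs {[l.value for l in goalset_labs]}")
    feasible.sort(key=lambda t: (t[0], t[1]))
    _, _, rig, settings = feasible[0]
    set_equipment_state(rig, STATE_BUSY)
    rig.last_used_tick = tick
    return rig, settings


def set_equipment_state(equipment, state: str, reason: str = "",
                        notifications: Optional[list] = None) -> None:
    """Validated state transition; OutOfService is terminal for the campaign.

    A notification record (stand-in for the maintenance email) is appended
    whenever equipment goes OutOfService.
    """
    table = _HPLC_TRANSITIONS if isinstance(equipment, HplcUnit) else _RIG_TRANSITIONS
    if (equipment.state, state) not in table:
        raise ValueError(f"invalid state transition {equipment.state} -> {state} "
                         f"for {equipment.iri.value}")
    equipment.state = state
    if notifications is not None and state == STATE_OUT_OF_SERVICE:
        notifications.append({"equipment": equipment.iri.value, "state": state,
                              "reason": reason})


@dataclass
class ControlGateResult:
    passed: dict        # lab iri value -> bool
    yields: dict        # lab iri value -> list of yields per control condition
    skipped: bool = False
    warning: str = ""

    @property
    def passing_labs(self) -> list:
        return [lab for lab, ok in self.passed.items() if ok]


def verify_control_conditions(labs: list, control_conditions: list,
                              tolerance: float,
                              run_fn: Callable[[Iri, ReactionCondition], float]) -> ControlGateResult:
    """Onboarding gate: each lab runs both control conditions through its full
    execute+analyse path and passes iff every yield lies within ``tolerance``
    (yield percentage points) of the cross-lab consensus (median) for that
    condition.  With only two labs a large disagreement fails both — there is
    no way to tell which rig is wrong — and the campaign aborts.
    """
    if len(control_conditions) != 2:
        raise ValueError("exactly two control conditions are required")
    if len(labs) < 2:
        yields = {lab.value: [run_fn(lab, c) for c in control_conditions] for lab in labs}
        return ControlGateResult(passed={lab.value: True for lab in labs},
                                 yields=yields, skipped=True,
                                 warning="single lab configured: control gate "
                                         "skipped (nothing to compare against)")
    yields = {lab.value: [run_fn(lab, c) for c in control_conditions] for lab in labs}
    passed = {}
    for i, _ in enumerate(control_conditions):
        values = sorted(yields[lab.value][i] for lab in labs)
        mid = len(values) // 2
        consensus = (values[mid] if len(values) % 2
                     else 0.5 * (values[mid - 1] + values[mid]))
        for lab in labs:
            ok = abs(yields[lab.value][i] - consensus) <= tolerance
            passed[lab.value] = passed.get(lab.value, True) and ok
    if not any(passed.values()):
        raise RuntimeError("control-condition gate failed for every lab: "
                           f"yields={yields}")
    return ControlGateResult(passed=passed, yields=yields)
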