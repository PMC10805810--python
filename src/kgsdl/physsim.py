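"""Stand-in for the physical laboratory layer.

A seeded isothermal plug-flow-reactor model of the base-catalysed aldol
condensation (benzaldehyde + acetone -> benzylideneacetone, over-condensation
to dibenzylideneacetone) plus a chromatogram synthesiser with injectable fault
modes.  The rate law and its parameters are declared fixtures — chosen to
reproduce the qualitative behaviour of the real system (yield rises with
temperature, is unimodal in acetone equivalents, depends weakly on residence
time) — and are NOT a fitted model of the true chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

R_GAS = 8.314462618  # J / mol / K

BENZALDEHYDE = "benzaldehyde"
ACETONE = "acetone"
NAOH = "naoh"
PRODUCT = "benzylideneacetone"
SIDE_PRODUCT = "dibenzylideneacetone"

#: g / mol
MOLAR_MASS = {
    BENZALDEHYDE: 106.12,
    ACETONE: 58.08,
    NAOH: 40.00,
    PRODUCT: 146.19,
    SIDE_PRODUCT: 234.29,
    "biphenyl": 154.21,
    "naphthalene": 128.17,
}

FAULT_NONE = "none"
FAULT_IS_PEAK_SHIFT = "is_peak_shift"
FAULT_PRODUCT_PEAK_SHIFT = "product_peak_shift"
FAULT_MODES = (FAULT_NONE, FAULT_IS_PEAK_SHIFT, FAULT_PRODUCT_PEAK_SHIFT)


@dataclass(frozen=True)
class KineticModel:
    """Effective termolecular rate constants with Arrhenius temperature scaling.

    r1 = k1(T) [benzaldehyde][acetone][OH-]     (product formation)
    r2 = k2(T) [product][benzaldehyde][OH-]     (over-condensation)
    """

    k1_ref: float = 1.7       # L^2 mol^-2 min^-1 at t_ref
    k2_ref: float = 0.15
    ea1: float = 70_000.0     # J / mol
    ea2: float = 90_000.0
    t_ref: float = 323.15     # K

    def __post_init__(self) -> None:
        if min(self.k1_ref, self.k2_ref, self.ea1, self.ea2, self.t_ref) <= 0:
            raise ValueError("kinetic parameters must all be positive")
        if not self.ea1 < self.ea2:
            raise ValueError("fixture requires Ea1 < Ea2")

    def rate_constants(self, temperature_c):
        """Arrhenius k(T) = k_ref * exp(-Ea/R * (1/T - 1/T_ref)), T in deg C."""
        t_k = np.asarray(temperature_c, dtype=float) + 273.15
        dinv = 1.0 / t_k - 1.0 / self.t_ref
        return (self.k1_ref * np.exp(-self.ea1 / R_GAS * dinv),
                self.k2_ref * np.exp(-self.ea2 / R_GAS * dinv))


@dataclass
class OutletComposition:
    """Reactor outlet concentrations (mol/L); inert species pass through."""

    concentrations: dict
    inlet_benzaldehyde: float

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c < -1e-12:
                raise ValueError(f"negative outlet concentration for {name}: {c}")
        err = self.balance_error()
        if err > 1e-6:
            raise ValueError(f"benzaldehyde balance violated: relative error {err:.3e}")

    def balance_error(self) -> float:
        """Relative benzaldehyde-unit imbalance: B + P + 2 D vs inlet B."""
        total = (self.concentrations.get(BENZALDEHYDE, 0.0)
                 + self.concentrations.get(PRODUCT, 0.0)
                 + 2.0 * self.concentrations.get(SIDE_PRODUCT, 0.0))
        if self.inlet_benzaldehyde == 0:
            return abs(total)
        return abs(total - self.inlet_benzaldehyde) / self.inlet_benzaldehyde


def integrate_pfr(b0, ac0, oh0, residence_time, temperature_c,
                  kinetics: KineticModel, n_steps: int = 240):
    """Vectorised RK4 integration of the PFR balances over the residence time.

    All arguments broadcast; returns (B, Ac, P, D) outlet arrays.  RK4 with a
    fixed step preserves the linear benzaldehyde invariant B + P + 2D exactly
    (to roundoff) because the invariant annihilates the right-hand side.
    """
    b0_, ac0_, oh, tau, t_c = np.broadcast_arrays(
        np.asarray(b0, float), np.asarray(ac0, float), np.asarray(oh0, float),
        np.asarray(residence_time, float), np.asarray(temperature_c, float))
    k1, k2 = kinetics.rate_constants(t_c)
    # keep k*dt small enough for RK4 stability at extreme residence times
    stiffness = float(np.max((k1 * ac0_ + k2 * b0_) * oh * tau, initial=0.0))
    n_steps = max(n_steps, min(int(np.ceil(stiffness / 0.25)), 200_000))
    dt = tau / n_steps
    b = b0_.copy()
    ac = ac0_.copy()
    p = np.zeros_like(b)
    d = np.zeros_like(b)

    def rhs(bv, av, pv):
        r1 = k1 * bv * av * oh
        r2 = k2 * pv * bv * oh
        return -r1 - r2, -r1, r1 - r2, r2

    for _ in range(n_steps):
        kb1, ka1, kp1, kd1 = rhs(b, ac, p)
        kb2, ka2, kp2, kd2 = rhs(b + 0.5 * dt * kb1, ac + 0.5 * dt * ka1, p + 0.5 * dt * kp1)
        kb3, ka3, kp3, kd3 = rhs(b + 0.5 * dt * kb2, ac + 0.5 * dt * ka2, p + 0.5 * dt * kp2)
        kb4, ka4, kp4, kd4 = rhs(b + dt * kb3, ac + dt * ka3, p + dt * kp3)
        b = b + dt / 6.0 * (kb1 + 2 * kb2 + 2 * kb3 + kb4)
        ac = ac + dt / 6.0 * (ka1 + 2 * ka2 + 2 * ka3 + ka4)
        p = p + dt / 6.0 * (kp1 + 2 * kp2 + 2 * kp3 + kp4)
        d = d + dt / 6.0 * (kd1 + 2 * kd2 + 2 * kd3 + kd4)
    return (np.maximum(b, 0.0), np.maximum(ac, 0.0),
            np.maximum(p, 0.0), np.maximum(d, 0.0))


def simulate_reactor(settings, feeds: dict, kinetics: KineticModel,
                     temperature: float, n_steps: int = 240) -> OutletComposition:
    """Run one experiment: flow-weighted inlet mixing, then PFR integration.

    ``settings`` needs ``pump_flow_rates`` (pump id -> mL/min) and
    ``residence_time`` (min); ``feeds`` maps pump id to a ChemicalAmount whose
    composition lists *effective* concentrations.  Inert species (internal
    standard, impurities) are diluted but not reacted.
    """
    flows = settings.pump_flow_rates
    q_total = sum(flows.values())
    if q_total <= 0:
        raise ValueError("total flow must be positive")
    inlet: dict[str, float] = {}
    for pump_id, q in flows.items():
        feed = feeds[pump_id]
        for species, conc in feed.composition:
            inlet[species] = inlet.get(species, 0.0) + q * conc / q_total
    b_in = inlet.get(BENZALDEHYDE, 0.0)
    b, ac, p, d = integrate_pfr(
        b_in, inlet.get(ACETONE, 0.0), inlet.get(NAOH, 0.0),
        settings.residence_time, temperature, kinetics, n_steps=n_steps)
    if not (np.isfinite(b) and np.isfinite(p)):
        raise ValueError(f"reactor integration failed for settings {settings!r}")
    out = dict(inlet)
    out[BENZALDEHYDE] = float(b)
    out[ACETONE] = float(ac)
    out[PRODUCT] = float(p)
    out[SIDE_PRODUCT] = float(d)
    return OutletComposition(concentrations=out, inlet_benzaldehyde=b_in)


@dataclass(frozen=True)
class ChromatogramPoint:
    retention_time: float   # min
    area: float             # a.u.
    assignment: Optional[str] = None  # species name, "unidentified", or None (raw)


@dataclass
class Chromatogram:
    points: list
    method_runtime: float
    fault_annotation: str = FAULT_NONE

    def __post_init__(self) -> None:
        if self.fault_annotation not in FAULT_MODES:
            raise ValueError(f"unknown fault mode {self.fault_annotation!r}")
        for pt in self.points:
            if not (0.0 <= pt.retention_time <= self.method_runtime):
                raise ValueError(f"retention time {pt.retention_time} outside "
                                 f"[0, {self.method_runtime}]")
            if pt.area < 0:
                raise ValueError("peak areas must be >= 0")


def synthesize_chromatogram(outlet: OutletComposition, hplc, rng: np.random.Generator,
                            fault_mode: str = FAULT_NONE,
                            unidentified_component: bool = False) -> Chromatogram:
    """Turn an outlet composition into pre-integrated HPLC peaks.

    ``hplc`` needs ``retention_windows`` (species -> (lo, hi) min),
    ``response_factors`` (species -> area per mol/L), ``internal_standard``,
    ``method_runtime``, ``detection_limit`` and ``area_noise_sigma``.

    Fault modes reproduce the two failure behaviours observed on the real
    rigs: ``is_peak_shift`` displaces the internal-standard peak out of its
    window and leaves a small spurious peak inside it (downstream
    quantification then reports a grossly superphysical yield);
    ``product_peak_shift`` nudges the product peak just outside its window
    (downstream yield 0 %).
    """
    if fault_mode not in FAULT_MODES:
        raise ValueError(f"unknown fault mode {fault_mode!r}")
    points: list[ChromatogramPoint] = []
    for species, (lo, hi) in sorted(hplc.retention_windows.items()):
        conc = outlet.concentrations.get(species, 0.0)
        if conc <= hplc.detection_limit:
            continue
        half = 0.5 * (hi - lo)
        rt = 0.5 * (lo + hi) + float(rng.uniform(-0.4, 0.4)) * half
        area = hplc.response_factors[species] * conc
        if hplc.area_noise_sigma > 0:
            area *= 1.0 + float(rng.normal(0.0, hplc.area_noise_sigma))
        area = max(area, 0.0)
        if fault_mode == FAULT_IS_PEAK_SHIFT and species == hplc.internal_standard:
            shifted = min(hi + 0.5 * (hi - lo) + 0.5, hplc.method_runtime)
            points.append(ChromatogramPoint(shifted, area))
            spurious = hplc.response_factors[species] * conc * 0.01
            points.append(ChromatogramPoint(0.5 * (lo + hi), spurious))
            continue
        if fault_mode == FAULT_PRODUCT_PEAK_SHIFT and species == PRODUCT:
            rt = min(hi + 0.05 * (hi - lo), hplc.method_runtime)
        points.append(ChromatogramPoint(rt, area))
    if unidentified_component:
        rt = getattr(hplc, "impurity_retention_time", 0.25)
        area = float(abs(rng.normal(1.0, 0.2))) * 0.05
        points.append(ChromatogramPoint(rt, area))
    return Chromatogram(points=points, method_runtime=hplc.method_runtime,
                        fault_annotation=fault_mode)


# -- noise-free ground-truth oracle ----------------------------------------

@dataclass(frozen=True)
class FeedFixture:
    """Effective feed concentrations on the three pumps (mol/L, purity applied)."""

    benzaldehyde: float = 0.5
    acetone: float = 6.73
    naoh: float = 0.1
    internal_standard: float = 0.06
    internal_standard_species: str = "biphenyl"

    def inlet_fractions(self, equiv_acetone, equiv_naoh):
        """Flow fraction of pump A and resulting inlet concentrations.

        Pump flows solve Q_B*C_Ac = e*Q_A*C_B and Q_C*C_OH = f*Q_A*C_B, so the
        inlet depends only on the flow *fractions*, not on the total flow.
        """
        e = np.asarray(equiv_acetone, float)
        f = np.asarray(equiv_naoh, float)
        x_a = 1.0 / (1.0 + e * self.benzaldehyde / self.acetone
                     + f * self.benzaldehyde / self.naoh)
        b0 = self.benzaldehyde * x_a
        return x_a, b0, e * b0, f * b0


def ground_truth_objectives(conditions, kinetics: KineticModel, economics,
                            feeds: Optional[FeedFixture] = None,
                            n_steps: int = 240):
    """Noise-free (yield %, cost) for an (n, 4) array of conditions.

    Bypasses chromatogram synthesis entirely: yield from the integrated outlet,
    cost from the analytic per-mole-benzaldehyde formula.  Used as the oracle
    for optimiser acceptance; identical conditions give identical values.
    """
    if feeds is None:
        feeds = getattr(economics, "feeds", None) or FeedFixture()
    x = np.atleast_2d(np.asarray(conditions, float))
    e, f, tau, temp = x[:, 0], x[:, 1], x[:, 2], x[:, 3]
    _, b0, ac0, oh0 = feeds.inlet_fractions(e, f)
    b, _, p, d = integrate_pfr(b0, ac0, oh0, tau, temp, kinetics, n_steps=n_steps)
    yield_pct = 100.0 * p / b0
    cost = economics.cost_per_basis(e, f)
    if np.ndim(conditions) == 1:
        return float(yield_pct[0]), float(cost if np.ndim(cost) == 0 else cost[0])
    return yield_pct, np.broadcast_to(cost, yield_pct.shape).copy()
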