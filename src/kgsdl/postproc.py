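"""Post-processing agent logic: chromatogram -> performance indicators.

Yield comes from the internal-standard area ratio with a single-point relative
response factor; run material cost counts the pump-sourced chemicals per mole
of benzaldehyde and is exactly linear in each molar-equivalent variable;
E-factor and space-time yield are scaled to the standard 5 mL benzaldehyde
injection.  Superphysical yields are flagged abnormal (kept in provenance,
excluded from optimiser history); 0 % yields are valid history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .physsim import (Chromatogram, ChromatogramPoint, FeedFixture, MOLAR_MASS,
                      PRODUCT)

UNIDENTIFIED = "unidentified"


class QuantificationError(ValueError):
    """Internal standard missing or unusable; the run is analysable only as abnormal."""


@dataclass(frozen=True)
class QuantMethod:
    """Single-point internal-standard quantification parameters for one HPLC unit."""

    internal_standard: str
    relative_response_factors: dict   # species -> RRF (RF_IS / RF_species)
    retention_windows: dict           # species -> (lo, hi) min
    abnormal_yield_threshold: float = 105.0  # % ; ~100 + 3 sigma of the area-noise fixture

    def __post_init__(self) -> None:
        if self.internal_standard not in self.retention_windows:
            raise ValueError("internal standard needs a retention window")
        for species, rrf in self.relative_response_factors.items():
            if rrf <= 0:
                raise ValueError(f"RRF must be > 0 for {species}")

    @staticmethod
    def from_hplc(hplc, abnormal_yield_threshold: float = 105.0) -> "QuantMethod":
        rf_is = hplc.response_factors[hplc.internal_standard]
        rrf = {s: rf_is / rf for s, rf in hplc.response_factors.items()}
        return QuantMethod(internal_standard=hplc.internal_standard,
                           relative_response_factors=rrf,
                           retention_windows=dict(hplc.retention_windows),
                           abnormal_yield_threshold=abnormal_yield_threshold)


@dataclass(frozen=True)
class Economics:
    """Per-mole prices of the pump-sourced chemicals and the cost basis."""

    prices: dict                      # species -> currency / mol
    feeds: FeedFixture = field(default_factory=FeedFixture)
    basis_moles: float = 0.0025       # mol benzaldehyde per standard 5 mL injection
    solvent_price_per_l: float = 0.0

    def __post_init__(self) -> None:
        for species, price in self.prices.items():
            if price < 0:
                raise ValueError(f"negative price for {species}")
        if self.basis_moles <= 0:
            raise ValueError("basis must be > 0")

    def cost_per_basis(self, equiv_acetone, equiv_naoh):
        """Currency per mole of benzaldehyde; exactly linear in each equivalent."""
        f = self.feeds
        for species in ("benzaldehyde", "acetone", "naoh", f.internal_standard_species):
            if species not in self.prices:
                raise KeyError(f"no price configured for species {species!r}")
        e = np.asarray(equiv_acetone, float)
        n = np.asarray(equiv_naoh, float)
        cost = (self.prices["benzaldehyde"]
                + e * self.prices["acetone"]
                + n * self.prices["naoh"]
                + (f.internal_standard / f.benzaldehyde)
                * self.prices[f.internal_standard_species])
        if self.solvent_price_per_l:
            litres_per_mol = 1.0 / f.benzaldehyde + e / f.acetone + n / f.naoh
            cost = cost + self.solvent_price_per_l * litres_per_mol
        if cost.ndim == 0:
            return float(cost)
        return cost


def assign_peaks(chromatogram: Chromatogram, method: QuantMethod) -> Chromatogram:
    """Assign each peak to the species whose retention window contains it.

    At most one peak per species (largest area wins); everything else is
    marked unidentified.
    """
    best: dict[str, ChromatogramPoint] = {}
    leftovers: list[ChromatogramPoint] = []
    for pt in chromatogram.points:
        hit = None
        for species, (lo, hi) in method.retention_windows.items():
            if lo <= pt.retention_time <= hi:
                hit = species
                break
        if hit is None:
            leftovers.append(ChromatogramPoint(pt.retention_time, pt.area, UNIDENTIFIED))
        elif hit in best:
            keep, drop = ((pt, best[hit]) if pt.area > best[hit].area else (best[hit], pt))
            best[hit] = ChromatogramPoint(keep.retention_time, keep.area, hit)
            leftovers.append(ChromatogramPoint(drop.retention_time, drop.area, UNIDENTIFIED))
        else:
            best[hit] = ChromatogramPoint(pt.retention_time, pt.area, hit)
    points = sorted(list(best.values()) + leftovers, key=lambda p: p.retention_time)
    return Chromatogram(points=points, method_runtime=chromatogram.method_runtime,
                        fault_annotation=chromatogram.fault_annotation)


def _area_of(chromatogram: Chromatogram, species: str) -> Optional[float]:
    for pt in chromatogram.points:
        if pt.assignment == species:
            return pt.area
    return None


def compute_yield(assigned: Chromatogram, method: QuantMethod,
                  internal_standard_conc: float, basis_conc: float) -> float:
    """Yield (%) of product relative to the benzaldehyde fed.

    n_product = (A_product / A_IS) * RRF_product * n_IS on a common volume
    basis, so concentrations substitute for moles.  Product peak absent ->
    0 %.  Internal standard absent or zero-area -> QuantificationError (the
    caller marks the run abnormal).
    """
    a_is = _area_of(assigned, method.internal_standard)
    if a_is is None or a_is <= 0.0:
        raise QuantificationError(
            f"internal standard ({method.internal_standard}) peak missing or empty")
    if basis_conc <= 0:
        raise ValueError("basis concentration must be positive")
    a_product = _area_of(assigned, PRODUCT)
    if a_product is None:
        return 0.0
    rrf = method.relative_response_factors[PRODUCT]
    n_product = (a_product / a_is) * rrf * internal_standard_conc
    return 100.0 * n_product / basis_conc


def compute_cost(condition, economics: Economics) -> float:
    """Run material cost for one condition (currency per mole benzaldehyde)."""
    return float(economics.cost_per_basis(condition.equiv_acetone, condition.equiv_naoh))


def compute_efactor_sty(product_conc: float, settings, reactor_volume_ml: float,
                        feed_densities: dict, benzaldehyde_pump: str = "A",
                        injection_volume_ml: float = 5.0):
    """(E-factor, space-time yield g/L/h) for one analysed run.

    The run is scaled to a standard benzaldehyde injection volume; every feed
    pump contributes volume proportional to its flow-rate share relative to
    pump A.  Total input mass = dispensed volumes x feed densities.
    """
    flows = settings.pump_flow_rates
    q_a = flows[benzaldehyde_pump]
    if q_a <= 0:
        raise ValueError("benzaldehyde pump flow must be positive")
    duration = injection_volume_ml / q_a  # min
    volumes = {p: q * duration for p, q in flows.items()}  # mL
    mass_in = sum(volumes[p] * feed_densities[p] for p in flows)  # g
    total_volume_l = sum(volumes.values()) / 1000.0
    mass_product = product_conc * total_volume_l * MOLAR_MASS[PRODUCT]  # g
    tau_h = settings.residence_time / 60.0
    reactor_l = reactor_volume_ml / 1000.0
    if mass_product <= 0:
        return None, 0.0
    e_factor = (mass_in - mass_product) / mass_product
    sty = mass_product / (reactor_l * tau_h)
    return e_factor, sty


def flag_abnormal(yield_pct: Optional[float], method: QuantMethod,
                  internal_standard_failed: bool = False) -> bool:
    """Abnormal iff the yield is superphysical or the internal standard failed.

    0 % yields are normal data and stay in history.
    """
    if internal_standard_failed:
        return True
    if yield_pct is None or not math.isfinite(yield_pct):
        return True
    return yield_pct > method.abnormal_yield_threshold
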