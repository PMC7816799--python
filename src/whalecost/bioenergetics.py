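"""Lunge-feeding energy accounting.

Per-lunge energy intake is engulfment volume x krill density x krill energy
density x assimilation efficiency.  Krill density is drawn per lunge from a
lognormal distribution parameterized by its geometric mean and geometric SD.
Daily expenditure is linear in the hours spent in each behavioral state, with
activity-specific cost rates; reproduction (mid-pregnancy gestation or peak
lactation) adds a fixed daily cost.  Net intake applies a foraging floor: if
the incremental cost of foraging exceeds what foraging brought in, the net
gain from foraging is zero, but the day's net intake can still be negative
through maintenance costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

STATES = ("NF", "SF", "DF")

__all__ = [
    "KrillDistribution",
    "WhaleParams",
    "EnergyBudget",
    "energy_per_lunge",
    "gross_daily_intake",
    "daily_expenditure",
    "net_intake",
    "reproduction_cost",
    "load_bioenergetics_config",
    "krill_from_config",
]


@dataclass(frozen=True)
class KrillDistribution:
    """Lognormal krill-density distribution (kg/m^3).

    Parameterized by geometric mean and geometric SD: log densities are
    normal with mean ln(geometric_mean) and SD ln(geometric_sd).
    """

    label: str
    geometric_mean: float
    geometric_sd: float

    def __post_init__(self) -> None:
        if self.geometric_mean <= 0:
            raise ValueError("geometric mean must be positive")
        if self.geometric_sd <= 1:
            raise ValueError("geometric SD must exceed 1")

    @property
    def log_mean(self) -> float:
        return float(np.log(self.geometric_mean))

    @property
    def log_sd(self) -> float:
        return float(np.log(self.geometric_sd))

    @property
    def mean(self) -> float:
        """Arithmetic mean density, exp(mu + sigma^2 / 2)."""
        return float(np.exp(self.log_mean + 0.5 * self.log_sd**2))

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n i.i.d. density draws (kg/m^3), all positive."""
        return rng.lognormal(self.log_mean, self.log_sd, size=int(n))


@dataclass(frozen=True)
class WhaleParams:
    """Size-dependent feeding and metabolic parameters for one individual."""

    length_m: float
    engulfment_coef: float = 1.03e-3
    engulfment_exponent: float = 3.56
    assimilation_efficiency: float = 0.84
    krill_energy_density: float = 4.2  # MJ/kg
    reference_length_m: float = 22.0
    metabolic_exponent: float = 2.25
    reference_cost_rates: dict = field(
        default_factory=lambda: {"NF": 106.0, "SF": 410.0, "DF": 515.0}
    )
    gestation_cost_ref: float = 430.0  # MJ/d at reference length
    lactation_cost_ref: float = 4700.0  # MJ/d at reference length

    def __post_init__(self) -> None:
        if self.length_m <= 0:
            raise ValueError("length must be positive")
        if not 0 < self.assimilation_efficiency <= 1:
            raise ValueError("assimilation efficiency must be in (0, 1]")
        if any(self.reference_cost_rates[s] <= 0 for s in STATES):
            raise ValueError("cost rates must be positive")

    @property
    def engulfment_volume(self) -> float:
        """Volume of water engulfed per lunge (m^3), allometric in length."""
        return self.engulfment_coef * self.length_m**self.engulfment_exponent

    @property
    def _metabolic_scale(self) -> float:
        return (self.length_m / self.reference_length_m) ** self.metabolic_exponent

    def cost_rate(self, state: str) -> float:
        """MJ/h spent while in the given behavioral state."""
        return self.reference_cost_rates[state] * self._metabolic_scale

    @classmethod
    def from_config(cls, cfg: dict, length_m: float) -> "WhaleParams":
        w = cfg["whale"]
        return cls(
            length_m=length_m,
            engulfment_coef=float(w["engulfment_coef"]),
            engulfment_exponent=float(w["engulfment_exponent"]),
            assimilation_efficiency=float(w["assimilation_efficiency"]),
            krill_energy_density=float(w["krill_energy_density_mj_per_kg"]),
            reference_length_m=float(w["reference_length_m"]),
            metabolic_exponent=float(w["metabolic_exponent"]),
            reference_cost_rates={
                s: float(w["cost_rates_mj_per_h"][s]) for s in STATES
            },
            gestation_cost_ref=float(w["gestation_cost_mj_per_day"]),
            lactation_cost_ref=float(w["lactation_cost_mj_per_day"]),
        )


@dataclass
class EnergyBudget:
    """Daily energy bookkeeping for one simulated day (all values MJ)."""

    gross_MJ: float
    expended_MJ: float
    net_MJ: float
    lost_MJ: float = 0.0

    @property
    def proportional_loss(self) -> float:
        """Lost gross energy over undisturbed gross energy, in [0, 1] (0/0 -> 0)."""
        if self.gross_MJ <= 0:
            return 0.0
        return min(max(self.lost_MJ / self.gross_MJ, 0.0), 1.0)


def energy_per_lunge(
    volume_m3: float, density_kg_m3: float, energy_density: float, efficiency: float
) -> float:
    """Assimilated energy (MJ) from one lunge: V * rho * e_k * eps."""
    return volume_m3 * density_kg_m3 * energy_density * efficiency


def gross_daily_intake(
    n_lunges: float,
    whale: WhaleParams,
    krill: KrillDistribution,
    rng: np.random.Generator,
) -> float:
    """Total assimilated energy (MJ) over ``n_lunges`` independent lunges.

    A fractional lunge count weights one extra density draw by the fraction,
    so the expectation stays linear in ``n_lunges``.
    """
    if n_lunges < 0:
        raise ValueError("lunge count must be non-negative")
    whole = int(n_lunges)
    frac = n_lunges - whole
    per = (
        whale.engulfment_volume
        * whale.krill_energy_density
        * whale.assimilation_efficiency
    )
    total = 0.0
    if whole:
        total += per * float(krill.draw(whole, rng).sum())
    if frac > 0:
        total += per * frac * float(krill.draw(1, rng)[0])
    return total


def daily_expenditure(hours_by_state: dict, whale: WhaleParams) -> float:
    """Daily energy expenditure (MJ) from an activity budget in hours.

    Hours must cover a full day (sum to 24).
    """
    total_h = sum(hours_by_state.get(s, 0.0) for s in STATES)
    if abs(total_h - 24.0) > 1e-6:
        raise ValueError(f"state hours must sum to 24, got {total_h}")
    return sum(
        hours_by_state.get(s, 0.0) * whale.cost_rate(s) for s in STATES
    )


def net_intake(gross: float, foraging_cost: float, maintenance_cost: float) -> float:
    """Daily net intake (MJ) with the foraging floor rule.

    Net gain from foraging is floored at zero when its incremental cost
    exceeds the energy acquired; maintenance is always paid, so the daily
    net intake can still be negative.
    """
    if min(gross, foraging_cost, maintenance_cost) < 0:
        raise ValueError("energy components must be non-negative")
    return max(gross - foraging_cost, 0.0) - maintenance_cost


def reproduction_cost(stage: str, whale: WhaleParams) -> float:
    """Additional daily cost (MJ/d) of the given reproductive stage.

    ``gestation`` is costed at mid-pregnancy, ``lactation`` at the maximum
    daily milk delivery; ``none`` costs nothing.
    """
    if stage == "none":
        return 0.0
    if stage == "gestation":
        return whale.gestation_cost_ref * whale._metabolic_scale
    if stage == "lactation":
        return whale.lactation_cost_ref * whale._metabolic_scale
    raise ValueError(f"unknown reproductive stage {stage!r}")


def load_bioenergetics_config(path=None) -> dict:
    """Load the bioenergetics constants YAML (packaged fixture if no path)."""
    if path is None:
        text = resources.files("whalecost").joinpath(
            "config", "bioenergetics.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def krill_from_config(cfg: dict, label: str) -> KrillDistribution:
    """Build a KrillDistribution ('lower' or 'upper') from the constants file."""
    k = cfg["krill"][label]
    return KrillDistribution(
        label=label,
        geometric_mean=float(k["geometric_mean"]),
        geometric_sd=float(k["geometric_sd"]),
    )
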