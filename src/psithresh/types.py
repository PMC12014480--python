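"""Domain types shared across the pipeline.

Sign convention: leaf water potential (psi) is stored in MPa and is always
<= 0. A positive psi anywhere in the pipeline is treated as a data error,
never silently negated.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

Axis = Literal["predawn", "midday"]
Window = Literal["predawn", "midday", "other"]

#: Reference VPD (kPa) at which the normalized conductance response equals
#: the psi-only curve.
VPD_REF = 1.0


@dataclass(frozen=True)
class SpeciesParams:
    """Generative parameters of one species' water-relations behaviour.

    The stomatal response to pre-dawn water potential is a negative
    exponential that switches to a shallow linear decline at the closure
    point ``pst_predawn_true``; the piecewise curve is continuous at the
    join. Midday water potential is mapped from pre-dawn potential by a
    continuous two-slope (wet/dry) hydroscape with its break at the same
    closure point.
    """

    species_id: str
    gs_max: float  # mol m-2 s-1, > 0
    pst_predawn_true: float  # MPa, < 0
    exp_rate: float  # per MPa, > 0; curvature of the exponential decline
    linear_slope: float  # normalized gs per MPa, >= 0; post-closure decline
    vpd_sensitivity: float  # dimensionless exponent on VPD/VPD_REF, <= 0
    tlp: float  # turgor loss point, MPa
    hydroscape_intercept: float  # MPa
    hydroscape_slope_wet: float  # MPa per MPa, applies above the break
    hydroscape_slope_dry: float  # MPa per MPa, applies below the break

    def __post_init__(self) -> None:
        if not self.gs_max > 0:
            raise ValueError(f"gs_max must be > 0, got {self.gs_max}")
        if not self.pst_predawn_true < 0:
            raise ValueError(
                f"pst_predawn_true must be < 0 MPa, got {self.pst_predawn_true}"
            )
        if not self.exp_rate > 0:
            raise ValueError(f"exp_rate must be > 0, got {self.exp_rate}")
        if self.linear_slope < 0:
            raise ValueError(f"linear_slope must be >= 0, got {self.linear_slope}")
        if self.vpd_sensitivity > 0:
            raise ValueError(
                f"vpd_sensitivity must be <= 0, got {self.vpd_sensitivity}"
            )

    @property
    def pst_midday_true(self) -> float:
        """Closure point on the midday axis implied by the hydroscape map."""
        return self.hydroscape_intercept + self.hydroscape_slope_wet * self.pst_predawn_true


@dataclass(frozen=True)
class SimConfig:
    """Design of a synthetic measurement campaign."""

    n_species: int = 9
    trees_per_species: int = 10
    n_campaigns: int = 35
    predawn_psi_range: tuple[float, float] = (-0.25, -2.0)  # (wet, dry), MPa
    noise_sd_gs: float = 0.05  # additive, normalized-conductance units
    noise_sd_psi: float = 0.05  # MPa, pre-dawn (pressure-chamber scale)
    noise_sd_psi_midday: float = 0.18  # MPa; midday psi scatters far more
    vpd_mean_range: tuple[float, float] = (0.9, 2.1)  # kPa, seasonal wet->dry ramp
    vpd_campaign_sd: float = 0.20  # log kPa, campaign-to-campaign weather
    vpd_within_campaign_sd: float = 0.25  # log kPa, leaf-to-leaf / hour-to-hour
    tree_intercept_sd: float = 0.15  # log-conductance units
    seed: int = 0
    season_start: str = "2021-05-01"
    season_days: int = 160

    def __post_init__(self) -> None:
        wet, dry = self.predawn_psi_range
        if not (wet < 0 and dry < 0 and wet > dry):
            raise ValueError(
                "predawn_psi_range must be (wet, dry) with wet > dry, both < 0; "
                f"got {self.predawn_psi_range}"
            )
        for name in (
            "noise_sd_gs",
            "noise_sd_psi",
            "noise_sd_psi_midday",
            "vpd_campaign_sd",
            "vpd_within_campaign_sd",
            "tree_intercept_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.n_species, self.trees_per_species, self.n_campaigns) < 1:
            raise ValueError("design counts must be >= 1")


@dataclass(frozen=True)
class TrueParams:
    """Generative truth retained alongside a simulated dataset.

    Never consumed by the estimators; only by recovery tests.
    """

    species: tuple[SpeciesParams, ...]
    growth_halt_psi: float = -1.2  # MPa; logistic midpoint of growth probability
    growth_logistic_steepness: float = 9.81  # log-odds per MPa toward wet

    def species_by_id(self, species_id: str) -> SpeciesParams:
        for sp in self.species:
            if sp.species_id == species_id:
                return sp
        raise KeyError(species_id)

    @property
    def growth_psi_at(self) -> "_GrowthInverter":
        return _GrowthInverter(self)

    def to_dict(self) -> dict:
        return asdict(self)


class _GrowthInverter:
    """Closed-form psi at a given growth probability for the generative logistic."""

    def __init__(self, truth: TrueParams):
        self._t = truth

    def __call__(self, p: float) -> float:
        t = self._t
        return t.growth_halt_psi + np.log(p / (1 - p)) / t.growth_logistic_steepness


@dataclass
class PstEstimate:
    """A species' estimated closure point on one psi axis."""

    species: str
    axis: Axis
    pst: float | None  # MPa; None when no closure detected
    method: Literal["ci_intersection", "fixed_gs_threshold"]
    detected: bool = True
    grid_step: float = 0.01
    band_width_at_pst: float | None = None
    min_gap: float | None = None  # closest approach when not detected
    diagnostics: dict = field(default_factory=dict)


@dataclass
class PstSummary:
    axis: Axis
    mean: float  # MPa
    sd: float  # MPa
    n_species: int
    undetected: list[str] = field(default_factory=list)
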