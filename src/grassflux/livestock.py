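"""Grazing livestock: herbage intake and excreta nitrogen returns.

The simulator does not model animals mechanistically; grazing is emulated by
removing herbage at a literature-derived daily intake and returning nitrogen
to the soil through urine and dung deposition events. Because ammonia
volatilization is not simulated as a process, urine and faecal N are reduced
at source by fixed NH3-loss fractions (0.600 of urine total N, 0.086 of
faecal total N); the volatilized N is reported as a gaseous loss term, not a
soil input. Deposition is spatially uniform over the grazed field.

Default parameter sets for adult beef cattle (600 kg live weight) and ewes
(75 kg) ship with the package; their urine NH4/DON split satisfies the
identity NH4 + DON = volume × N concentration × (1 − NH3 fraction), which is
enforced at load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date

__all__ = [
    "LivestockSpec",
    "StockingPeriod",
    "ExcretaReturn",
    "daily_intake",
    "excreta_returns",
    "load_default_specs",
    "urine_don_per_event",
]

log = logging.getLogger(__name__)

URINE_IDENTITY_TOL = 1e-9


def urine_don_per_event(
    volume_l: float, n_conc_g_per_l: float, nh3_fraction: float, nh4_g: float
) -> float:
    """Dissolved organic N per urination event after volatilization.

    DON = volume × N concentration × (1 − NH3 loss fraction) − NH4.
    """
    return volume_l * n_conc_g_per_l * (1.0 - nh3_fraction) - nh4_g


@dataclass(frozen=True)
class LivestockSpec:
    """Per-animal intake and excreta parameterization.

    All *_g quantities are grams per single event; NH4/DON values are the
    post-volatilization amounts reaching the soil.
    """

    animal_type: str                      # "beef" | "ewe"
    live_weight_kg: float
    bites_per_day: float
    bite_mass_g_dm: float
    urine_events_per_day: float
    urine_volume_l: float
    urine_n_conc_g_per_l: float
    urine_area_m2: float
    urine_nh3_fraction: float
    urine_nh4_g: float
    urine_don_g: float
    faeces_events_per_day: float
    faecal_dm_g: float
    faecal_n_g: float                     # total N per event, pre-volatilization
    faecal_n_conc_g_per_g_dm: float       # carried as metadata; may disagree with faecal_n_g
    faecal_area_m2: float
    faecal_nh3_fraction: float
    faecal_nh4_g: float
    faecal_don_g: float

    def __post_init__(self) -> None:
        for name in (
            "live_weight_kg", "bites_per_day", "bite_mass_g_dm",
            "urine_events_per_day", "urine_volume_l", "urine_n_conc_g_per_l",
            "urine_area_m2", "urine_nh4_g", "urine_don_g",
            "faeces_events_per_day", "faecal_dm_g", "faecal_n_g",
            "faecal_area_m2", "faecal_nh4_g", "faecal_don_g",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("urine_nh3_fraction", "faecal_nh3_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

        urine_total = self.urine_volume_l * self.urine_n_conc_g_per_l
        expected = urine_total * (1.0 - self.urine_nh3_fraction)
        if abs(self.urine_nh4_g + self.urine_don_g - expected) > 1e-6:
            raise ValueError(
                "urine NH4 + DON must equal volume x N concentration x "
                f"(1 - NH3 fraction): got {self.urine_nh4_g + self.urine_don_g}, "
                f"expected {expected}"
            )
        faecal_avail = self.faecal_n_g * (1.0 - self.faecal_nh3_fraction)
        if self.faecal_nh4_g + self.faecal_don_g > faecal_avail + 1e-9:
            raise ValueError(
                "faecal NH4 + DON exceed post-volatilization faecal N"
            )
        implied = self.faecal_dm_g * self.faecal_n_conc_g_per_g_dm
        if abs(implied - self.faecal_n_g) > 1e-6:
            log.info(
                "faecal N per event (%.3f g) differs from DM x concentration "
                "(%.3f g); using the per-event value", self.faecal_n_g, implied,
            )

    @property
    def intake_kg_dm_per_day(self) -> float:
        """Herbage intake per animal, kg DM d-1."""
        return self.bites_per_day * self.bite_mass_g_dm / 1000.0

    @property
    def faecal_organic_n_g(self) -> float:
        """Post-volatilization faecal N not in NH4/DON, g per event."""
        return (
            self.faecal_n_g * (1.0 - self.faecal_nh3_fraction)
            - self.faecal_nh4_g - self.faecal_don_g
        )


@dataclass(frozen=True)
class StockingPeriod:
    start: Date
    end: Date
    head_count: float
    field_area_ha: float
    animal_type: str = "beef"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("stocking period end precedes start")
        if self.head_count < 0:
            raise ValueError("head count must be non-negative")
        if self.field_area_ha <= 0:
            raise ValueError("field area must be positive")

    def covers(self, day: Date) -> bool:
        return self.start <= day <= self.end


@dataclass(frozen=True)
class ExcretaReturn:
    """Daily field-scale N and C deposition from grazing, kg ha-1 d-1."""

    urine_nh4_n: float
    urine_don: float
    faecal_organic_n: float
    faecal_nh4_n: float
    faecal_don: float
    volatilized_n: float       # NH3-N loss, reported but never a soil input
    dung_c: float              # faecal C entering fresh organic matter

    @property
    def total_soil_n(self) -> float:
        return (
            self.urine_nh4_n + self.urine_don
            + self.faecal_organic_n + self.faecal_nh4_n + self.faecal_don
        )


def daily_intake(spec: LivestockSpec, stocking: StockingPeriod) -> float:
    """Field-scale herbage demand, kg DM ha-1 d-1.

    The orchestrator caps the actual removal at the herbage available above
    stubble and logs any shortfall.
    """
    return spec.intake_kg_dm_per_day * stocking.head_count / stocking.field_area_ha


def excreta_returns(
    spec: LivestockSpec, stocking: StockingPeriod, dung_c_fraction: float = 0.45
) -> ExcretaReturn:
    """Daily excreta deposition per hectare of the grazed field."""
    scale = stocking.head_count / stocking.field_area_ha / 1000.0  # g -> kg ha-1
    u_events = spec.urine_events_per_day
    f_events = spec.faeces_events_per_day
    urine_total_n = spec.urine_volume_l * spec.urine_n_conc_g_per_l
    volatilized = (
        urine_total_n * spec.urine_nh3_fraction * u_events
        + spec.faecal_n_g * spec.faecal_nh3_fraction * f_events
    )
    return ExcretaReturn(
        urine_nh4_n=spec.urine_nh4_g * u_events * scale,
        urine_don=spec.urine_don_g * u_events * scale,
        faecal_organic_n=spec.faecal_organic_n_g * f_events * scale,
        faecal_nh4_n=spec.faecal_nh4_g * f_events * scale,
        faecal_don=spec.faecal_don_g * f_events * scale,
        volatilized_n=volatilized * scale,
        dung_c=spec.faecal_dm_g * dung_c_fraction * f_events * scale,
    )


def load_default_specs() -> dict[str, LivestockSpec]:
    """Shipped parameter sets for adult beef cattle and ewes."""
    beef = LivestockSpec(
        animal_type="beef",
        live_weight_kg=600.0,
        bites_per_day=25_220.0,
        bite_mass_g_dm=0.775,
        urine_events_per_day=8.60,
        urine_volume_l=2.20,
        urine_n_conc_g_per_l=17.00,
        urine_area_m2=0.370,
        urine_nh3_fraction=0.600,
        urine_nh4_g=11.07,
        urine_don_g=3.89,
        faeces_events_per_day=10.0,
        faecal_dm_g=235.0,
        faecal_n_g=4.15,
        faecal_n_conc_g_per_g_dm=0.025,
        faecal_area_m2=0.017,
        faecal_nh3_fraction=0.086,
        faecal_nh4_g=0.034,
        faecal_don_g=0.835,
    )
    ewe = LivestockSpec(
        animal_type="ewe",
        live_weight_kg=75.0,
        bites_per_day=33_480.0,
        bite_mass_g_dm=0.087,
        urine_events_per_day=17.0,
        urine_volume_l=0.150,
        urine_n_conc_g_per_l=10.00,
        urine_area_m2=0.030,
        urine_nh3_fraction=0.600,
        urine_nh4_g=0.050,
        urine_don_g=0.550,
        faeces_events_per_day=22.0,
        faecal_dm_g=30.00,
        faecal_n_g=0.750,
        faecal_n_conc_g_per_g_dm=0.025,
        faecal_area_m2=0.018,
        faecal_nh3_fraction=0.086,
        faecal_nh4_g=0.003,
        faecal_don_g=0.192,
    )
    return {"beef": beef, "ewe": ewe}
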