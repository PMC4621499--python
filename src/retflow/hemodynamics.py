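"""Per-vessel volumetric flow and arterial/venous totals.

The retina is an end organ: every measured branch artery carries blood that
entered through the central retinal artery, and every branch vein drains into
the central retinal vein. Summing per-vessel flows over all arteries and over
all veins therefore yields two independent estimates of the same total
retinal blood flow, and their agreement is a per-subject validity check.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataQualityWarning, IncompleteRecordError
from .units import MM_TO_UM, UM3_PER_S_TO_UL_PER_MIN

#: Vessels narrower than this are unreliable on fundus photographs and must
#: come from the OCT images instead.
OCT_DIAMETER_CUTOFF_UM = 65.0
#: Default flag threshold on |Q_A,tot - Q_V,tot| / Q_tot. Healthy-eye
#: measurements typically show imbalances below ~10%.
DEFAULT_IMBALANCE_THRESHOLD = 0.20


class VesselType(str, enum.Enum):
    ARTERY = "artery"
    VEIN = "vein"


class DiameterSource(str, enum.Enum):
    PHOTOGRAPH = "photograph"
    OCT = "oct"


@dataclass(frozen=True)
class VesselMeasurement:
    """One retinal vessel's calibrated measurements.

    Attributes
    ----------
    vessel_id
        Label, unique within a subject-condition record.
    vessel_type
        Artery or vein.
    mean_velocity_mm_s
        Pulse-averaged absolute blood velocity, mm/s.
    diameter_um
        Vessel (lumen) diameter, um.
    diameter_source
        Whether the diameter came from the fundus photograph (static vessel
        analysis) or from the OCT image; diameters below 65 um should be OCT.
    beta_deg
        Angle between the velocity vector and the detection plane, degrees.
    distance_to_onh_um
        Distance from the measurement location to the optic-nerve-head
        center, um; drives the trans-wall saturation correction.
    measured_saturation
        Hemoglobin oxygen saturation at the measurement location, fraction.
    """

    vessel_id: str
    vessel_type: VesselType
    mean_velocity_mm_s: float
    diameter_um: float
    beta_deg: float = 0.0
    distance_to_onh_um: float = 0.0
    measured_saturation: float = float("nan")
    diameter_source: DiameterSource = DiameterSource.PHOTOGRAPH

    def __post_init__(self) -> None:
        object.__setattr__(self, "vessel_type", VesselType(self.vessel_type))
        object.__setattr__(self, "diameter_source", DiameterSource(self.diameter_source))
        if self.mean_velocity_mm_s <= 0:
            raise ValueError(
                f"vessel {self.vessel_id}: mean velocity must be positive, "
                f"got {self.mean_velocity_mm_s}"
            )
        if self.diameter_um <= 0:
            raise ValueError(
                f"vessel {self.vessel_id}: diameter must be positive, got {self.diameter_um}"
            )
        if self.distance_to_onh_um < 0:
            raise ValueError(f"vessel {self.vessel_id}: distance to ONH must be >= 0")
        s = self.measured_saturation
        if not np.isnan(s) and not 0.0 <= s <= 1.0:
            raise ValueError(
                f"vessel {self.vessel_id}: saturation must be a fraction in [0, 1], got {s}"
            )
        if (
            self.diameter_um < OCT_DIAMETER_CUTOFF_UM
            and self.diameter_source is not DiameterSource.OCT
        ):
            warnings.warn(
                f"vessel {self.vessel_id}: diameter {self.diameter_um:.1f} um is below "
                f"{OCT_DIAMETER_CUTOFF_UM:.0f} um but sourced from a photograph",
                DataQualityWarning,
                stacklevel=2,
            )

    @property
    def radius_um(self) -> float:
        return 0.5 * self.diameter_um


@dataclass(frozen=True)
class HemodynamicSummary:
    """Per-subject flow aggregates.

    ``q_total_ul_min`` is the arithmetic mean of the arterial and venous
    totals; ``imbalance`` is their absolute difference relative to that mean
    and serves as the conservation validity check.
    """

    q_per_vessel_ul_min: dict[str, float]
    q_arterial_total_ul_min: float
    q_venous_total_ul_min: float
    q_total_ul_min: float
    imbalance: float
    flagged: bool = field(default=False)


def vessel_flow(velocity_mm_s: float, diameter_um: float) -> float:
    """Volumetric flow (ul/min) through a vessel of circular cross section.

    Q = v * pi * (d/2)^2, computed in um^3/s and converted to ul/min.
    A zero velocity is a valid boundary (no motion, zero flow); negative
    velocity or non-positive diameter is an error.
    """
    if velocity_mm_s < 0:
        raise ValueError(f"velocity must be >= 0, got {velocity_mm_s}")
    if diameter_um <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_um}")
    area_um2 = np.pi * (0.5 * diameter_um) ** 2
    q_um3_s = velocity_mm_s * MM_TO_UM * area_um2
    return q_um3_s * UM3_PER_S_TO_UL_PER_MIN


def total_flows(
    vessels: list[VesselMeasurement],
    imbalance_threshold: float = DEFAULT_IMBALANCE_THRESHOLD,
) -> HemodynamicSummary:
    """Sum per-vessel flows into arterial and venous totals.

    Requires at least one artery and one vein. When the arterial/venous
    imbalance exceeds ``imbalance_threshold`` the summary is flagged (with a
    warning) but never dropped.
    """
    arteries = [v for v in vessels if v.vessel_type is VesselType.ARTERY]
    veins = [v for v in vessels if v.vessel_type is VesselType.VEIN]
    if not arteries or not veins:
        raise IncompleteRecordError(
            f"need at least one artery and one vein, got {len(arteries)} arteries "
            f"and {len(veins)} veins"
        )
    q = {v.vessel_id: vessel_flow(v.mean_velocity_mm_s, v.diameter_um) for v in vessels}
    q_a = float(sum(q[v.vessel_id] for v in arteries))
    q_v = float(sum(q[v.vessel_id] for v in veins))
    q_tot = 0.5 * (q_a + q_v)
    imbalance = abs(q_a - q_v) / q_tot if q_tot > 0 else 0.0
    flagged = imbalance > imbalance_threshold
    if flagged:
        warnings.warn(
            f"arteriovenous flow imbalance {100 * imbalance:.1f}% exceeds "
            f"{100 * imbalance_threshold:.0f}%",
            DataQualityWarning,
            stacklevel=2,
        )
    return HemodynamicSummary(
        q_per_vessel_ul_min=q,
        q_arterial_total_ul_min=q_a,
        q_venous_total_ul_min=q_v,
        q_total_ul_min=q_tot,
        imbalance=imbalance,
        flagged=flagged,
    )
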