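"""Dual-beam Doppler phase-to-velocity conversion.

A dual-beam bidirectional Doppler OCT system probes each retinal vessel with
two beams that intersect at a known angle ``delta_alpha``. The difference of
the two channels' Doppler phase shifts is proportional to the absolute blood
velocity and — unlike a single-beam measurement — independent of the unknown
angle between the beam and the vessel. The only residual geometric factor is
``beta``, the angle of the velocity vector relative to the plane spanned by
the two beams, which enters as ``1/cos(beta)``.

The conversion implemented here is

    v = dphi * lambda0 / (4 * pi * n * tau * delta_alpha * cos(beta))

with ``lambda0`` the source central wavelength, ``n`` the refractive index of
blood, ``tau`` the line-scan period and ``dphi`` the inter-channel phase
difference per line period.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AngleUnresolvableError, DataQualityWarning, InvalidGeometryError
from .units import M_PER_S_TO_MM_PER_S, NM_TO_M, US_TO_S

#: Refractive index of the vitreous used in the reduced-eye model.
VITREOUS_REFRACTIVE_INDEX = 1.336
#: Distance (mm) from the cornea to the eye's nodal point in the reduced-eye model.
NODAL_OFFSET_MM = 7.1
#: Default rejection threshold on |cos(beta)|; beta within ~10 degrees of
#: perpendicular makes the 1/cos(beta) correction unreliable.
DEFAULT_COS_BETA_MIN = 0.17
#: Study inclusion bound on ametropia (diopter); violation warns, never errors.
AMETROPIA_BOUND_D = 3.0


def compute_inter_beam_angle(
    separation_mm: float, eye_length_mm: float, ametropia_d: float = 0.0
) -> float:
    """Inter-beam angle (rad) at the retina from pupil-plane beam separation.

    Uses a reduced-eye model: the two parallel beams, separated by
    ``separation_mm`` at the pupil, cross at the retina under the small angle

        delta_alpha = separation / (n_vitreous * (eye_length - nodal_offset))

    Ametropia is accepted for validation (it is already reflected in the
    measured axial eye length) and only triggers a warning outside the
    +-3 diopter inclusion band.

    Parameters
    ----------
    separation_mm
        Separation of the two probe beams at the pupil plane, mm. Must be > 0.
    eye_length_mm
        Axial eye length, mm. Must lie in [20, 30].
    ametropia_d
        Spherical equivalent refraction, diopter.

    Returns
    -------
    float
        Inter-beam angle in radians, strictly positive.
    """
    if separation_mm <= 0:
        raise InvalidGeometryError(
            f"beam separation must be positive, got {separation_mm} mm"
        )
    if eye_length_mm <= 0:
        raise InvalidGeometryError(
            f"eye length must be positive, got {eye_length_mm} mm"
        )
    if not 20.0 <= eye_length_mm <= 30.0:
        raise InvalidGeometryError(
            f"eye length {eye_length_mm} mm outside the physiological band [20, 30] mm"
        )
    if abs(ametropia_d) >= AMETROPIA_BOUND_D:
        warnings.warn(
            f"ametropia {ametropia_d} D outside the +-{AMETROPIA_BOUND_D} D "
            "inclusion bound",
            DataQualityWarning,
            stacklevel=2,
        )
    return separation_mm / (
        VITREOUS_REFRACTIVE_INDEX * (eye_length_mm - NODAL_OFFSET_MM)
    )


@dataclass(frozen=True)
class BeamGeometry:
    """Optical and geometric constants of the dual-beam system for one eye.

    ``inter_beam_angle_rad`` is derived from the pupil-plane separation and
    the axial eye length via :func:`compute_inter_beam_angle` when not given
    explicitly.
    """

    central_wavelength_nm: float = 838.8
    line_period_us: float = 27.0
    blood_refractive_index: float = 1.37
    beam_separation_mm: float = 2.0
    eye_length_mm: float = 24.2
    ametropia_d: float = 0.0
    inter_beam_angle_rad: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("central_wavelength_nm", "line_period_us", "blood_refractive_index"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be strictly positive")
        if self.inter_beam_angle_rad is None:
            object.__setattr__(
                self,
                "inter_beam_angle_rad",
                compute_inter_beam_angle(
                    self.beam_separation_mm, self.eye_length_mm, self.ametropia_d
                ),
            )
        if self.inter_beam_angle_rad <= 0:
            raise InvalidGeometryError("inter-beam angle must be strictly positive")


@dataclass(frozen=True)
class PhaseSample:
    """One inter-channel phase difference sample.

    ``phase_difference_rad`` is the raw (wrapped) difference of the Doppler
    phase shifts of the two channels, representable only on (-pi, pi].
    """

    phase_difference_rad: float
    timestamp_s: float


def unwrap_phase(series) -> np.ndarray:
    """Unwrap a 1-D temporal phase-difference series.

    Raw phase differences live on (-pi, pi]; a jump of more than pi between
    successive samples is interpreted as a 2*pi wrap and removed by
    continuation. Elementwise the output is congruent to the input mod 2*pi.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(arr <= -np.pi - 1e-12) or np.any(arr > np.pi + 1e-12):
        raise ValueError("wrapped phases must lie in (-pi, pi]")
    return np.unwrap(arr)


def wrap_phase(series) -> np.ndarray:
    """Wrap phases back onto (-pi, pi] (inverse of :func:`unwrap_phase`)."""
    arr = np.atleast_1d(np.asarray(series, dtype=float))
    wrapped = np.mod(arr + np.pi, 2 * np.pi) - np.pi
    # map the -pi boundary to +pi so the range is the half-open (-pi, pi]
    wrapped[wrapped == -np.pi] = np.pi
    return wrapped.reshape(np.shape(series))


def velocity_from_phase(
    delta_phi_rad,
    geometry: BeamGeometry,
    beta_deg: float,
    cos_beta_min: float = DEFAULT_COS_BETA_MIN,
):
    """Absolute blood velocity (mm/s) from the inter-channel phase difference.

    Implements the bidirectional closed form; works elementwise on arrays.
    Raises :class:`AngleUnresolvableError` when the vessel is too close to
    perpendicular to the detection plane (|cos(beta)| below ``cos_beta_min``),
    the configuration the system's rotatable beam displacer exists to avoid.
    """
    cos_beta = math.cos(math.radians(beta_deg))
    if abs(cos_beta) < cos_beta_min:
        raise AngleUnresolvableError(
            f"|cos(beta)| = {abs(cos_beta):.3f} below threshold {cos_beta_min}; "
            "vessel nearly perpendicular to the detection plane"
        )
    lam_m = geometry.central_wavelength_nm * NM_TO_M
    tau_s = geometry.line_period_us * US_TO_S
    v_m_per_s = np.asarray(delta_phi_rad, dtype=float) * lam_m / (
        4.0
        * np.pi
        * geometry.blood_refractive_index
        * tau_s
        * geometry.inter_beam_angle_rad
        * cos_beta
    )
    out = v_m_per_s * M_PER_S_TO_MM_PER_S
    return float(out) if np.ndim(delta_phi_rad) == 0 else out


def phase_from_velocity(
    velocity_mm_s,
    geometry: BeamGeometry,
    beta_deg: float,
):
    """Inverse of :func:`velocity_from_phase`: the (unwrapped) phase difference
    a given velocity produces. Used for simulation and round-trip checks."""
    cos_beta = math.cos(math.radians(beta_deg))
    lam_m = geometry.central_wavelength_nm * NM_TO_M
    tau_s = geometry.line_period_us * US_TO_S
    phi = (
        np.asarray(velocity_mm_s, dtype=float)
        / M_PER_S_TO_MM_PER_S
        * 4.0
        * np.pi
        * geometry.blood_refractive_index
        * tau_s
        * geometry.inter_beam_angle_rad
        * cos_beta
        / lam_m
    )
    return float(phi) if np.ndim(velocity_mm_s) == 0 else phi


def mean_velocity(series) -> float:
    """Arithmetic mean of a velocity series (mm/s).

    In practice the series covers several whole cardiac cycles (~5 s of
    acquisition per location), so the plain mean is the pulse-averaged
    velocity.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot average an empty velocity series")
    return float(arr.mean())
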