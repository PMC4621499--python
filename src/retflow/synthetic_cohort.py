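"""Synthetic subject-condition generator with ground-truth bookkeeping.

Emulates the statistical structure of an 8-subject two-condition (room air
vs 100% oxygen breathing) retinal-hemodynamics study: per subject roughly
11 branch arteries and 8 branch veins around the optic nerve head, a total
retinal blood flow near 44 ul/min at baseline that falls below 20 ul/min
under hyperoxia (retinal vasoconstriction), arterial saturations near 95%
(99%+ under oxygen) and venous saturations near 68% (77% under oxygen).

Generation is "physiology-first": the subject's true total flow, true
central-vessel saturations and systemic covariates are drawn, per-vessel
flows are a Dirichlet split of the total (arterial and venous sums are equal
by construction), velocities are back-computed from flow and lumen area, and
the trans-wall oxygen-loss model is applied in the forward direction so the
recorded at-distance saturations are exactly consistent with the true
at-disk values. Measurement noise is then layered on top. Every draw is
bookkept in a :class:`GroundTruth` so pipeline recovery can be verified to
machine precision in the noise-free limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CohortGenerationError
from .hemodynamics import (
    DiameterSource,
    OCT_DIAMETER_CUTOFF_UM,
    VesselMeasurement,
    VesselType,
)
from .oximetry import WallLossParams, wall_saturation_loss
from .oxygen_extraction import (
    Condition,
    OxygenModelParams,
    SubjectRecord,
    extraction,
    oxygen_content,
    per_100g,
    saturation_to_po2,
)
from .units import MM_TO_UM, UM3_PER_S_TO_UL_PER_MIN


@dataclass(frozen=True)
class CohortSpec:
    """Calibration of the synthetic cohort.

    Defaults for the two conditions are available via :meth:`baseline` and
    :meth:`oxygen` and encode the study-level group means this generator
    emulates. Noise magnitudes (velocity CV, diameter SD, saturation SD) and
    the per-vessel structural choices (log-normal diameters, Dirichlet flow
    shares, venous saturation spread) are generator choices, documented as
    such.
    """

    condition: Condition = Condition.BASELINE
    n_subjects: int = 8
    n_arteries_mean: float = 11.0
    n_arteries_sd: float = 2.2
    n_veins_mean: float = 8.1
    n_veins_sd: float = 1.6
    min_vessels: int = 4
    target_total_flow_ul_min: float = 44.3
    total_flow_sd_ul_min: float = 9.0
    arterial_sat_mean_pct: float = 95.3
    arterial_sat_sd_pct: float = 1.9
    venous_sat_mean_pct: float = 68.0
    venous_sat_sd_pct: float = 3.9
    vein_sat_spread_pct: float = 3.5
    hb_mean_g_ml: float = 0.138
    hb_sd_g_ml: float = 0.012
    pao2_mean_mmhg: float = 95.0
    pao2_sd_mmhg: float = 8.0
    artery_diameter_um: float = 85.0
    vein_diameter_um: float = 105.0
    #: Condition-level scale on the diameter medians; hyperoxia constricts
    #: retinal vessels, so the oxygen calibration uses 0.8.
    diameter_scale: float = 1.0
    diameter_log_sd: float = 0.18
    diameter_bounds_um: tuple[float, float] = (40.0, 180.0)
    dirichlet_concentration: float = 2.0
    distance_range_um: tuple[float, float] = (1000.0, 3000.0)
    velocity_bounds_mm_s: tuple[float, float] = (1.0, 60.0)
    velocity_noise_cv: float = 0.05
    diameter_noise_sd_um: float = 2.0
    saturation_noise_sd_pct: float = 1.0
    max_retries: int = 200
    seed: int = 0
    wall_loss: WallLossParams = field(default_factory=WallLossParams)
    oxygen_model: OxygenModelParams = field(default_factory=OxygenModelParams)

    def __post_init__(self) -> None:
        for name in (
            "n_arteries_sd", "n_veins_sd", "total_flow_sd_ul_min",
            "arterial_sat_sd_pct", "venous_sat_sd_pct", "hb_sd_g_ml",
            "pao2_sd_mmhg", "velocity_noise_cv", "diameter_noise_sd_um",
            "saturation_noise_sd_pct",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.target_total_flow_ul_min <= 0:
            raise ValueError("target total flow must be positive")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")

    @classmethod
    def baseline(cls, **overrides) -> "CohortSpec":
        """Room-air calibration (the class defaults)."""
        return cls(condition=Condition.BASELINE, **overrides)

    @classmethod
    def oxygen(cls, **overrides) -> "CohortSpec":
        """100%-oxygen-breathing calibration: reduced total flow
        (vasoconstriction), raised saturations, hyperoxic arterial PO2."""
        defaults = dict(
            condition=Condition.OXYGEN,
            target_total_flow_ul_min=18.7,
            total_flow_sd_ul_min=4.2,
            arterial_sat_mean_pct=99.4,
            arterial_sat_sd_pct=0.3,
            venous_sat_mean_pct=76.6,
            venous_sat_sd_pct=5.2,
            pao2_mean_mmhg=300.0,
            pao2_sd_mmhg=40.0,
            diameter_scale=0.8,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def noise_free(self) -> "CohortSpec":
        """Copy of this spec with all measurement noise switched off."""
        return replace(
            self,
            velocity_noise_cv=0.0,
            diameter_noise_sd_um=0.0,
            saturation_noise_sd_pct=0.0,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about one synthetic subject."""

    subject_id: str
    condition: Condition
    total_flow_ul_min: float
    vessel_ids: list[str]
    vessel_types: list[VesselType]
    true_flows_ul_min: dict[str, float]
    true_velocities_mm_s: dict[str, float]
    true_diameters_um: dict[str, float]
    true_sat_at_onh: dict[str, float]
    sat_cra: float
    sat_crv: float
    hb_g_ml: float
    pao2_mmhg: float
    venous_po2_mmhg: float
    content_cra_ml_ml: float
    content_crv_ml_ml: float
    ext_o2_ul_min: float
    ext_o2_per_100g_ml_min: float


def _truncated_normal(rng, mean, sd, low=-np.inf, high=np.inf, max_draws=1000):
    """Rejection-sampled truncated normal; exact symmetric truncation keeps
    the mean at ``mean`` when the bounds are symmetric."""
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(max_draws):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    raise CohortGenerationError(
        f"truncated normal ({mean}, {sd}) on [{low}, {high}] failed to accept"
    )


def _velocity_mm_s(q_ul_min: float, diameter_um: float) -> float:
    area_um2 = np.pi * (0.5 * diameter_um) ** 2
    q_um3_s = q_ul_min / UM3_PER_S_TO_UL_PER_MIN
    return q_um3_s / area_um2 / MM_TO_UM


def generate_subject(spec: CohortSpec, seed) -> tuple[SubjectRecord, GroundTruth]:
    """Draw one synthetic subject-condition record plus its ground truth.

    Deterministic for a fixed ``seed`` (int or ``numpy.random.SeedSequence``).
    Vessel geometries are resampled (up to ``spec.max_retries``) until every
    back-computed velocity lies in ``spec.velocity_bounds_mm_s``; exhausting
    the retries raises :class:`~retflow.errors.CohortGenerationError` with
    diagnostics.
    """
    rng = np.random.default_rng(seed)
    subject_id = f"syn{spec.condition.value[:3]}-{rng.integers(0, 10**8):08d}"

    # --- systemic covariates and true central-vessel state -----------------
    hb = _truncated_normal(rng, spec.hb_mean_g_ml, spec.hb_sd_g_ml, 0.06, 0.24)
    pao2 = _truncated_normal(
        rng, spec.pao2_mean_mmhg, spec.pao2_sd_mmhg,
        spec.pao2_mean_mmhg - 2.5 * spec.pao2_sd_mmhg,
        spec.pao2_mean_mmhg + 2.5 * spec.pao2_sd_mmhg,
    )
    sat_cra = _truncated_normal(
        rng, spec.arterial_sat_mean_pct, spec.arterial_sat_sd_pct, high=100.0
    ) / 100.0
    sat_crv_target = _truncated_normal(
        rng, spec.venous_sat_mean_pct, spec.venous_sat_sd_pct,
        low=30.0, high=100.0 * sat_cra - 5.0,
    ) / 100.0

    # --- vascular tree: resample the whole subject until every back-computed
    # velocity is physiological (an infeasible draw corresponds to a subject
    # whose vessels could not all be measured). Flow shares are rank-matched
    # to diameters so larger vessels carry more flow, as in real trees.
    lo_v, hi_v = spec.velocity_bounds_mm_s
    lo_d, hi_d = spec.diameter_bounds_um
    med_a = spec.artery_diameter_um * spec.diameter_scale
    med_v = spec.vein_diameter_um * spec.diameter_scale
    flow_sd = spec.total_flow_sd_ul_min
    for attempt in range(spec.max_retries):
        # symmetric +-2.5 sigma truncation keeps the mean at the target
        q_total = _truncated_normal(
            rng, spec.target_total_flow_ul_min, flow_sd,
            spec.target_total_flow_ul_min - 2.5 * flow_sd,
            spec.target_total_flow_ul_min + 2.5 * flow_sd,
        )
        n_art = max(spec.min_vessels, round(rng.normal(spec.n_arteries_mean, spec.n_arteries_sd)))
        n_vein = max(spec.min_vessels, round(rng.normal(spec.n_veins_mean, spec.n_veins_sd)))
        diam_a = np.array([
            _truncated_normal_lognormal(rng, med_a, spec.diameter_log_sd, lo_d, hi_d)
            for _ in range(n_art)
        ])
        diam_v = np.array([
            _truncated_normal_lognormal(rng, med_v, spec.diameter_log_sd, lo_d, hi_d)
            for _ in range(n_vein)
        ])
        q_a = q_total * _rank_matched_shares(
            rng, diam_a, spec.dirichlet_concentration
        )
        q_v = q_total * _rank_matched_shares(
            rng, diam_v, spec.dirichlet_concentration
        )
        vel_a = np.array([_velocity_mm_s(q, d) for q, d in zip(q_a, diam_a)])
        vel_v = np.array([_velocity_mm_s(q, d) for q, d in zip(q_v, diam_v)])
        if (
            np.all((vel_a >= lo_v) & (vel_a <= hi_v))
            and np.all((vel_v >= lo_v) & (vel_v <= hi_v))
        ):
            break
    else:
        raise CohortGenerationError(
            f"subject {subject_id}: no feasible vascular tree in "
            f"{spec.max_retries} attempts (last: Q_tot={q_total:.1f} ul/min, "
            f"{n_art} arteries, {n_vein} veins; velocity bounds {spec.velocity_bounds_mm_s})"
        )

    # --- per-vein at-disk saturations around the target mix ----------------
    spread = spec.vein_sat_spread_pct / 100.0
    dev = rng.normal(0.0, spread, n_vein)
    sat_v_disk = np.clip(sat_crv_target + dev, 0.25, sat_cra - 0.02)
    sat_crv = float(np.dot(sat_v_disk, q_v) / q_v.sum())

    distances = rng.uniform(*spec.distance_range_um, n_art + n_vein)
    betas = rng.uniform(0.0, 60.0, n_art + n_vein)

    # --- forward wall-loss model + measurement noise ------------------------
    vessels: list[VesselMeasurement] = []
    ids, types = [], []
    true_flows, true_vels, true_diams, true_sats = {}, {}, {}, {}
    sat_noise = spec.saturation_noise_sd_pct / 100.0
    order = [(VesselType.ARTERY, i, q_a[i], diam_a[i], vel_a[i]) for i in range(n_art)]
    order += [(VesselType.VEIN, j, q_v[j], diam_v[j], vel_v[j]) for j in range(n_vein)]
    for k, (vtype, idx, q, d, v) in enumerate(order):
        vid = f"{'A' if vtype is VesselType.ARTERY else 'V'}{idx + 1}"
        L = distances[k]
        ds = wall_saturation_loss(0.5 * d, L, q, hb, spec.wall_loss)
        if vtype is VesselType.ARTERY:
            s_true = sat_cra
            s_meas = s_true - ds  # oxygen lost between disk and measurement point
        else:
            s_true = float(sat_v_disk[idx])
            s_meas = s_true + ds  # blood was richer upstream of the disk
        s_meas = float(np.clip(s_meas + rng.normal(0.0, sat_noise), 0.0, 1.0))
        v_meas = max(v * (1.0 + rng.normal(0.0, spec.velocity_noise_cv)), 0.1)
        d_meas = max(d + rng.normal(0.0, spec.diameter_noise_sd_um), 25.0)
        vessels.append(
            VesselMeasurement(
                vessel_id=vid,
                vessel_type=vtype,
                mean_velocity_mm_s=v_meas,
                diameter_um=d_meas,
                beta_deg=float(betas[k]),
                distance_to_onh_um=float(L),
                measured_saturation=s_meas,
                diameter_source=(
                    DiameterSource.OCT if d_meas < OCT_DIAMETER_CUTOFF_UM
                    else DiameterSource.PHOTOGRAPH
                ),
            )
        )
        ids.append(vid)
        types.append(vtype)
        true_flows[vid] = float(q)
        true_vels[vid] = float(v)
        true_diams[vid] = float(d)
        true_sats[vid] = s_true

    # --- ground-truth downstream quantities (same model as the pipeline) ----
    po2_v = saturation_to_po2(sat_crv, spec.oxygen_model)
    c_cra = oxygen_content(sat_cra, pao2, hb, spec.oxygen_model)
    c_crv = oxygen_content(sat_crv, po2_v, hb, spec.oxygen_model)
    ext = extraction(q_total, c_cra, c_crv)
    record = SubjectRecord(
        subject_id=subject_id,
        condition=spec.condition,
        vessels=vessels,
        hb_g_ml=hb,
        pao2_mmhg=pao2,
    )
    truth = GroundTruth(
        subject_id=subject_id,
        condition=spec.condition,
        total_flow_ul_min=q_total,
        vessel_ids=ids,
        vessel_types=types,
        true_flows_ul_min=true_flows,
        true_velocities_mm_s=true_vels,
        true_diameters_um=true_diams,
        true_sat_at_onh=true_sats,
        sat_cra=sat_cra,
        sat_crv=sat_crv,
        hb_g_ml=hb,
        pao2_mmhg=pao2,
        venous_po2_mmhg=po2_v,
        content_cra_ml_ml=c_cra,
        content_crv_ml_ml=c_crv,
        ext_o2_ul_min=ext,
        ext_o2_per_100g_ml_min=per_100g(ext, spec.oxygen_model),
    )
    return record, truth


def _rank_matched_shares(rng, diameters: np.ndarray, concentration: float) -> np.ndarray:
    """Dirichlet flow shares, rank-matched to diameter so the widest vessel
    carries the largest share (Murray-like, without fitting an exponent)."""
    shares = rng.dirichlet(np.full(diameters.size, concentration))
    out = np.empty_like(shares)
    out[np.argsort(diameters)] = np.sort(shares)
    return out


def _truncated_normal_lognormal(rng, median, log_sd, low, high, max_draws=1000):
    """Log-normal with the given median and log-scale SD, rejection-truncated."""
    for _ in range(max_draws):
        x = median * np.exp(rng.normal(0.0, log_sd))
        if low <= x <= high:
            return float(x)
    raise CohortGenerationError("log-normal diameter sampling failed to accept")


def subject_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Counter-based per-subject seed derivation: reproducible and extensible
    (adding subjects never changes earlier ones)."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def generate_cohort(spec: CohortSpec) -> list[tuple[SubjectRecord, GroundTruth]]:
    """Generate ``spec.n_subjects`` independent subjects from ``spec.seed``."""
    if spec.n_subjects < 2:
        raise ValueError("a cohort needs at least two subjects")
    out = []
    for i in range(spec.n_subjects):
        rec, truth = generate_subject(spec, subject_seed(spec.seed, i))
        rec = SubjectRecord(
            subject_id=f"S{i + 1:02d}",
            condition=rec.condition,
            vessels=rec.vessels,
            hb_g_ml=rec.hb_g_ml,
            pao2_mmhg=rec.pao2_mmhg,
            geometry=rec.geometry,
        )
        truth = replace(truth, subject_id=rec.subject_id)
        out.append((rec, truth))
    return out
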