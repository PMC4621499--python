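# Methods

## Model

`retflow` computes total retinal oxygen extraction by the Fick principle
applied to the whole retinal circulation. Because the retina is an end organ,
the flow in the central retinal artery (CRA) equals the sum of all branch
arterial flows at the optic nerve head (ONH), and likewise for the central
retinal vein (CRV); the arteriovenous difference in oxygen content times
that total flow is the oxygen the tissue removed.

The stages, per subject-condition record:

1. **Velocity.** If a vessel carries a raw phase-difference series, it is
   unwrapped (1-D temporal 2π continuation), converted with
   `v = ΔΦ·λ₀/(4π·n·τ·Δα·cos β)` and averaged over the acquisition (whole
   cardiac cycles). Defaults: λ₀ = 838.8 nm, τ = 27 μs, n = 1.37. The
   inter-beam angle uses a reduced-eye model,
   `Δα = separation / (1.336·(eye_length − 7.1 mm))`; the model is isolated
   behind `compute_inter_beam_angle` so a ray-traced alternative can be
   swapped in. Vessels with |cos β| < 0.17 (within ~10° of perpendicular to
   the detection plane) are rejected rather than corrected, because the
   1/cos β error diverges there. Most workflows instead supply a precomputed
   `mean_velocity_mm_s` column and skip this stage.
2. **Flow.** `Q = v·π(d/2)²` assuming a circular cross-section, computed in
   μm³/s and reported in μl/min. `Q_tot` is the mean of the arterial and
   venous totals; their relative absolute difference (the *imbalance*) above
   20% flags the record (default threshold; flagged records are never
   silently dropped). Healthy-eye imbalances are typically below 10%.
3. **Saturation correction.** Oxygen diffuses across the vessel wall between
   the disk and the measurement point, so measured arterial saturations are
   raised and venous saturations lowered by
   `ΔS = j·2πRL/(Q·Hb·1.35)` before mixing. The trans-wall flux default
   `j = 1.0×10⁻³ ml(O₂)·cm⁻²·min⁻¹` is a **calibration constant of this
   package**, chosen so that ΔS ≈ 1% over a 2 mm path at typical branch
   flows — consistent with corrected values remaining close to measured
   ones — not a measured physiological constant; set it explicitly when a
   preparation-specific flux estimate exists.
4. **Mixing.** CRA saturation is the unweighted mean of corrected arterial
   values: every branch artery carries the same freshly bifurcated blood, so
   averaging only suppresses measurement error. CRV saturation is the
   flow-weighted mean of corrected venous values, because the vein mixes
   streams of genuinely different saturation in proportion to flow. A
   flow-weighted CRA variant exists (off by default) for sensitivity
   analysis.
5. **Contents and extraction.** `c = 1.35·Hb·S + (0.003/100)·PO₂` in
   ml(O₂)/ml blood. The solubility is 0.003 ml O₂ per **100 ml** blood per
   mmHg; the per-ml reading would let dissolved oxygen rival bound oxygen,
   contradicting basic physiology. Arterial PO₂ always comes from the
   earlobe blood-gas sample (never from inverting the curve at the arterial
   saturation); venous PO₂ always comes from inverting the Hill curve
   `S = P^n/(P^n + P50^n)` with P50 = 26.8 mmHg (valid at PCO₂ 37 mmHg,
   37 °C) at the mixed CRV saturation. The Hill exponent n = 2.7 is a
   standard adult-hemoglobin value — the measurement conditions pin only
   P50 — and is configurable; an alternative dissociation model can be
   plugged in behind `saturation_to_po2`/`po2_to_saturation`. Negative
   extraction (venous content above arterial) is reported with a warning,
   never clamped: it is a data-quality signal.
6. **Per-mass normalization.** `extO₂ / (retina_mass · perfused_fraction)`,
   rescaled to 100 g. Defaults: retina 326 mg (literature whole-retina
   mass), perfused fraction 0.5 — the inner retina is ~0.43 of retinal mass
   and the retinal circulation also supplies ~11% of the outer retina, so
   the exact propagated fraction is 0.43 + 0.11·0.57 = 0.4927
   (`perfused_mass_fraction`), conventionally rounded to one half.

Saturation clamping to [0, 1] always warns; silent clamping is forbidden
throughout.

## Synthetic cohort generator

The generator emulates the structure of an 8-subject, two-condition
(room air vs 100% O₂ breathing) study. Per subject it draws, at baseline /
hyperoxia:

| quantity | baseline | hyperoxia | note |
|---|---|---|---|
| arteries / veins | N(11.0, 2.2) / N(8.1, 1.6), min 4 | same | rounded |
| total flow (μl/min) | N(44.3, 9.0) | N(18.7, 4.2) | ±2.5σ symmetric truncation |
| CRA saturation (%) | N(95.3, 1.9), ≤100 | N(99.4, 0.3), ≤100 | |
| CRV saturation (%) | N(68.0, 3.9) | N(76.6, 5.2) | truncated below CRA−5 |
| Hb (g/ml) | N(0.138, 0.012) | same | |
| PaO₂ (mmHg) | N(95, 8) | N(300, 40) | hyperoxic value is a content-consistency calibration |
| diameter medians (μm) | 85 (A) / 105 (V), log-normal σ=0.18, bounds [40, 180] | ×0.8 | hyperoxic vasoconstriction |

Generation is physiology-first: per-vessel flows are a symmetric
Dirichlet(2.0) split of the subject's true total flow — arterial and venous
sums equal the total *exactly*, by construction — with shares rank-matched
to diameters so wider vessels carry more flow (Murray-like, without fitting
an exponent). Velocities are back-computed as `v = Q/A` and the subject is
resampled (counts, flow, diameters, shares) until all velocities fall in
[1, 60] mm/s; an infeasible draw corresponds to a subject whose vessels
could not all be measured, and generation fails with diagnostics after 200
attempts. Per-vein at-disk saturations spread N(0, 3.5 pp) around the drawn
CRV value so the flow-weighted mixing is non-trivial. The wall-loss model is
applied in the *forward* direction — recorded at-distance saturations are
exactly consistent with the true at-disk values — and measurement noise
(5% CV on velocity, 2 μm SD on diameter, 1 pp SD on saturation; generator
choices, the study conditions pin only downstream dispersions) is layered on
last. Measurement distances are uniform on [1, 3] mm from the ONH.

Every intermediate is bookkept in a `GroundTruth`, so the noise-free
pipeline round trip is testable to ≤10⁻⁶ relative error (it holds to
machine precision). Per-subject seeds derive from the master seed by a
counter-based scheme (`SeedSequence(master, spawn_key=(i,))`): cohorts are
reproducible and extensible — adding subjects never changes earlier ones.

What the generator does **not** emulate: spatial image formation and bulk
motion (no B-scans), pulse-resolved waveforms, diameter–saturation
measurement covariance, inter-eye anatomy, and any subject-level correlation
between flow and saturation (draws are independent). Passing round-trip
tests therefore show the *model algebra* is inverted correctly under
realistic dispersions and noise, not that the instruments themselves are
unbiased.

## Study comparison

Group summaries are means ± SD of per-subject values; percent change is
computed on group means. Note the group mean of per-subject extractions is
not the product of the group means (per-subject covariance between flow and
content difference), which is why both per-subject means and intermediate
contents are surfaced. Paired two-sided t-tests (`scipy.stats.ttest_rel`)
compare conditions; degenerate difference distributions are resolved
explicitly (identical pairs → p = 1; constant non-zero difference → p = 0)
since the t statistic is undefined there. Two-sided is the conservative
default where sidedness is unstated.

## Numerical choices

- Flows in μm³/s internally, μl/min on output; velocities always mm/s; all
  unit constants in `retflow.units`. Rounding (half-to-even) only at report
  time.
- Dissociation-curve inversion is the exact closed form, not iterative;
  forward/inverse round trip holds to ≤10⁻⁹ over s ∈ [0.01, 0.99].
- Phase unwrapping is `numpy.unwrap` on the temporal series; correct
  whenever true inter-sample phase steps stay below π.
- Truncated draws use rejection sampling; symmetric bounds keep means at
  their targets exactly.
- The bundled example table's reported flow column sits systematically
  ≈0.89× below `v·π(d/2)²` recomputed from its own velocity and diameter
  columns (an instrument convention, likely lumen-vs-wall diameter or
  velocity averaging); it is used only as mixing weights, never to validate
  the continuity formula.

## Validation problem sizes

Round-trip validation uses 100 replicate 8-subject cohorts per condition
(800 subjects each), which puts Monte-Carlo error on the grand means well
below the acceptance bands (e.g. SE ≈ 0.3 μl/min on baseline total flow);
noise-free parameter recovery uses 200 subjects per condition.

## Known limitations

- The trans-wall flux j is a calibration constant (see above); absolute
  corrected saturations inherit its uncertainty, though with ΔS ≈ 1% the
  downstream effect on extraction is small.
- No Bohr-shift modelling: the dissociation curve is fixed at PCO₂ 37 mmHg,
  37 °C, pH-neutral conditions.
- The OCT-vs-photograph diameter cross-calibration is carried only as a
  provenance flag (`diameter_source`); no recalibration is applied.
- Fundus-reflectometry saturations enter as numbers; any systematic bias of
  the oximetry calibration propagates directly into venous content and
  extraction.
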