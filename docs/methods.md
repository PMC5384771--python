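# Methods

This package re-implements, as a tested pipeline over synthetic data, the
quantitative analyses used to establish that the *C. elegans* synaptonemal
complex (SC) switches from a dynamic to a stable state during pachytene and
that crossover-designated recombination intermediates stabilise it
chromosome-autonomously. Because no raw image data are available, every
analysis operator is exercised end-to-end on a ground-truthed synthetic gonad
generator that encodes the kinetic and recombination structure the analyses
assume. This note documents the models, the parameters that matter, what the
generator does and does not emulate, and the numerical choices.

## Compartment model of SC subunit exchange

Each nucleus carries `n_pairs` SC traces discretised into short segments
*i* with binding capacity *c_i* (arc length × local fluorophore density).
Bound fluorescence *B_i(t)* exchanges with a single well-mixed nucleoplasmic
pool. The model assumptions are:

- A fixed share *f* (mobile fraction, dimensionless in [0, 1]) of the
  material in every segment is exchangeable on the experimental time scale;
  the remaining 1 − *f* is immobile.
- Mobile material relaxes first-order at rate *k* (min⁻¹) toward the
  partition proportional to segment capacities. This is the simplest rate
  law consistent with a single observed recovery time scale; nothing in the
  underlying observations constrains the functional form further.
- Protein import is negligible during an experiment (`import_rate = 0`;
  total nuclear fluorescence rises only ~two-fold over the many hours of
  pachytene, i.e. <5% per hour-long experiment).
- The pool's equilibrium occupancy is 0 by default (`pool_weight = 0`): at
  steady state essentially all fluorophore is SC-bound and the pool acts as
  a transfer compartment. With this choice the model admits a closed form.

For a bleach that multiplies the fluorescence in a region holding content
fraction *a* by survival *s*, the extent of recovery

E(t) = [F_bl(t)/F_nuc(t)] / [F_bl(pre)/F_nuc(pre)]

obeys

E(0⁺) = s/T,  E(∞) = f + (1 − f)·s/T,  T = 1 − a(1 − s),

relaxing exponentially at rate *k*. The linear system is propagated in
closed form (no ODE stepping), so total fluorescence is conserved to
machine precision; the 1e−9 relative tolerance asserted in tests is
comfortably met. This closed form is also the *independent oracle*: the
rendered-image pipeline (splat → PSF blur → project → ROI fluorometry) is
required to reproduce it within 2% relative, noise-free.

The mobile fraction is recovered from a fitted recovery curve by inverting
E(∞): f̂ = (Ê∞·T − s)/(T − s), clipped to [0, 1] with a flag. When the
whole nucleus is bleached T → s and f is unidentifiable from E (E ≡ 1);
such nuclei are analysed by absolute recovery against an unbleached
reference nucleus instead, and `fit_recovery` returns f̂ = NaN.

## Stage-dependent kinetics and the genotype panel

Per-genotype kinetics are supplied as (f, k) per stage. Defaults:

| genotype preset | early | mid | late | breaks (λ) | h | enrichment |
|---|---|---|---|---|---|---|
| `wt` | (0.80, 0.12) | (0.45, 0.10) | (0.10, 0.08) | 1 designated CO per pair (late) | 0 | on |
| `spo11` | (0.80, 0.12) | same | same | 0.2 | 0 | on |
| `cosa1` | (0.80, 0.12) | same | same | 0 (no foci mature) | 0 | off |
| `dsb2` | as `wt` | | | 2.0 | 0 | on |
| `plk2` | (0.80, 0.12) | same | same | 1 per pair (late) | 0 | off |
| `plk2-dsb2` | flat | | | 2.0 | 0 | off |
| `szt1-spo11` | flat | | | 0.3 | 0.33 | on |
| `spo11-ir` | flat | | | 0.3 | 0 | on |

Magnitudes of f are free parameters of the generator: the observations
they encode are ordinal (recovery strong early, weak late in wild type; no
decline in crossover-defective mutants). The wild-type values were chosen
from the closed form so that, with the standard bleach geometry (a ≈
0.3–0.5, s = 0.25), the early→late plateau ratio declines by about half —
the magnitude reported for the real tissue. k defaults put most of the
recovery within the first 15–20 minutes. Per-nucleus f is jittered
(Gaussian, sd 0.05, truncated to [0, 1]) to emulate biological
variability. `spo11-ir` stands for the irradiated break-initiation mutant:
the same lesion rate as the translocation heterozygote but with full
homology, serving as its comparison cohort.

## Synthetic gonad generator

- **Layout.** `n_rows` = 24 rows of 3 nuclei, radius 2 µm, ordered
  distal→proximal. Staging position is x = row/n_rows with early/mid/late
  boundaries at 1/3 and 2/3. The fluorophore density ramp is linear over
  (row − 1)/(n_rows − 1), so the most-proximal row is exactly `ramp_fold`
  (default 2.1) times the most-distal row; the two coordinates differ so
  that the rendered proximal/distal intensity ratio equals the nominal
  fold while position profiling keeps the row-number convention.
- **Traces.** Six interpolating cubic splines through random waypoints,
  one per homolog pair, exactly one labelled X. Waypoint clouds are
  anchored to well-separated directions (distinct nuclear territories) and
  axially flattened; rejection sampling enforces containment, a per-trace
  length window, and minimum separation — measured in PSF-scaled
  coordinates (z compressed by the axial/lateral PSF ratio, default 2), so
  the constraint bounds optical cross-bleed rather than bare distance.
  Total SC length per nucleus is held in a narrow window (20–28 µm,
  emulating the fixed genome) so per-nucleus mean intensity reports
  density, not length. Real SC geometry is not being modelled; only
  counts, connectivity, and separation matter downstream.
- **Breaks and enrichment.** Wild-type rule: exactly one focus per trace
  in late pachytene. Otherwise per-nucleus break counts are
  Poisson(λ), each break *effective* with probability 1 − h (h models the
  heterosynapsed genome fraction of translocation heterozygotes), effective
  breaks landing uniformly on traces (≤ 4 per trace). Enrichment gives
  every focus-bearing trace in a late nucleus a factor of 2.0 and rescales
  all traces so total nuclear signal is conserved — redistribution, not
  creation. A non-conserving mode exists for sensitivity analysis. The
  enrichment magnitude is a free choice (the real magnitude was never
  quantified); 2.0 makes one enriched SC among six take share 2/7.
- **Imaging.** Voxels 0.1 × 0.1 × 0.24 µm; anisotropic Gaussian PSF
  (σ 0.15 µm lateral, 0.4 µm axial); constant background (10 counts);
  optional Poisson shot noise plus Gaussian read noise (sd 2). The default
  density (20 000 photons per µm of SC at the distal end) gives whole-
  nucleus integrated signals of order 10⁶ counts, in line with EMCCD
  acquisitions bright enough for per-nucleus ratio fluorometry; at this
  budget single-curve (f, k) estimates have sd ≈ 0.013 and ≈ 9%. The
  focus marker is rendered as a separate channel (point sources of 5 000
  counts), mirroring a second fluorophore.
- **Bleaching.** `zstack` mode multiplies everything inside the ROI
  footprint at every z by s (confocal stepwise z-series bleach);
  `single_plane` mode attenuates by axial distance d from the chosen focal
  plane with factor 1 − (1 − s)·exp(−d²/2σ_d²), σ_d = 0.5 µm (widefield
  bleach). Default survival s = 0.25.

**What the generator does not emulate** — chromatin texture, nucleolus or
gut autofluorescence, nuclear movement and rotation (the real experiments
needed manual tracking and exclusion rules; synthetic nuclei are static),
stage-continuous kinetics (stages are piecewise constant), photobleaching
during acquisition, and depth-dependent aberrations. Passing tests
therefore validate the *operators* (fluorometry, normalization, detection,
classification, inference) under the stated model, not the robustness of
those operators to the full mess of live-tissue imaging.

## Measurement operators

- **FRAP fluorometry** follows the sum-projection protocol: project the
  z-stack, measure background-corrected totals in a bleached-portion ROI
  and a whole-nucleus ROI, normalize the ratio to its pre-bleach value.
  Background is the pooled mean of three small corner ROIs, recomputed per
  time point. The bleached-portion ROI is a circular segment whose chord
  is inset 0.5 µm from the bleach boundary — drawn "well within" the
  bleached zone so PSF bleed across the boundary stays below the 2% oracle
  tolerance. Sampling grid: one pre-bleach frame, bleach at t = 0, then
  2.5-min spacing to 30 min.
- **Plateau** defaults to the mean of E at t ≥ 25 min; a fitted exponential
  asymptote is available (`fit_asymptote`). For monotone curves the mean
  rule is conservative (≤ asymptote).
- **Strong-recovery call** (widefield-style scoring): bleached/unbleached
  SC-segment mean-intensity ratio at 30 min ≥ τ, default τ = 0.8. The real
  scoring was double-blind visual ("evening-out of fluorescence"); τ is a
  declared operationalisation, not inferred from data.
- **Evenness** r = max_i I_i / median_j I_j over per-trace mean intensities
  measured through ground-truth masks (voxels within 0.15 µm of a trace,
  nearest-trace assignment). A trace is *enriched* when I_i > θ·median,
  θ = 1.5; a nucleus is *uneven* iff ≥ 1 trace is enriched. θ was chosen so
  the flat-genotype false-positive rate is ≤ 5% at default noise; with six
  equal-density traces the max/median ratio from PSF cross-bleed alone
  stays ≤ ~1.4. Note max/median is deliberately robust to a *single*
  enriched SC; nuclei with ≥ 3 enriched SCs of six shift the median and can
  be called even — the statistic targets the break-limited regime it is
  used in. Real-image SC tracing is out of scope.
- **Focus detection**: Gaussian pre-smoothing (one voxel per axis), then 3D
  local maxima above background mean + 5 sd (background from a 3-pixel
  border frame of the smoothed stack), anisotropic neighbourhood
  non-maximum suppression at 0.4 µm; border voxels are excluded from peak
  candidacy (smoothing edge artefacts). Foci are assigned to the nearest
  trace within 0.3 µm, ties to the lower trace id.
- **Windows**: presence/absence scoring uses the second half of pachytene
  (x > 0.5); enriched-SC counting uses the last quarter (x > 0.75). Both
  thresholds are half-open to avoid double counting.

## Inference

- **Zero-class Poisson estimation.** With effective breaks per nucleus
  Poisson(λ), the even-nucleus fraction estimates p₀ = e^(−λ), so
  λ̂ = −ln p̂₀. The 95% CI is a Wilson interval on p₀ transformed through
  the log. When no nucleus is even, p₀ is censored at 1/(2n) and the
  estimate flagged as a lower bound (a convention; the case never arises in
  the regimes analysed). Calibration: bias < 0.05 at λ = 0.2, n = 2000;
  CI coverage 90–99% at n = 500 over 500 replicates.
- **Heterosynapsis attenuation**: 100·(1 − λ̂_transloc/λ̂_plain). At
  λ = 0.3 and n = 2000 per cohort the estimator sd is ≈ 5 percentage
  points, so individual runs scatter around the true 33% accordingly.
- **Proportion z-test** (X disproportion): z = (k − np₀)/√(np₀(1 − p₀)),
  no continuity correction, one-sided upper tail. This is the unique
  standard test reproducing the printed p = 0.0018 from k = 13, n = 38,
  p₀ = 1/6; the exact binomial tail gives ≈ 0.0066, a discrepancy the
  report notes rather than hides.
- **Rank-sum / contingency tests**: Mann-Whitney U (exact enumeration for
  tie-free samples ≤ 8 per group, tie-corrected normal approximation
  otherwise), Fisher exact (two-sided by the point-probability rule),
  Pearson chi-square without continuity correction. All agree with
  brute-force enumeration on small inputs in the test suite. No
  multiple-testing correction is applied, matching per-comparison
  reporting.

## Problem sizes and determinism

Simulated cohort sizes are chosen so each analysis resolves its effect
cleanly at desk scale: 20 nuclei per stage for FRAP comparisons (the real
per-group n was 14–30), 50 for parameter-recovery calibration, 20–60
rendered nuclei for distribution scoring, and 2 000–5 000 count-level
nuclei for zero-class inference. Statistical-scale cohorts sample break
counts through the same thinning rule as the geometric generator but skip
trace geometry, which adds nothing to a zero-class tally.

All randomness flows from one integer seed; each nucleus uses a child
stream keyed by (seed, nucleus index), so any subset of nuclei reproduces
bit-for-bit and layouts restricted to one stage agree exactly with the
corresponding full layouts. Reports embed the seed and a configuration
hash, and regeneration from identical inputs is byte-identical.

## Known limitations

- The generator's mobile-fraction magnitudes and the enrichment factor are
  declared, not measured; conclusions about operator correctness transfer
  to real data, effect magnitudes do not.
- Gonad-level clustering (nuclei within a gonad share acquisition
  conditions) is not modelled and no mixed-effects analysis is provided.
- Trace geometry is a convenience model; morphological statistics of real
  SCs (curvature, axis separation) are out of scope.
- The importing of new protein is modelled only as a linear pool influx,
  adequate for the <5% regime it is restricted to.
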