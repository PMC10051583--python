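# Methods

## Ideal helix geometry

The helix builder extends a polypeptide backbone by internal coordinates
(NeRF placement) using fixed standard bond lengths and angles (N–Cα
1.458 Å, Cα–C' 1.525 Å, C'–N 1.329 Å, C'=O 1.231 Å, N–H 1.02 Å; angles
N–Cα–C' 111.2°, Cα–C'–N 116.2°, C'–N–Cα 121.7°; ω = 180°), with uniform
(φ, ψ) supplied by the user. The amide proton is placed in the peptide
plane trans to the carbonyl oxygen; a pseudo-Cβ (also for Gly) marks the
side-chain direction. Because every residue repeats identical internal
coordinates, the rigid transform between consecutive backbone triads
(N, Cα, C') is exactly one screw motion: its axis is the helix axis, its
rotation angle the twist per residue, its axial translation the rise.

We use the screw axis, not a total-least-squares line through the Cα
trace, as the definitive axis: a TLS line on a finite helix is biased by
end effects (fractional final turn) at the 0.1–1° level, whereas the
screw axis is exact, which is what makes the invariant "consecutive
azimuths differ by exactly the twist" hold to 10⁻⁶ degrees. Tests compare
the two and check rotation invariance of the fit.

Conventions: azimuths are measured about the axis in the sense of the
screw rotation, with residue 1's Cα→Cβ projection defining 0°; pitch
rotations use the same reference. At (φ, ψ) = (−65°, −45°) the builder
gives 3.76 residues/turn; at the textbook (−57°, −47°) it gives 3.62.

## Forward ¹⁵N shift model

The amide ¹⁵N tensor is anchored to the peptide plane of each residue:
σ33 in-plane at β_NH from the N–H bond, tilted toward the N–C' bond (the
standard amide geometry); σ22 along the plane normal; σ11 completes the
triad. Principal values default to (σ11, σ22, σ33) = (57, 81, 227) ppm
with β_NH = 17° — standard backbone-amide literature values, fully
exposed in the config because oriented-sample analyses are sensitive to
them (the restriction-map bands move by roughly the same ppm as the
tensor values).

The lab configuration at orientation (τ, ρ) is M = R_y(τ)·R_z(ρ) applied
to the helix; with B₀ along lab z the field unit vector seen in the helix
frame is Mᵀẑ = (−sin τ cos ρ, sin τ sin ρ, cos τ) and the static shift is
the quadratic form b̂ᵀσb̂, always within [σ11, σ33].

Motional averaging: tilt wobble (Gaussian SD 10°) and axial rotation
fluctuation (Gaussian SD 18°) are treated as independent 1-D Gaussians on
τ and ρ, and the *resonance value* (not the tensor) is averaged. The
average is a tensor-product Gauss–Hermite quadrature, 21 nodes per
dimension by default; doubling the node count changes results by < 10⁻³
ppm, and a seeded 10⁶-draw Monte-Carlo oracle agrees within 0.05 ppm. For
grid scans the quadratic form is expanded as
sin²τ·A(ρ) + cos²τ·σ_zz + sin 2τ·C(ρ), which factorizes the 2-D
quadrature into independent tilt and pitch moments; a full 181 × 360 scan
at 1° then costs milliseconds and is bit-identical to the pointwise
quadrature.

## Restriction analysis

Per restraint, a (tilt, pitch) cell is compatible iff
|⟨σ_obs⟩ − σ_measured| ≤ Δσ with Δσ the printed half-width — measurement
error only, no extra broadening. Maps are intersected cell-wise;
connected regions use 8-connectivity with wrap-around on the periodic
pitch axis (scipy labeling plus a union-find seam merge, cross-checked
against a brute-force flood fill in tests). Defaults: 1° grid, minimum
region area 3 deg² (speck suppression at the map's granularity); region
centroids use a circular mean on pitch. Classification bounds (config):
in-plane for centroid tilt in [75°, 105°], transmembrane below 30° or
above 150°, tilted otherwise.

The observable is exactly invariant under field inversion,
(τ, ρ) → (180°−τ, ρ+180°); solution regions therefore appear in
spectroscopically indistinguishable pairs. We deliberately report every
raw region *and* group them into degeneracy classes
(`degeneracy_classes`): the class count is the number of distinguishable
solutions, which is the scientifically meaningful multiplicity. For the
measured SAAP-148 restraints (80.0 ± 2.5 ppm at residue 11, 70.0 ± 4.0 ppm
at residue 12) at the defaults this yields four regions in two classes,
all in-plane — i.e. two distinguishable surface-bound orientations — and
the count is stable to ±5 ppm perturbations of σ33 and to halving the
grid step.

## Solution-state analyses

* **CSD:** deviations from an embedded Wishart-style random-coil Hα/Cα
  table (aqueous, near-neutral pH, no neighbour corrections). Absolute
  CSDs from a live predictor with pH/temperature corrections would differ
  slightly; all internal analyses and generators use this one table, so
  only the deviations matter. Helix support: Δδ(Hα) ≤ −0.1 ppm or
  Δδ(Cα) ≥ +0.7 ppm, vetoed when the other atom crosses its threshold in
  the opposing direction; segments are runs of ≥ 4 supporting residues
  ("persistent" operationalized as the canonical minimum helix length).
* **Amide dispersion:** max − min of HN shifts; reference-free.
* **PRE:** loss = 100·(1 − C/B); error 100·(C/B)·(ΔB/B + ΔC/C). The
  linear propagation is intentional and conservative — a Monte-Carlo
  (quadrature-sum) propagation gives a smaller error, which a test
  documents. Apparent gains (C > B) are reported as negative losses and
  flagged, not clipped.
* **Periodicity:** cosine model a + b·cos(2π(i − i₀)/P); P seeded by a
  0.05-step grid search on [3.0, 4.5] (linear least squares in the phase
  at each candidate) and refined by bounded nonlinear least squares. If
  the fitted amplitude is below twice the residual SD the profile is
  declared non-periodic and no period is reported.
* **Faces:** one-sided Wilcoxon rank-sum (cationic < other), exact null
  distribution for small tie-free samples, normal approximation
  otherwise. The cationic set is parsed from the sequence (K/R).

## Deuterium order parameters

S_CD = (4/3)·Δν/(e²qQ/h), qcc = 167 kHz; the inverse map feeds the
generators and round-trips to machine precision. CD3 groups are treated
like CD2 (no 3-fold correction) unless enabled in config — ratio profiles
are unaffected by any per-carbon constant factor. Ratios
S_with/S_without are reported per carbon with a maximum-percent-reduction
summary; carbons with S_without = 0 are flagged undefined.

## Synthetic data

Generators emulate the statistical structure each analysis assumes, with
Gaussian noise throughout and all magnitudes config-exposed; every
generator returns (table, ground truth) and is bit-reproducible per seed.

* Shift tables: coil scatter SD 0.02 ppm (Hα), 0.1 ppm (Cα), 0.08 ppm
  (HN); helix adds Δδ(Hα) = −0.25 ppm, Δδ(Cα) = +2.0 ppm over the helix
  span (residues 1–21 of the 24-mer by default, with a proline-like break
  at 22) and a 0.35 ppm periodic HN modulation so helices disperse amides
  more than coils.
* PRE: loss_i = 50 + 30·cos(2π(i − i₀)/3.6) with i₀ phased onto the
  apolar face (circular mean of non-K/R wheel positions), cationic losses
  scaled by 0.6, noise SD 3 percentage points (10 % of the amplitude);
  intensities back-computed with B = 100 and noise floors of 2.
* ¹⁵N restraints: forward-averaged shifts at a chosen true orientation
  (default tilt 90°, pitch 130°) plus N(0, error/2) noise, errors
  (2.5, 4.0) ppm.
* S_CD: plateau 0.20 (C2–C8) decaying to 0.05 at C16; the peptide
  multiplies by a linear reduction ramp reaching 30 % at C16 (the chain
  terminus is perturbed most, as expected for an interfacially inserted
  peptide).

What passing recovery tests on these data do show: the estimators invert
their own forward models at realistic noise. What they do not show:
robustness to spectral artifacts, peak overlap, assignment errors,
non-Gaussian noise, or deviations from ideal uniform helicity — none of
which the generators emulate.

## Problem sizes and numerical choices

Full restriction scans run at 1° (181 × 360 cells); recovery and
stability tests use 2° and 0.5° grids. Monte-Carlo oracles use 10⁶ draws.
Periodicity recovery is assessed over 20 seeds per condition. The whole
suite runs in a few seconds on one CPU.

## Known limitations

* The ¹⁵N tensor is a literature default, not a measured one; region
  shapes (though not the in-plane conclusion or the solution count, per
  the sensitivity checks) depend on it.
* No dipolar couplings or separated-local-field observables; a single
  helix conformation (no kinks, no fraying) with uniform dihedrals.
* Motional model is two independent Gaussians; correlated or anisotropic
  motions are not represented.
* PRE analysis is intensity-ratio based; no distance calibration of the
  paramagnetic effect is attempted.
* Splitting-to-carbon assignment is assumed given; no de-Pakeing of
  powder line shapes.
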