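# Methods

## Passive compartmental model

Each morphology node becomes one compartment with membrane leak
`g_i = g_pas · A_i` and capacitance `c_i = C_m · A_i`; tree edges carry
axial conductances `g_ij = π d̄² / (4 R_a l)` where `d̄` is the mean of the
endpoint diameters and `l` the edge arc length. A compartment's membrane
area is the sum of the half-areas of its incident edges (cylinder with mean
endpoint diameter), which makes the model's total capacitance and leak
identical to the edge-sum section statistics; an isolated single node uses
the sphere area `4πr²` so isopotential fixtures are expressible. All
compartments share the same specific parameters — only geometry
differentiates them — and there are no active conductances, synapse
kinetics, or temperature dependence. The model therefore speaks to passive
signal spread only; any conclusion about propagation direction assumes the
membrane stays in its linear regime.

**Units.** Internally mV, ms, nA, µS, nF, µm (so nA/µS = mV, nF/µS = ms,
1/µS = MΩ). Specific parameters enter in the conventional units Ω·cm
(`R_a`), µF/cm² (`C_m`), S/cm² (`g_pas`) and are converted exactly once
when the model is built: 1 µF/cm² = 10⁻² pF/µm², 1 S/cm² = 10 nS/µm², and
µm/(Ω·cm) = 10² µS. These factors are what make a 1611 µm² membrane at
1 µF/cm² carry 16.11 pF.

**Solvers.** The steady state solves the symmetric positive-definite system
`(G_m + L)(V − E_pas) = I` directly (sparse LU). Transients use backward
Euler at `dt = 0.025 ms` by default (first-order, unconditionally stable on
stiff trees); Crank–Nicolson is available behind a flag where second-order
accuracy matters. For current-only stimuli the chosen stepping scheme is
evaluated through an exact modal decomposition: symmetrizing with
`C^{1/2}` and diagonalizing turns each mode into a scalar first-order
recursion, which `scipy.signal.lfilter` evaluates at C speed. This is the
same scheme, not an approximation — the explicit time loop (retained for
voltage-clamp protocols, which pin compartments and report the holding
current) agrees with it to ~10⁻⁹ mV. Backward Euler at `dt = τ/500` matches
the RC charging closed form to < 0.1 %; a 1 µm discretization of a
sealed-end cable matches the cosh attenuation profile to < 10⁻⁶.

## Morphology handling

SWC dialect: 7 columns, radius (not diameter) in column 6, 1-based ids,
parent −1 at the root; regions (soma / AL / LH / contralateral / other) are
encoded in the structure-type column (1/2/3/4/5) or supplied via a
two-column sidecar. Zero-length edges are collapsed on read with a warning.

`simplify` resamples each unbranched run at uniform arc-length spacing
`L/⌈L/max⌉`, interpolating positions on the original polyline and radii
linearly in arc length, and records the exact arc length of each new edge
as an override; total path length is therefore preserved exactly even on
bent branches, at the cost that `write_swc` (positions only) drops the
overrides. Interior radii of each resampled run are rescaled by a single
factor so the run's membrane area is preserved exactly (the area is linear
in the interior radii); runs that would collapse to a single segment keep
one interior node whenever their taper is not linear, for the same reason.
Coarsening never increases the node count; asking for a spacing finer than
the original refines instead. The operation is idempotent at fixed spacing.

Section statistics attribute each edge to the region of its child node.
`Ri` is the summed axial resistance from the region's origin (first node of
the region in root-first order) to the length-midpoint of the longest
within-region path from that origin; the definition of "origin" and
"middle" is a documented choice — other conventions are defensible and the
quantity is reported for orientation, not used downstream.

## Parameter fitting

The objective is the pooled per-sample squared error (mV²) between
simulated and recorded somatic voltage across all protocols, with
voltage-clamp residuals (nA) scaled by 100 mV/nA so a 10 pA error weighs
like a 1 mV error. Bounds (`R_a` 10⁻⁴–5·10³ Ω·cm, `C_m` 0.1–2 µF/cm²,
`g_pas` 10⁻⁶–0.1 S/cm², `E_pas` free) are enforced by a smooth box
transform — logistic in log-space for `R_a` and `g_pas`, logistic in linear
space for `C_m` — and the search is multi-start Nelder–Mead in the
transformed coordinates (starts log-uniform/uniform in the box, `E_pas`
initialized near −45 mV), with the winning start polished at tight
tolerance. The landscape is shallow (many parameter combinations fit
somatic traces comparably), which is exactly why multi-start matters.
Identifiability caveat: on an isopotential compartment only the totals
`G = g_pas·A`, `C = C_m·A` and `E_pas` are identifiable; the recovery
harness checks totals there. `R_a` is identifiable only when the recording
has both bandwidth and amplitude — the default synthetic protocols (a
−50 pA step and 0.1 nA-SD white noise, giving a few mV of somatic
deflection, within the 2–20 mV working range used for calibrated
injections) recover all four parameters to < 1 % noiselessly and to < 10 %
with 0.5 mV recording noise over 2 s.

## Propagation experiments

Injection experiments draw source compartments uniformly from a region's
compartments (a documented choice; length- or area-weighted sampling is a
switch away), calibrate each square-pulse amplitude by bisection until the
local peak deflection lies in 2–20 mV, and report each monitor window's
peak |ΔV| (mean over the window's sites) as a proportion of the source
peak. "Peak" is the max over time of |V − E_pas|; pulses default to 10×
the membrane time constant so peak and steady state coincide and the
steady-state identities apply. The asymmetry identity — proportion ratio
equals inverse input-resistance ratio — is algebraically exact at steady
state and is verified through two independent computation routes (transfer
matrix vs direct solves).

The virtual ablation severs one edge, rebuilds the component containing the
LH monitors, and re-applies whatever stimuli still have their target
compartments: an AL-isolating cut drops the AL hyperpolarization (modelled
as current injection, since the model is passive), a contralateral control
cut retains it. AL "inhibition" as current rather than conductance is a
deliberate simplification; a shunting synapse would make the boost after
transection larger still.

## Synthetic data

The imaging generator emulates slow-indicator volumetric odor imaging: 12
odors × 3 trials, 90 volumes/trial at 6.5 volumes/s, odor on at 2 s for
1 s, positive textured baseline, alpha-function temporal kernel peaking
~1 s after onset (slow-indicator-like), per-voxel Gaussian noise (0.02
ΔF/F per voxel by default), response amplitude 0.3 ΔF/F. AL-like scenarios
plant one shared non-negative mode with negative odor gains and one
sign-flipped weak outlier odor (ammonia-like); LH-like scenarios plant
per-odor non-negative modes, optionally grouped so some odor pairs are
similar. Image size defaults to 64×64 (the recordings' 256×256 is a
config away); tests and the acceptance script use 32×32, which preserves
every statistical property being tested at a fraction of the cost. What
the generator does **not** emulate: motion artifacts, photobleaching,
indicator kinetics beyond the fixed kernel, optical sectioning, and
correlated (non-Gaussian) noise — so passing planted-recovery tests shows
the statistics behave as designed, not that real movies are this clean.

The random-tree generator allocates an exact total-length budget per region
(AL 40 %, LH 30 %, contralateral 20 %, other 10 % of 1 mm by default), so
realized fractions match requests; radii taper linearly with path distance
(0.5 µm → 0.05 µm). The contralateral arbor hangs off a commissural stem
of 0.02 µm radius — the caliber EM measurements report for such processes —
making it electrotonically remote, as in the real cell; the control
transection in tests is placed mid-commissure, mirroring a laser cut along
the neurite rather than at the soma.

## Numerical choices and degenerate inputs

- ΔF/F pixels with non-positive baseline are NaN-masked, counted and
  logged, not silently zeroed.
- The Gaussian smoothing kernel is 4×4 px, σ = 1 px, unit-sum, reflective
  boundary (even-size kernels are centered between pixels).
- The peak-response search runs from odor onset to 3 s after offset, on the
  smoothed ROI-mean trace, by absolute deflection (so inhibitory peaks are
  found); the 3-volume window is determined once per preparation and reused
  across trials. Peaks at the series edge clip the window with a warning.
- PCA is an SVD of the column-centered pixels × odors matrix (per-odor mean
  removed over pixels — the princomp convention; row-centering would remove
  the shared inhibitory mode PC1 is meant to reveal). Score images are
  zero off-mask; variance fractions are non-increasing and sum to 1 for
  full-rank input.
- Per-pixel CV excludes pixels with |mean across odors| < 10⁻³ ΔF/F
  (configurable) instead of producing unbounded ratios; zero-variance
  response images make correlations NaN with a warning.
- Linkage is average (UPGMA) by default — monotone and robust for
  correlation-derived distances; single and complete are accepted.
- Paired comparisons with exactly zero differences return t = 0, p = 1;
  zero-variance nonzero differences return NaN with a warning.
- Bisection in amplitude calibration works on a geometric grid and is
  deterministic; unreachable targets raise.

## Known limitations

- One compartment per morphology node; finer electrical discretization is
  obtained by resampling the morphology, not inside the model builder.
- The fitted model assumes spatially uniform specific parameters, as the
  study design does; regional heterogeneity is out of scope.
- The propagation proportions of a real reconstruction depend on the actual
  parameter values, which are not uniquely identified by somatic fits; the
  package's claims are therefore about the identity structure (reciprocity,
  resistance ratios, ablation signs), which hold for any passive
  parameterization.
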