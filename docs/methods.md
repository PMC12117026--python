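# Methods

`scatpol` implements the per-pixel analysis chain of a correlative
polarimetric / scattered-light fiber-imaging experiment on unstained brain
sections, together with a forward simulator so that every stage can be
validated against known ground truth. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## 3D-PLI signal model and fit

A section between a rotating linear polarizer (azimuth ρ) and a circular
analyzer produces, per pixel, a sinusoid with period 90° in ρ:

    I(ρ) = I0 + ΔI · sin(2ρ − 2φ)

Myelin birefringence sets the amplitude, the in-plane fiber direction φ the
phase. The derived quantities follow the field's conventions: transmittance
τ = I0/2, retardation |sin δ| = ΔI/I0 ∈ [0, 1], direction φ ∈ [0°, 180°)
with 0° along the positive x-axis and the signal maximal at ρ = φ + 45°.

The fit is a discrete Fourier coefficient fit: I0 = mean(I),
s = (2/n) Σ I_k sin 2ρ_k, c = (2/n) Σ I_k cos 2ρ_k, ΔI = √(s²+c²),
φ = ½·atan2(−c, s). For n equidistant angles covering [0°, 180°) this is the
exact least-squares solution of the three-parameter model (verified against
an independent nonlinear least-squares oracle in the tests); non-equidistant
grids fall back to linear least squares on the basis {1, sin 2ρ, cos 2ρ},
which reduces to the same coefficients on equidistant grids.

Numerical choices:

- Amplitudes below 64·ε·max(|I0|, max|I|) (ε = double-precision machine
  epsilon) are treated as exact zeros, so constant profiles report no
  direction instead of a round-off phase. This also keeps constant
  background pixels direction-free.
- Pixels with I0 ≤ 10⁻⁶ of the stack maximum are invalid; their maps are
  NaN, never 0 — "no light" is distinct from "no birefringence".
- Retardation normalization ("the retardation of in-plane parallel fibers")
  uses, in `auto` mode, the 99th percentile of the valid retardation values
  as a robust stand-in, since the reference is sample-dependent and no
  measurement protocol for it is universal. A scalar reference can be given
  instead.

## Retardation–inclination model

The out-of-plane inclination α weakens the birefringence signal. The package
uses the standard thin-section model r(α) = sin(δ0 cos²α)/sin(δ0) with the
in-plane retardance δ0 (default π/2, a quarter-wave match typical of
~60 µm sections at green wavelengths) and inverts it for a continuous α
estimate. Only the bin labels are normative, tied to the printed retardation
thresholds: r ≥ 0.68 ↔ in-plane (α ≤ 30°), r ≤ 0.17 ↔ steep (α ≥ 65°),
inclined in between. The continuous estimate is model-configurable because
no closed functional form reproduces both printed threshold pairs exactly;
downstream classification uses only the thresholds.

## ComSLI peak analysis

Oblique illumination from azimuths covering [0°, 360°) yields, per pixel, a
circular intensity profile in which a fiber bundle at direction φ scatters
into a pair of peaks at φ + 180° ± d/2 (perpendicular to the fiber axis);
the pair mid-position mod 180° is the direction, and the pair distance d is
180° for in-plane fibers, shrinking with inclination.

- **Peak detection.** Local maxima on the circle with topographic
  prominence. The profile is unwrapped at its global minimum — which can
  never carry a peak — and `scipy.signal.find_peaks` provides the standard
  prominence on the cut profile; this equals circular prominence, as the
  tests verify against a brute-force exhaustive-path oracle. Plateau peaks
  report their center sample (the smaller-angle center for even plateaus).
  The prominence threshold is applied on raw intensities and is a per-
  dataset configuration value; the phantom analyses use 10 a.u. at the
  simulator's 12-bit-like scale.
- **Pairing.** Peaks whose circular separation lies within 180° ± 35°
  (boundary inclusive) are paired greedily in order of decreasing summed
  prominence, each peak used at most once. The greedy matching attains the
  maximum number of valid pairs on all tested configurations (checked
  against an exhaustive matching oracle).
- **Directions.** Each pair contributes its mid-position mod 180°; a single
  prominent peak (with no pairs and no other peaks) contributes its own
  position mod 180°. A lone unpaired peak coexisting with valid pairs
  contributes nothing. At most three directions per pixel, ordered by
  prominence.
- **Optional sub-bin refinement.** A weighted circular centroid over the
  samples above (peak − prominence/2), with weights taken as the intensity
  excess above that cutoff (baseline-subtracted weighting keeps the
  asymmetric sampling window from biasing the centroid). Off by default to
  match the discrete analysis; on noiseless off-grid phantoms it reduces
  the worst-case direction error from half the angular step (7.5° at 24
  angles) to below 2°.

Identical pixel profiles are analyzed once and the results broadcast, which
makes noiseless phantom runs effectively constant-time in the image size.

## Tissue and architecture classification

Thresholds replicate the printed inequality directions exactly:

| quantity | rule | default |
| --- | --- | --- |
| background | mean scattering Ī ≤ `bg_avg_max` | 20 a.u. |
| gray matter | not background and r < `gm_ret_max` | 0.07 |
| white matter | remainder | — |
| parallel in-plane | r ≥ `inplane_ret_min` | 0.68 |
| parallel inclined | 0.17 < r < 0.68 and prominence ≥ `prominence_min` | 0.3 (human) / 1.0 (vervet) |
| parallel steep | r ≤ `steep_ret_max` and Ī > `steep_avg_min` | 1200 (human) / 430 (vervet) a.u. |
| crossing | remaining white matter | — |

Prominence and average-scattering thresholds are in raw camera units and
therefore ship as sample presets (`human`, `vervet`). NaN retardation
(invalid PLI pixel) counts as r = 0 for classification and as "no PLI
direction" for fusion.

## Multimodal fusion

Per pixel the first matching rule wins:

1. crossing → all ComSLI directions (PLI averages over crossings and cannot
   separate them);
2. other white matter where the modalities disagree — closest-direction
   difference above `agree_tol_deg` — or where no valid PLI direction
   exists → ComSLI directions;
3. white parallel pixels whose PLI direction agrees with some ComSLI
   direction → PLI in channel 1 (lower angular discretization, more stable
   signal), remaining ComSLI channels kept;
4. gray matter → ComSLI channel 1 if present, else PLI; further ComSLI
   channels kept;
5. background, and white pixels without any ComSLI direction → empty. A
   PLI direction unsupported by any scattering signal is not considered
   reliable, which is why steep-fiber regions can stay black even when PLI
   reports a direction there.

Design choices: `agree_tol_deg` defaults to 25°, between the ComSLI angular
step (15°) and the pairing tolerance (35°) — the agreement threshold itself
is not standardized, so it is configurable. Rule 2 is extended to white
pixels with ComSLI but no PLI direction (agreement cannot be confirmed, so
the scattering directions are used); rule 2 fills all found ComSLI channels,
not only the first. Provenance labels (`none`/`pli`/`sli`) are stored per
channel, and every emitted direction is verbatim one of the input
directions.

## Mueller module

The auxiliary polarimetric path solves I_s = a_s·M·g_s per pixel by least
squares over ≥ 16 states (the Kronecker design matrix must have full column
rank; deficiency raises an error naming the unresolvable elements). The
canonical 36-state (6 × 6 basis states) and minimal 16-state sequences are
provided; the exact instrument sequence is configurable. The Lu-Chipman
polar decomposition factors M/m00 = M_Δ·M_R·M_D with the diattenuator built
from the first row, the depolarizer from the matrix square root of m'm'ᵀ
(sign from det m'), and the retarder as the remainder. Scalar summaries:
D = ‖(m01,m02,m03)‖/m00, R = arccos(tr(M_R)/2 − 1), the depolarization
index 1 − |tr(M_Δ) − 1|/3 (a common scalar summary; other indices exist and
the factors are exposed for custom ones), and the linear-retardance
fast-axis orientation ½·atan2(a₂, a₁) from the retarder's axis vector
(NaN for zero or purely circular retardance). Per-pixel decomposition
failures yield NaN maps rather than aborting.

## Synthetic phantom and forward simulation

The `vervet-like` layout tiles the image with a background frame, a
gray-matter band, in-plane / inclined / steep parallel-fiber bands, and
2-/3-way crossing blocks — the architectures exemplified in real sections by
the corpus callosum (in-plane), fornix (inclined), cingulum (steep), and
corona radiata (crossing). Acquisition geometry defaults match the
instrument protocol: 18 polarizer angles in 10° steps for 3D-PLI, 24
illumination azimuths in 15° steps for ComSLI.

**3D-PLI forward model.** Incoherent weighted sum of population sinusoids,
I(ρ) = I_base·(1 + Σ_p w_p sin δ(α_p) sin 2(ρ − φ_p)) with
δ(α) = δ0 cos²α; equal populations 90° apart cancel exactly, reproducing
PLI's blindness to orthogonal crossings. Base intensity 1000 a.u.
(12-bit-like) so the printed intensity thresholds are meaningful.

**ComSLI forward model.** Baseline 300 a.u. plus, per population, a
wrapped-Gaussian peak pair (σ = 20°, amplitude 200·w a.u.) centered so the
mid-position equals φ, with pair distance d(α) = 180° − κ·α. The distance
law is a declared stand-in (no published closed form exists); κ defaults to
0.5 so that the inclined band (α = 50°, the representative inclination whose
retardation 0.60 sits inside the inclined bin) produces pairs at d = 155°,
inside the 180° ± 35° pairing window — with κ = 1 every inclination in the
inclined retardation bin would fall outside the window and could never pair,
contradicting the intended round-trip behaviour. Steep-fiber pixels get a
broad (σ = 60°), low-contrast (2 a.u.) modulation on an elevated baseline of
1500 a.u.: strong average scattering (> the steep thresholds) without
detectable peaks, which both triggers the steep classification and
reproduces the empty-ComSLI behaviour of near-orthogonal bundles. Gray
matter is a flat 100 a.u. profile, background a constant 5 a.u.

**Phantom parameter choices.** Inclinations 50° (inclined) and 75° (steep)
place the band retardations at 0.60 and 0.105 — inside their bins and, for
the steep band, above the 0.07 gray-matter threshold. Crossing blocks use
unequal population weights (0.56/0.44 and 0.40/0.33/0.27): physically,
crossing bundles rarely have identical density, and exactly equal weights
would cancel the PLI sinusoid completely, pushing the residual retardation
below the gray-matter threshold and misclassifying the block. The chosen
weights leave residual retardations of 0.12 and 0.113, inside the
(0.07, 0.17] window that keeps the blocks white yet neither in-plane,
inclined (their prominence is high, but r ≤ 0.17), nor steep (their average
scattering stays below the steep thresholds under the human preset, which
the phantom analyses therefore use).

**Noise and artifacts.** Additive Gaussian noise (σ in a.u.) and optional
Poisson shot noise, seeded and reproducible; the same seed yields the same
standard-normal draws, so direction error grows monotonically with σ.
Deterministic artifact overlays emulate known instrument effects: a
multiplicative gain gradient (transmittance asymmetry from retarder
ellipticities — it moves the transmittance map but leaves the fitted phase
untouched) and a localized "wheel" (an azimuthal modulation whose phase
rotates around a center, producing spurious local directions as embedding-
medium artifacts do). Ground truth is never modified.

**What the simulator does not emulate.** Real point-spread functions and
optical blur, tissue heterogeneity within a pixel, spatially correlated
noise, illumination inhomogeneity beyond the linear gradient, scattering
anisotropy line shapes beyond wrapped Gaussians, and any physical link
between the PLI and ComSLI intensity scales. Passing round-trip tests
therefore demonstrates the correctness and self-consistency of the analysis
chain under the stated models, not its accuracy on real acquisitions.

## Rendering

Directions are axial, so the color wheel uses hue = 2φ (plus a configurable
rotation; φ = 0° maps to red by default), making φ and φ + 180° identical
and the wheel a bijection on [0°, 180°). Multi-direction pixels become
f × f subpixel mosaics (default f = 2) whose subpixels cycle through the
pixel's directions — one direction fills the block, two give a 2+2 split,
three a 2+1+1 split; direction-free pixels are black. Vector overlays draw,
per n × n kernel (default 20), one segment per distinct (direction, weight)
combination in the block, length scaled by the weight map normalized to its
global maximum. Image row 0 renders at the top; angles are interpreted in
math convention (y up) and flipped only at draw time.

## Problem sizes and tolerances in the test suite

Noiseless round trips run on 64×64 phantoms throughout and once on 256×256;
noisy direction-recovery checks use 10⁴ profiles at σ = 1% of I0 (RMSE
< 0.5° for retardation ≥ 0.3); oracle-equivalence suites use 100 random
sinusoids (agreement to 10⁻⁸ relative) and 200 random 24-sample circular
profiles (exact agreement); Mueller recovery is exercised to 10⁻⁶ on
canonical elements and round-trips to 10⁻⁸ on nondepolarizing products.
These sizes keep the full suite in a few seconds while every tolerance is
meaningful for the corresponding arithmetic.

## Known limitations

- The continuous inclination estimate is as good as the r(α) model; only
  the bins are protocol-anchored.
- The peak-distance-vs-inclination law in the simulator is a stand-in; the
  exported pair-distance map is not converted to inclination.
- Greedy peak pairing maximizes summed prominence first; pathological
  peak sets could in principle admit a different maximum-cardinality
  matching (none found in randomized testing against the exhaustive
  oracle).
- No flat-field or retarder-voltage calibration is modeled; the Mueller
  module assumes the instrument's state vectors are known exactly.
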