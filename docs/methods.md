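# Methods

This note documents the models, numerical choices and known limitations of
`paretoplan`. Everything here describes what the code does and why; no
empirical claim is made beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Coordinate conventions

Regular voxel grid, axis order (x, y, z): x left–right, y anterior–posterior
with **+y posterior**, z inferior–superior with **+z superior**. Voxel centres
carry all geometry; every distance in the package (margin expansion,
conformality shells, fall-off thresholds) is a voxel-centre distance. Defined
once in `paretoplan.coords` and used everywhere.

## Phantom

The phantom emulates prostate-only anatomy planned under a 60 Gy / 20-fraction
simultaneous-integrated-boost protocol: prostate and up to 2 cm of proximal
seminal vesicles as targets; rectum, bladder and — in the institution-B
profile — femoral heads and bowel as organs at risk. Organs are analytic
ellipsoids/cylinders voxelised by the centre-inside rule; per-patient anatomy
is drawn from documented uniform ranges (`phantom.DEFAULT_ANATOMY`, mm) by a
seeded generator, so a seed fully determines a patient.

Design choices:

* **Grid** defaults to 64×64×48 at 4 mm. Clinical CTs are ~2 mm; the coarser
  grid is a deliberate desk-scale choice (every stage runs in seconds) and
  both grid and spacing are configurable. Tests and the acceptance script use
  32³–48³ grids at 4 mm.
* **Rectum abutment.** The rectum is a posterior tube whose analytic surface
  interpenetrates the prostate by `rectum_overlap` (default 2 mm) and is then
  carved back, making the masks disjoint but face-adjacent. Exact tangency
  (overlap 0) occasionally leaves a one-voxel gap on the 4 mm lattice, which
  would break the intended behaviour that PTV57.5's 5 mm posterior margin
  crosses the rectal wall. The 2 mm value can leave a few lateral sliver
  voxels of rectum inside PTV60; the prostate–rectum disjointness and PTV
  nesting invariants always hold.
* **Margins.** PTV60 = prostate + 5 mm (0 posterior); PTV57.5 = prostate +
  10 mm (5 posterior); PTV48 = (prostate ∪ vesicles) + 10 mm; all clipped to
  the body contour. Expansion is morphological dilation with an anisotropic
  footprint: offset v is included iff `Σ_i (v_i / m_i(sign v_i))² ≤ 1`, the
  ellipsoidal interpolation between the six directional margins. This matches
  common treatment-planning-system behaviour and is verified against a
  brute-force per-voxel distance oracle.
* Seminal-vesicle extent is a parameter (default 15–20 mm) — the anatomy is a
  stand-in, not a claim of clinical fidelity.

## Dose engine

A linear beamlet model `d = D·x`: the single 360° arc is discretised to
`n_beams` equispaced static coplanar beams (default 36; studies in this
package use 8–16 for speed); per beam, beamlets tile the targets'
beam's-eye-view bounding box (+10 mm margin) on an 8 mm raster. A beamlet's
dose to a voxel is

    output_scale · exp(−μ · depth) · exp(−lateral² / (2σ²))

with depth the ray-marched path length inside the body (4 mm steps,
nearest-voxel sampling) and lateral the in-plane distance from the beamlet
axis. Constants μ = 0.005 /mm and σ = 5 mm are **non-clinical**: they are the
simplest physics that makes target-vs-OAR trade-offs real. σ/pitch was chosen
≈ 0.6 deliberately — below ~0.5 the Gaussian comb leaves a static ±9%-per-axis
ripple that no fluence modulation can remove, which would make homogeneity
goals unattainable by construction. Lateral kernel values below 1% of peak are
dropped (sparsity floor). Rows for voxels outside the body are identically
zero.

Plans are normalised by a single scale factor so the boost PTV's median dose
(D50%) equals the prescription (60.0 Gy), applied identically to both
institution profiles.

## Protocol and penalties

Goals carry priority P1/P2/P3; optimiser weights are 1000 / 250 /
the goal's stored weighting factor (WF). Targets resolve from Gy, % of the
ROI's own PTV prescription, % of the overall prescription, or % of ROI volume.

Penalties are quadratic, one-sided, volume-normalised (Gy² units), with exact
analytic gradients:

* min-dose `Σ max(0,T−d)²/N`; max-dose/conformality `Σ max(0,d−T)²/N`;
  mean-dose `max(0, mean−T)²`.
* **Dose-volume maximum**: with allowed fraction f and voxels above the dose
  level L, the `n_above − ⌊fN⌋` *lowest-dosed* voxels above L are pulled
  toward L. Penalising the cheapest violators keeps the penalty continuous in
  dose at tie boundaries.
* **Median ceiling** ("D50% max") is a dose-volume maximum at 50% volume.
* **Fall-off**: threshold map `max(low, high − g·dist)` with dist the
  Euclidean centre-distance (cm) to the source region — the union of PTVs for
  the external fall-off (applied on body ∖ PTVs), the next-higher PTV for
  intra-PTV fall-offs (applied on the ROI ∖ higher PTVs). The PTV57.5
  intra-PTV fall-off with high = low = 54 Gy degenerates, intentionally, to a
  uniform 54 Gy ceiling.
* **Region convention**: ceiling-type goals (max-dose, median ceiling,
  dose-volume maximum) on a lower-prescription PTV are evaluated on the PTV
  minus all higher-prescription PTVs, since the nested boost violates the
  full-ROI form by construction. This mirrors the PTV-subtraction convention
  used when reporting D98/D2/HI.
* Max-dose goals are optimised on all voxels above target, but their
  *achieved* value for dynamic positioning uses the near-max D1% surrogate
  (stable under discretisation); reported plan metrics give the true voxel
  maximum alongside.

## PBAIO loop

Each outer loop: inner optimisation → dynamic positioning → dynamic
weighting; a final inner optimisation and normalisation close the plan. The
inner optimiser is projected gradient descent (fluence ≥ 0) with backtracking
line search; accepted steps never increase the objective and the whole loop is
deterministic, so a plan is bit-reproducible from its inputs.

* **Dynamic positioning**: every P3 goal with a DVH or mean parameter gets
  `target ← max(0, achieved − δ)`; δ = 2% for volume-type and 1 Gy for
  dose-type parameters (global per unit kind, overridable). Initial targets
  are the protocol targets; their value is irrelevant after the first loop.
* **Dynamic weighting**: `w ← w · clip(((WF·penalty)/τ)^α, 1/ρ, ρ)` with
  α = 0.5, ρ = 4, τ = 1e-4. The fixed point `WF·penalty = τ` makes the stored
  WF the cross-patient balancing knob. Because the positioning rule keeps
  most trade-off penalties permanently above their fixed point, the raw rule
  would amplify weights by ρ^loops (≈65k at the defaults) and invert the
  P1 > P2 > P3 hierarchy — measured on the phantom, this destroys target
  coverage. The update is therefore additionally banded relative to the
  stored WF: `w ∈ [WF/16, 2·WF]` (`weight_band_down`/`weight_band_up`). The
  band preserves both stated functions of the rule (objective values trend
  toward a target; WF sets relative balance) while keeping weights on the
  same scale as the hard-coded 1000/250, which is what makes Table-2-scale
  WFs meaningful calibration knobs.
* Loop sizes default to 60 inner iterations × 8 outer loops; the cohort
  studies use 20 × 3 (documented desk-scale choice, behaviourally identical).

### Attainability at desk scale

With the institution-A protocol on the default phantom, boost-PTV (PTV60)
target goals are met within 1.5% (D98/D2 convention). The lower PTVs' D98
sits several percent below target: their posterior margins overlap the
abutting rectum tube within one penumbra width, and the rectum trade-off
goals legitimately win there. This persists with more iterations, more beams
and 2.5 mm voxels — it is a property of the phantom geometry plus simplified
penumbra, not of the loop — and the corresponding test asserts the 1.5%
bound for PTV60 and a documented 10% bound for the lower PTVs.

## Pareto navigation

Dimensions are goal parameters (WF or target) with 2–7 strictly increasing
sampled values; the dataset holds one plan per value combination (shared
geometry, influence matrix and seed), generated exhaustively in lexicographic
order. A warning is emitted above 4 dimensions (grid size grows as the product
of sample counts). Navigation interpolates the 2^D corner doses of the
enclosing cell multilinearly, voxel-wise, on **normalised** plan doses; no
extrapolation outside the sampled hyper-rectangle. Metric evaluation at a
position never re-runs optimisation (the real-time contract of a slider
interface). WF dimensions interpolate in raw parameter value; since stored
WFs span orders of magnitude, choosing log-spaced sample values is the
recommended (and tested) way to cover a decade. Sequential navigations are
supported by committing a position and generating the next dataset from the
committed protocol. Merging calibrations averages WFs arithmetically
(geometric mean selectable); targets must agree.

## Metrics and statistics

Dx% uses descending order statistics at midpoint cumulative fractions
`(i+0.5)/N` with linear interpolation and clamping at the extremes — simple
enough to verify against a brute-force sorting oracle, which the suite does on
random fields. V(d) counts voxels with dose ≥ d. HI = (D2% − D98%)/D50%
(reported prominently because the comparison tables depend on this choice);
Paddick CI = TV_PIV²/(TV·PIV) with the reference isodose defaulting to 95% of
the PTV's nominal prescription. D98/D2/HI are reported on PTVs with
higher-prescription PTVs subtracted.

The paired comparison uses a two-sided Wilcoxon signed-rank test: zero
differences omitted; fewer than 10 informative pairs → "not tested"; exact
null law for n ≤ 15 via a rank-sum distribution over all 2^n sign assignments
(dynamic programming on doubled ranks, tied ranks averaged); tie-corrected
normal approximation with continuity correction for n > 15. The exact route
is tested against full 2^n enumeration and against an independent library
implementation.

## Study machinery

* The calibration-propagation experiment builds the four-dimension navigation
  (PTV60 min/max dose targets, rectum mean-dose WF, external fall-off WF) on
  patient 1, commits a rectum-sparing vertex (Cal1) and a balanced vertex
  (Cal2), replans the cohort under both and reports rectum Dmean, HI(PTV60),
  CI(PTV48) and their Cal1−Cal2 deltas. Defaults: 10 patients, 48³ grid,
  12 beams, 2 samples per dimension.
* The end-to-end study runner has no clinical comparator arm at desk scale;
  it substitutes a deliberately mis-prioritised protocol (rectum and fall-off
  weights slashed) so that the comparison machinery — metric panel, Wilcoxon
  table, goal pass rates, 1–1 plots, reproducibility manifest — is exercised.
  Its outputs are byte-reproducible from the manifest (seeds, configs,
  version).

## What the synthetic setting does and does not show

Passing tests demonstrate the *mechanisms*: margin and shell geometry, linear
dosimetry, penalty calculus, the positioning/weighting dynamics, navigation
identities, calibration propagation with the expected trade-off signs, and
the statistical rules. They do not validate clinical dose levels: the dose
kernel is invented, anatomy is idealised, there is no aperture sequencing,
monitor-unit modelling or delivery constraint, and absolute metric values on
phantoms are not comparable to values obtained on patient CTs with a
commercial planning system.
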