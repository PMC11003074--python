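# paretoplan

Automated radiotherapy treatment planning with Pareto-navigation calibration,
runnable end to end on procedurally generated prostate phantoms.

## What problem this addresses

Automated inverse-planning engines must be *calibrated*: someone has to decide
how strongly each normal-tissue trade-off (rectum dose, bladder dose, dose
fall-off, conformality) is weighted relative to target coverage. The usual
options — trial-and-error or machine learning on historical plans — give the
planner no live view of what each choice costs. This package implements the
alternative: a **protocol-based automatic iterative optimisation (PBAIO)**
planning engine whose trade-off weights are chosen by **multi-dimensional
Pareto navigation** — generate a grid of differently weighted plans once,
explore the continuum between them by interpolation in real time, and store
the navigated weights back into the planning protocol.

It is aimed at medical-physics researchers who want a fully inspectable,
desk-scale model of this workflow: every stage (anatomy, dose, optimisation,
navigation, statistics) is synthetic, deterministic and testable without
clinical data or a commercial treatment planning system.

## The model

**Protocol.** A planning protocol is an ordered list of goals in three
priority levels: P1 critical conformality goals and P2 target goals carry
hard-coded optimiser weights (1000 and 250); P3 normal-tissue trade-off goals
carry explicit weighting factors (WF) — the calibration knobs. Goal penalties
are quadratic, one-sided and volume-normalised, e.g. a minimum-dose goal with
target T contributes `Σ_v max(0, T − d_v)² / N`, and dose fall-off goals
penalise dose above a per-voxel threshold
`max(low, high − g·dist(v))` built from the distance to the target volumes.

**PBAIO loop.** Between fluence optimisation passes (projected gradient
descent on the weighted penalty sum, fluence ≥ 0) each P3 objective is

* *repositioned*: its target is set a constant offset δ below the DVH value
  it currently achieves (a V23.4Gy objective achieving 9.0% gets target
  `9.0% − δ`), so trade-offs keep being pushed; and
* *reweighted*: its weight is multiplied by
  `clip(((WF·penalty)/τ)^α, 1/ρ, ρ)`, whose fixed point `WF·penalty = τ`
  makes the stored WF control each trade-off's residual — the mechanism that
  propagates one calibration consistently across patients.

**Pareto navigation.** A navigation dimension is any goal parameter (a WF or
a target) with 2–7 sampled values; one plan is optimised per value
combination. A continuous position in parameter space is rendered by
voxel-wise multilinear interpolation of the 2^D surrounding corner plans, so
DVHs and metrics update without re-optimisation. `commit_calibration` writes
the navigated values into the protocol; calibrations from several patients
can be merged by averaging WFs.

**Evaluation.** Plans are scored with the standard panel: Dx%, V_dose,
Dmean/Dmax, homogeneity index `HI = (D2% − D98%)/D50%`, Paddick conformity
index `CI = TV_PIV²/(TV·PIV)`, and a CHHiP-style clinical goal table (60 Gy
in 20 fractions, simultaneous integrated boost; PTV60/PTV57.5/PTV48). Paired
cohorts are compared metric-by-metric with a two-sided Wilcoxon signed-rank
test, omitting exact ties and reporting "n < 10" instead of a p value when
fewer than ten informative pairs remain.

The dose engine is a deliberately simple linear beamlet model (equispaced
coplanar beams, exponential depth attenuation, Gaussian lateral penumbra) —
physically plausible, non-clinical, and sufficient to make the trade-offs
real. Plans are normalised so the boost PTV's median dose equals 60.0 Gy.

## Worked example

```bash
python examples/03_pareto_navigation.py
```

generates a 3×3 Pareto dataset over rectum-Dmean WF × external fall-off WF
on a 32³ phantom and navigates it:

```
dataset: 9 plans over dimensions ['rectum.mean_dose.weighting_factor', 'external.dose_falloff_external.weighting_factor']
rectum WF   0.58: rectum Dmean = 22.906, PTV60 HI = 0.059, PTV48 CI@45.6Gy = 0.777
rectum WF   5.84: rectum Dmean = 21.921, PTV60 HI = 0.059, PTV48 CI@45.6Gy = 0.775
rectum WF  20.00: rectum Dmean = 19.889, PTV60 HI = 0.060, PTV48 CI@45.6Gy = 0.770
rectum WF  58.40: rectum Dmean = 14.380, PTV60 HI = 0.063, PTV48 CI@45.6Gy = 0.756
committed rectum Dmean WF: 20.0
```

Sliding the rectum weight up spares the rectum (Dmean 22.9 → 14.4 Gy) at the
expense of boost homogeneity (HI 0.059 → 0.063) and conformality
(CI 0.777 → 0.756) — the
trade-off the operator balances before committing a position. The other
examples cover phantom generation, a single automated plan with its goal
table, and a miniature calibrated-vs-comparator cohort study.

A thin CLI mirrors the main entry points
(`paretoplan phantom|autoplan|evaluate|study`).

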