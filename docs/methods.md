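# Methods

## Model structure and assumptions

The package couples two tiers. Tier 1 is a 1-D reaction–diffusion system
for FGF8, WNT8C and RA on the spatial maturation domain — the 2500 μm
strip between the NMP zone (caudal, x = 0) and the anterior boundary of
the last formed somite (rostral, x = 2500 μm). The domain comoves with
axial elongation at v = 3 μm/min, so no advection term appears; instead
the caudal *Fgf8* transcription input carries the comoving decay constant
λ = β_Fm / v = 0.006 / 3 = 0.002 μm⁻¹, with β_Fm = ln 2 / 120 min ≈
0.006 min⁻¹ from the 2 h transcript half-life. mRNAs do not diffuse;
proteins and RA do. RA synthesis is proxied by RALDH2 translation (one
state variable plays both roles) and CYP26A-mediated RA catabolism is
folded into an FGF8-dependent decay multiplier 1 + β_FR·hill(F; F_FR2)
with β_FR = 6 treated as a dimensionless fold-increase (its printed
"/min" unit is inconsistent with its position inside the bracket).

Tier 2 is a 15-variable Hill-ODE network per cell (mRNA + protein for
T/BRA, SOX2, NKX1.2, CDX4, X, PAX6, Y; *Ngn2* mRNA as terminal readout),
driven by interpolated (F, W, R) along the cell's trajectory. There is no
feedback from transcription factors onto the signals, no NOTCH/GDF11/Hox13
input, and NP production is implicit in the constant-velocity comoving
frame — all stated scope limits of the underlying network model.

All regulatory functions are built from three primitives on the reduced
variable u = (x/K)ⁿ: activation u/(1+u), repression 1/(1+u), and
shared-promoter competition (b + Σu_act)/(1 + Σu_act + Σu_rep) with an
optional basal term (used only by *Pax6*, whose promoter additionally
requires the RA arm as a multiplicative gate). Hill exponents are 2
throughout (dimeric binding). Hill constants are the half-effect
concentrations and are inversely related to interaction strength.

## Parameters

Signaling rates (min⁻¹): α_Fm = 1, β_Fm = 0.006, α_Fp = 0.3,
β_Fp = 0.005; α_Wm = 0.1, β_Wm = 0.03, α_Wp = 0.3, β_Wp = 0.01;
α_Rm = 1, β_Rm = 0.03, α_Rp = 0.3, β_Rp = 0.025. Diffusivities
(μm²/min): D_F = 120, D_W = 10, D_R = 1200. Input amplitude 0.06 AU.
The six interaction Hill constants come in eight preset columns (I–VIII);
column II (F_FW = 10, F_FR1 = 1, F_FR2 = 10, W_WR = 1, R_RF = 1,
R_RR = 50) is the balance reference and the default.

TF rates: α_m = 1, β_m = 0.03, α_p = 1, β_p = 0.2 min⁻¹ for every factor
except the CDX4 protein (β_Cp = 0.05 min⁻¹, reflecting its enhanced
stability). The 20 curated Hill constants live on `TFParams`; uniform
(all-20, all-2) variants and global/individual scaling are one-call
transforms. The domain-extraction threshold (0.1 of a gene's spatial
peak), the classifier thresholds and all perturbation amplitudes are
exposed in the config layer.

## Numerics

Method of lines: central second differences with zero-flux (reflecting,
ghost-point) boundaries at both ends — the natural closed-tissue choice;
the scheme conserves the trapezoidal integral under pure diffusion. The
default grid has 251 points (dx = 10 μm), so the shortest diffusion
length, √(D_W/β_Wp) ≈ 32 μm, spans ≥3 cells. Time integration is LSODA
with a banded Jacobian (point-major state ordering gives bandwidth 6),
rtol 1e-6 / atol 1e-9, sampled every 10 min to t_end = 6000 min. Solver
undershoot is clamped to zero before entering Hill terms, sampled values
below zero are clipped, and a negative excursion beyond −1e-6 aborts the
run as a blow-up. Doubling the grid changes final profiles by <0.01%
relative L2.

The default initial condition is the established *Fgf8* mRNA gradient
(Fm = α_Fm F0(x)/β_Fm, everything else zero): the modeled window opens
with caudal *Fgf8* transcription already in place, and the switch presets
then complete in 970 / 2500 / 5160 min (fast < intermediate < slow). From
an all-zero cold start (available via `initial=`) RA wins before FGF8 is
established and the same presets complete in ~400–500 min without the
fast/slow ordering; the cold start is used only where a from-nothing
relaxation is itself the point (e.g. the long-run stationarity check).

Cohort integration: assembling a 251-position profile needs 251 cell
histories. Each cell's lifetime is mapped onto a common scaled age
s ∈ [0, 1] (derivatives scale by lifespan), signals are pre-sampled along
each trajectory at 1-min resolution, and all cells advance through one
banded-LSODA solve (bandwidth 14; blocks are independent). This is ~20×
faster than per-cell solves and agrees with them to <1% (tested).

## Regime classification

The four outcome labels were assigned qualitatively in the source
experiments; the decision cascade here is an explicit reconstruction with
all thresholds on `ClassifierConfig`:

1. **FGF dominance**: max R < 1% of max F at the final time.
2. **Aberrant/oscillatory RA**: spatially integrated RA over the final
   half of the run shows ≥3 alternating extrema with range >20% of its
   mean (prominence filter 5% rejects solver ripple), **or** integrated RA
   peaked earlier at >1.5× its final value (a burst that collapsed back to
   FGF8 production), **or** the final RA profile peaks in the interior
   with the rostral endpoint below 50% of the peak (RA should rise toward
   the somites). The burst/interior-peak arms are required because one
   aberrant preset produces a single transient burst rather than a
   sustained oscillation.
3. **FGF→RA switch**: RA ≥ FGF8 (signaling-molecule levels, R > 0) at
   every grid point, sustained to the end; the completion time is the
   first such sample.
4. **Balance**: an RA-vs-FGF8 front exists and drifts <5% of the domain
   length over the final third.

Anything else raises an explicit "unclassifiable" error rather than
guessing.

## Domains, pattern verdict and perturbations

A gene's transcription domain is where its mRNA exceeds 10% of its own
spatial maximum — a detectability criterion chosen to mirror in-situ
hybridisation, which reports transcripts well below their peak (at 50%
the uniform-strength control networks spuriously pass the pattern test).
Edges are linearly interpolated between grid points; gaps ≤20 μm are
bridged and slivers <10 μm dropped (noise-ragged boundaries). When a
perturbed profile is compared to a control, thresholds come from the
*control's* maxima so collapsed genes report lost domains instead of
renormalising.

`check_pattern` requires, for CORRECT_STAGGERED: T/Bra confined to the
caudal half and disjoint from Pax6/Ngn2; a transition zone (Nkx1.2's
rostral boundary caudal to Ngn2's caudal boundary); Pax6 on caudal to
Ngn2. OVERLAPPING flags stem/differentiation mixing — T/Bra breaking its
confinement, or Nkx1.2 invading Ngn2 territory (the *Cdx4*-null
phenotype). Everything else is OTHER.

Perturbation defaults (the source experiments state no amplitudes):
periodic signal noise 20% at 200 min period; random signal noise 25%
redrawn per 10-min sample and species; *Cdx4* transcriptional noise 25%
redrawn per 10 min **per cell** (transcriptional noise is
cell-autonomous; a tissue-global variant roughly doubles the boundary
shifts). Boolean input replacement collapses the tissue to two signaling
states switching at the common FGF8→RA handover position — stepping each
signal at its own half-max would leave the spatial order intact, which
contradicts the observed loss of transition-zone resolution. Linear
replacement draws the straight line through the endpoint values. *Cdx4*
overexpression is modeled as scale × endogenous + (scale − 1) × maximal
constitutive transcription: a misexpression transgene escapes the
endogenous promoter's spatial control, which is what lets it silence
*Ngn2* in rostral cells where endogenous *Cdx4* is off (pure
multiplication cannot).

## What the simulations do and do not show

The synthetic inputs are the model's own presets; no empirical
measurements enter. Passing tests therefore show that the *postulated*
network wiring with the curated interaction strengths reproduces the
qualitative embryonic phenomenology (regime menu, ordered domains,
canalization), not that the chick embryo uses these rate constants.
Absolute concentrations are arbitrary units; only orderings, boundary
positions and regime labels are interpretable. Known limitations: the
*Cdx4*-null Nkx1.2 expansion reproduces the model's prediction, which
disagrees with dominant-negative experiments in vivo (the construct
actively represses targets rather than removing CDX4); 1-D geometry; no
cell proliferation dynamics beyond the comoving frame; oscillation-period
estimates are only as fine as the 10-min sampling.

Problem sizes used throughout (tests, examples, reproduction script):
251 grid points × 6000 min for signaling (30000 min for the stationarity
check), 251-cell cohorts for TF profiles, 10 seeds for stochastic
verdicts — the same sizes the results are reported at.
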