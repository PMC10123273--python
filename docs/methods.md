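# Methods

## Overview

`txcardio` asks a mechanistic question: given only the changes in mRNA
abundance that a drug induces in a cardiomyocyte, what should happen to that
cell's action potential, Ca²⁺ transient and contraction — and how close does
the drug push the cell to arrhythmia when a second stressor arrives?  The
package answers it in four stages:

1. map drug-vs-vehicle expression fold changes onto the parameters of a
   coupled excitation–contraction model,
2. simulate paced behavior and extract waveform metrics,
3. grade three arrhythmogenic insults (hypokalemia, I_CaL gain, I_Kr block)
   on top of each drug-scaled model and locate the arrhythmia threshold,
4. summarize susceptibility shifts in an Arrhythmic Index (AI) and explain
   them by per-current integrated-charge differences (ΔQ).

## The cell model

The electrophysiology and Ca²⁺-handling core is a ventricular-like human
iPSC-CM formulation in the Paci-model lineage: Hodgkin–Huxley INa (m³hj),
GHK-driving-force I_CaL with voltage- and Ca²⁺-dependent inactivation, the
delayed rectifiers I_Kr/I_Ks, inward rectifier I_K1, transient outward I_to,
funny current I_f, NaK pump, NCX exchanger, sarcolemmal and SERCA Ca²⁺ pumps,
a ten Tusscher-style SR release with a Ca²⁺-dependent inactivation gate, and
fast-buffer approximations for cytosolic and SR Ca²⁺.  Membrane potential is
integrated in volts and time in seconds; currents are per-capacitance (A/F),
so charge integrals are reported in A·ms/F.

Every constant is stored in `src/txcardio/data/baseline_parameters.tsv` with
units and a provenance note, making deviations from the published source
auditable.  Two formulation choices matter and are deliberate:

- **SR release is fully CaSR-dependent.**  A release term that stays active
  at vanishing SR content can integrate the SR Ca²⁺ concentration through
  zero.  The release flux here is
  `G_RyR · gain · (a+c) · CaSR²/(b²+CaSR²) · d · g`, which self-limits as the
  SR empties, and the release-inactivation gate's Ca²⁺ threshold (`g_thresh`,
  0.15 µM) sits inside this cell's systolic Ca²⁺ range so release terminates
  after the transient peak.  The overall gain was calibrated once to a
  physiological iPSC-CM Ca²⁺ transient (diastolic ≈ 0.03 µM, systolic
  ≈ 0.2 µM) and frozen in the parameter file.
- **Ko dependence of K⁺ currents.**  I_Kr and I_K1 conductances carry the
  adult-myocyte convention √(Ko/5.4), and the K⁺ Nernst potential follows Ko
  directly, so hypokalemia simultaneously hyperpolarizes E_K and *reduces*
  repolarizing conductance — the paradoxical AP prolongation that makes low
  [K⁺] arrhythmogenic.

### Contraction

The myofilament module is a reduced troponin→crossbridge→sarcomere-length
model (three states), not a transcription of a published myofilament model:
troponin-C Ca²⁺ occupancy (on-rate `k_trpn_on`, half-activation `ca50_trpn`)
feeds a cooperative permissiveness (Hill exponent `n_xb`) that drives
crossbridge attachment against first-order detachment; attached crossbridges
generate force scaled by `sigma_act` and a linear thick–thin filament overlap
factor, and sarcomere length relaxes viscously against a passive restoring
stiffness.  Troponin-bound Ca²⁺ feeds back on cytosolic Ca²⁺ as an explicit
buffer flux, so contraction is two-way coupled to Ca²⁺ handling.

The three transcriptomically scalable contraction parameters act where their
gene products act: `Trop_Conc` (TNNC1) scales the troponin pool (both its
buffering and its activation drive), `Myosin_scale` (MYH6+MYH7) scales the
maximal crossbridge force, `Actin_scale` (ACTC1) scales thin-filament
availability in the attachment rate.

Because iPSC-CMs reach much lower systolic Ca²⁺ than adult myocytes, the
troponin half-activation was reduced from the adult ≈ 0.6 µM until baseline
fractional shortening fell in the 5–10% band (`ca50_trpn` = 0.12 µM, giving
≈ 6% at the paced steady state); the chosen value lives in the parameter file and is exposed for
override.  This compensation is a documented stand-in — the values the source
models used for the same purpose are not public.

### Numerics

LSODA (stiff-capable) with rtol 1e-6, atol 1e-8 (1e-9 for cytosolic Ca²⁺,
which sits near 3×10⁻⁵ mM), and a 1 ms max step — EAD detection is sensitive
to integration accuracy.  Output is sampled at 1 ms except the first 20 ms
after each stimulus, which are sampled at 0.1 ms so the narrow sodium
transient is resolved in the recorded currents (charge integrals over the AP
then change by < 0.5% when the sampling interval is halved).  Stimulation is
a 5 ms rectangular pulse at 3.39 A/F, 1.5× the 2.26 A/F diastolic threshold
found once by bisection on the default model (`find_stimulus_threshold`) and then
frozen in the protocol defaults.  Simulations start from a packaged steady
state obtained by pacing the default model 100 beats at 1 Hz from the
published-baseline-like resting state (`data/paced_state.tsv`); a failed
integration raises, it never returns a partial trace.

## Expression integration

For each parameter, the scale factor is the ratio of weighted replicate-mean
abundance sums over the parameter's gene set, drug over vehicle, computed
within a cell line.  Weights default to 1 (the gene map ships as a TSV and
accepts per-gene weights).  Genes absent from the matrix drop out of both
sums symmetrically with a warning; a parameter that loses all genes is an
error.  A +0.5 pseudocount on the replicate means is applied only when the
control sum is exactly zero — applying it unconditionally would bias every
factor and break exact identity (drug ≡ vehicle ⇒ factor ≡ 1), which
downstream tests rely on; each application is logged.  Scaled parameters are
`default × factor`, all other model equations unmodified.

## Metrics and classification

APD50/APD90 (and the Ca²⁺ analogues CaD50/CaD90) run from the upstroke to
50%/90% recovery of the beat amplitude with linear interpolation between
samples; the upstroke is the first sample reaching 90% of the beat's maximal
dV/dt, a convention that is deterministic on idealized ramp waveforms where
the maximum itself ties.  Triangulation is the 90/50 ratio (≥ 1 by
construction).  The Ca²⁺ decay time constant comes from a least-squares
mono-exponential fit between 10% of decay below the peak and 5% of amplitude
above diastole; a non-convergent fit yields NaN rather than a fabricated
value.  CaT AUC integrates the diastolic-baseline-subtracted transient per
beat, making it invariant to constant offsets.  Fractional shortening is
(SL_dia − SL_min)/SL_dia per beat; a constant sarcomere length is a valid 0%.

Beat classification works per stimulus interval with configurable detectors
(`ClassifierConfig`): an EAD is a ≥ 2 mV rise above the running local minimum
during repolarization (between 0 and −70 mV, before V first reaches −70);
repolarization failure means V never returns below −60 mV after the beat's
peak before the next stimulus; a spontaneous depolarization is a full
upstroke (dV/dt ≥ 5 V/s) at least 50 ms before a stimulus and outside the
30 ms post-stimulus response window.  When several features coexist the
precedence is EAD, then repolarization failure, then spontaneous.  The
numeric detector thresholds are package choices — the event definitions are
standard, their quantitative detectors are not — and all are exposed in the
run configuration.

Per-metric drug effects are classified as increase (ratio > 1.2), decrease
(ratio < 0.8) or no change, with strict inequalities at the boundaries.
Rankings use log2 of the metric's drug/control ratio (contractile failure
ranks by the fold *reduction* of shortening); Spearman comparisons between
cell lines use the union of the two top-k lists with full-cohort ranks.
The log base and the rank convention are package choices where several
defensible options exist.

## Insults, thresholds, AI, ΔQ

Default grids span none→severe in 10 levels: Ko linear 5.4→2.0 mM
(embedding the experimental 5.4/4.1/2.9/2.5 mM ladder, available as a
preset), G_CaL ×1.0→×3.0, I_Kr block 0→90%.  Insults compose
multiplicatively with drug scaling.  The threshold is the first level whose
last-3-s classification is non-normal under the 120 s / 1 Hz protocol; an
integrator failure at a level counts as arrhythmic there (severe insults can
push the equations past integrability, and skipping such levels would bias
thresholds toward "safe"), while failure with no insult is an error.

The Arrhythmic Index is the weighted mean over insults of
(t_ctrl − t_drug)/L with the never-arrhythmic sentinel mapped to L+1
(unit weights by default).  It is zero when thresholds match, positive when
the drug brings arrhythmia to milder insults, and exactly antisymmetric under
swapping drug and control.  This normalization is a declared stand-in (the
index is defined conceptually as a weighted threshold average, but its exact
transformation is not public); it is isolated in one function
(`arrhythmic_index`) so it can be swapped.

ΔQ integrates each of the 8 analyzed currents (I_K1, I_to, I_Kr, I_Ks,
I_CaL, I_NaK, I_Na, I_NCX) over the last complete action potential — from
the upstroke to 90% repolarization or the next stimulus, whichever comes
first, a window that stays well defined when repolarization fails — using
trapezoidal quadrature with interpolated endpoints.  NCX, which reverses
during the AP, is integrated separately over its outward and inward
subintervals (the two components sum to the total exactly).  ΔQ < 0 (less
outward or more inward charge) opposes repolarization and is labelled
proarrhythmic.  Mechanism reports evaluate ΔQ at the level immediately below
the drug's threshold — the state in which the next increment of insult tips
the cell over — and rank currents by |ΔQ|.

## Synthetic data

The generator emulates the consumed study design: two cell lines, a 26-drug
panel plus vehicle, three replicates.  Per-gene baselines are drawn once
from a broad log-uniform range (10–1000, CPM-like) so sum-based factors see
unequal gene contributions; planted effects are per-(line, drug, gene) fold
changes; replicate noise is multiplicative log-normal (σ = 0.1 by default),
the simplest positive-valued replicate model for normalized data.  A planted
truth table lists the parameter scale factors implied analytically by the
folds.  What the generator does *not* emulate: count-level sampling noise
(UMI/negative-binomial), library-size or composition artifacts, correlated
gene programs, or any genes beyond the mapped set plus inert decoys.  Tests
passing on this generator therefore validate the pipeline's arithmetic and
its simulation logic, not robustness to real RNA-seq artifacts — a normalized
matrix of comparable quality is assumed upstream.

The divergent preset plants opposite-direction folds on KCNJ2 (I_K1) and
KCND3 (I_to) in the two lines, with the targeted genes' baselines pinned so
they dominate their parameter sums; reduced repolarization reserve lowers the
insult thresholds in one line while the mirrored upregulation raises them in
the other, producing opposite-signed AI by construction.

## Problem sizes and determinism

The default protocol is 120 s at 1 Hz with the last 3 s analyzed, for every
simulation including threshold scans (a full 26-drug × 2-line battery is a
few thousand 120 s simulations; the `--drugs`/`--cell-lines` options subset
it).  Simulations are deterministic given identical inputs and solver
settings; identical parameter sets are memoized within a run
(`SimulationCache`, keyed by a content hash of the parameter vector and the
protocol).  All randomness in the synthetic generator flows from one integer
seed.  The acceptance script (`scripts/acceptance.py`) uses 25 generator
seeds for the noisy-recovery summary and the full default protocol for every
simulation it reports.

## Known limitations

- The electrophysiology constants were transcribed from the published model
  lineage without access to a machine-readable source; the parameter file is
  the ground truth for what this package computes, and the SR release gain
  and gate threshold are calibrated rather than inherited.
- The myofilament module is deliberately reduced; it reproduces twitch
  magnitude and the three transcriptomic couplings, not crossbridge-cycling
  kinetics, force–velocity behavior or length-dependent activation in detail.
- mRNA abundance is taken as a proxy for functional protein density with no
  translation/trafficking lag; 48 h drug exposure is assumed long enough for
  transcript changes to manifest functionally.
- Single-cell only: no tissue coupling, no atrial/nodal variants, no
  cross-phenotype translation.
- The AI weights and transformation are the package's own convention; rank
  orders are comparable within this package, not against other indices.
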