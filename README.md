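# txcardio

Transcriptomics-informed prediction of drug-induced cardiotoxicity in human
iPSC-derived cardiomyocytes (iPSC-CMs).

Many kinase-inhibitor cancer drugs perturb cardiac gene expression at
clinically relevant concentrations without causing overt toxicity in a dish.
`txcardio` turns such expression changes into mechanistic, testable
predictions: drug-induced mRNA fold changes scale the parameters of a coupled
cardiomyocyte electrophysiology / Ca²⁺-handling / contraction model, and
simulations then predict how each drug alters action potentials (AP), Ca²⁺
transients (CaT) and sarcomere shortening — and, critically, how it shifts
the cell's susceptibility to secondary arrhythmogenic insults
("two-hit" risk).

The package is aimed at computational cardiac electrophysiologists and
systems pharmacologists who have a normalized expression matrix (drug vs
vehicle, per cell line) and want per-drug, per-individual risk readouts.

## The model and the pipeline

**Scaling.** For each model parameter *p* with mapped genes *g* (weights
*w_g*, default 1), the drug scale factor within a cell line is the ratio of
weighted replicate-mean abundances

&nbsp;&nbsp;&nbsp;&nbsp;SF = Σ w_g·Ȳ_g,drug / Σ w_g·Ȳ_g,vehicle,&nbsp;&nbsp;&nbsp;&nbsp;p_drug = p_default × SF.

Fifteen parameters are scalable — the conductances/permeabilities G_Na,
G_CaL, G_RyR, G_to, G_Ks, G_Kr, G_K1, the pump/exchanger magnitudes P_NaK,
I_up (SERCA), G_pCa, K_NaCa, the funny current G_f, and three contraction
couplings (troponin-C pool, maximal myosin crossbridge force, actin
thin-filament availability). The default gene map (e.g. G_Kr ← KCNH2,
G_K1 ← KCNJ2+KCNJ12, I_up ← ATP2A2, Myosin ← MYH6+MYH7) ships as a TSV.

**Simulation.** A ventricular-like human iPSC-CM electrophysiology/Ca²⁺
model (Hodgkin–Huxley gating, GHK-type I_CaL, SR release/uptake, NCX, NaK)
coupled to a reduced troponin→crossbridge→sarcomere-length contraction
module, paced at 1 Hz for 120 s with a stiff solver; the last 3 s are
analyzed for APD50/90, triangulation (APD90/APD50), CaT amplitude, CaD50/90,
decay time constant, CaT area under the curve, and fractional shortening.

**Risk.** Three graded insults — hypokalemia (extracellular K⁺ 5.4→2.0 mM),
L-type Ca²⁺ current gain (×1→×3), and I_Kr block (0→90%) — are applied over
10 levels to each drug-scaled model. The first level whose last-3-s waveform
shows an arrhythmic event (early afterdepolarization, repolarization
failure, or spontaneous pre-stimulus depolarization) is that model's
threshold. The **Arrhythmic Index** AI = mean over insults of
(t_ctrl − t_drug)/L is positive when the drug makes the cell arrhythmic at
milder insults. Mechanisms are decomposed by **ΔQ**: the drug−control
difference of each ionic current integrated over one AP (8 currents; NCX
split into inward/outward); negative ΔQ opposes repolarization and is
proarrhythmic.

See `docs/methods.md` for assumptions, parameter provenance, numerical
choices, and what the synthetic generator does and does not emulate.

## Worked example

Generate a synthetic two-cell-line dataset in which one drug ("TRA")
downregulates the K⁺-current genes KCNJ2 and KCND3 in cell line A and
upregulates them in line B, then run the insult battery for that drug:

```bash
txcardio synth --seed 1 --out demo --divergent
txcardio insults --expression demo/expression.tsv \
    --annotations demo/annotations.tsv --drugs TRA --out demo_insults
```

The `insults` command prints the Arrhythmic Index table (also written to
`demo_insults/arrhythmic_index.tsv`):

```
cell_line    drug  hypokalemia  ICaL_increase  IKr_block        AI
        A     TRA          0.5            0.9        0.5  0.633333
        A vehicle          0.0            0.0        0.0  0.000000
        B     TRA         -0.1            0.0        0.0 -0.033333
        B vehicle          0.0            0.0        0.0  0.000000
```

Reading: in cell line A the vehicle-treated model first becomes arrhythmic
at hypokalemia level 10 (2.0 mM K⁺) and tolerates the full I_CaL and I_Kr
ladders, while the drug-scaled model develops early afterdepolarizations at
hypokalemia level 5, I_CaL level 2 and I_Kr-block level 6 — AI = +0.63,
strongly susceptible. In line B the same drug *raises* the hypokalemia
threshold past the end of the ladder (AI < 0, protective).
`demo_insults/delta_q.tsv` attributes the difference: in line A the drug
removes outward charge through I_K1 and I_to (negative, proarrhythmic ΔQ),
in line B it adds it.

The baseline model itself:

```bash
txcardio baseline --out demo_baseline
```

prints (among the other metrics) APD90 = 254.7 ms, AP triangulation = 1.36,
CaT decay tau = 118.4 ms and fractional shortening = 5.8% — typical
ventricular-like iPSC-CM values at 1 Hz.

## Layout

```
src/txcardio/
  model.py       coupled EP/Ca2+/contraction ODE model (numba-jitted RHS)
  expression.py  expression matrix, gene map, scale factors
  metrics.py     AP/CaT/contraction metrics, beat classification
  insults.py     insult grids, thresholds, Arrhythmic Index, ΔQ
  synthetic.py   seeded synthetic expression generator + planted truth
  pipeline.py    end-to-end stages behind the CLI
  cli.py         txcardio baseline|synth|integrate|insults|mechanism
  data/          versioned model constants, gene map, drug roster,
                 packaged paced steady state
```
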