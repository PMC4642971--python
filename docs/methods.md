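# Methods

`il4redox` models how reactive oxygen species (ROS) — chiefly hydrogen
peroxide acting as a second messenger — regulate IL-4/JAK/STAT6
signaling in lymphocytes. All models are systems of ordinary
differential equations with elementary mass-action kinetics; amounts
are in arbitrary units (au), time in minutes. This note records the
modeling assumptions, the parameters that matter, and the design
choices made where the design was genuinely open.

## The reduced model library

The pathway is decomposed into a core — ligand-driven activation of a
lumped receptor complex (receptor chains plus constitutively bound
JAKs), STAT6 phosphorylation by the active complex, ROS production by
the active complex with first-order clearance, and generic
protein-tyrosine-phosphatase (PTP) dephosphorylation in cytosol and
nucleus — plus four optional regulatory mechanisms:

1. **PTP oxidation** (`P`): `P_c + ROS -> Pox`, with first-order
   re-reduction. The oxidation step consumes ROS, so an abundant
   reduced phosphatase pool buffers ROS until it is titrated away.
2. **Receptor/JAK oxidation** (`J`): oxidation of the receptor-JAK
   complex blocks its *activation* (`R + ROS -> Rox`, `Rox -> R`).
   Oxidation is written against the inactive pool: in this reduced
   abstraction the redox lesion prevents the kinase-dependent assembly
   of an active complex rather than erasing complexes already active.
3. **ROS-driven phosphatase relocation** (`S`): ROS catalyzes
   nucleus-to-cytosol transport of the nuclear phosphatase
   (mass action in `ROS * P_n`), with slow constitutive return.
4. **Phospho-dependent STAT6 cycling** (`D`): when set, only
   phosphorylated STAT6 enters the nucleus and only dephosphorylated
   STAT6 leaves; when unset, both forms shuttle bidirectionally.

All 2^4 = 16 flag combinations define the library. Sequential steps
(receptor-complex assembly, pSTAT6 dimerization) are collapsed into
single reactions, enzymes are written without intermediate complexes,
and the nuclear compartment carries no oxidation chemistry (it is the
more reducing environment). Reduced models have no SOCS feedback or
STAT6 turnover; those belong to the detailed model.

### Why two pSTAT6 peaks select for PTP oxidation + dependent cycling

At the calibrated centers, a two-peak total-pSTAT6 trace arises from
two coupled slow processes: (i) slow ROS production is absorbed by the
reduced phosphatase pool until the pool is titrated, at which point
dephosphorylation switches off tens of minutes after stimulation; and
(ii) phospho-dependent cycling traps STAT6 in the nucleus as
unphosphorylatable stock, so the late burst of phosphorylation burns
the remaining cytosolic substrate and then declines — producing a
genuine second local maximum. Remove either ingredient and the trace
plateaus or stays single-peaked; this is the mechanistic content of
the screen's outcome.

### Monte-Carlo screen

Rate constants are sampled independently log-uniformly over one decade
total (center / sqrt(10) to center * sqrt(10)); the default ensemble is
50,000 draws per topology and the scaled runs in the test suite and
acceptance script use 5,000. Each draw is integrated over 0–120 min
with a compiled Dormand–Prince 5(4) integrator at a 0.5-min reporting
grid, and the total-pSTAT6 trace is classified by its number of
*distinct* interior local maxima: two maxima count as distinct only if
the valley between them lies below both by at least 2% of the trace
range (boundary extrema excluded; the 2% prominence guards against
solver ripple). A topology passes when its two-peak fraction strictly
exceeds 0.1%. Integration failures are logged and scored as
non-two-peak; they never abort an ensemble.

**Center calibration.** The screening workflow tunes every model to
the same coarse response template (fast rise within minutes, slow
relaxation over two hours) before sampling. Here one shared
center vector is used for all topologies, with a single override block
for the eight phosphorylation-independent-cycling topologies
(symmetric nuclear import/export of both STAT6 forms, so their resting
nuclear/cytosolic distribution is balanced, plus a weaker shuttle).
The optional modules are deliberately parameterized as weak,
fast-relaxing perturbations at the center: receptor oxidation is
slower to install and faster to reverse than PTP oxidation (the PTP
active-site cysteine's low pKa makes it unusually reactive), and
phosphatase translocation is slow relative to catalysis. Under this
calibration the screen reproduces a characteristic ordering: the
PTP-oxidation + dependent-cycling topology yields the most two-peak
draws (~13% at the shipped centers), adding receptor oxidation or
shuttling reduces the count, and every independent-cycling topology
fails the 0.1% threshold. One dependent-cycling topology without PTP
oxidation (shuttle + dependent cycling) sits marginally at ~0.2%. The
ordering is a property of the shipped calibration, not a
parameter-free fact: the screen explores a fixed box around the
centers, and a different calibration could move boundary cases.

**Feature matching.** Two-peak traces contribute (h2/h1, t2−t1,
final/h1) feature triples. Bivariate Gaussian-kernel densities
(`scipy.stats.gaussian_kde`, Scott's rule) over (ratio of heights ×
separation) and (ratio of heights × final/h1) are evaluated at the
features of the measured curve — extracted from a generalized
cross-validation smoothing spline of the mean time course — normalized
by each density's maximum over its own cloud, and averaged.

## ROS input

Redox-sensitive dye (CM-H2DCFDA) fluorescence is cumulative, so the
instantaneous oxidation trend is the time derivative of a Hill curve
`offset + fmax * t^n / (k^n + t^n)` fitted to the cumulative signal
(multistart least squares over Hill exponents 1–6 and half-times
0.1–1 × the observation span; the offset is excluded from the
derivative). The model input is `u(t) = a + b * dHill/dt`, with
baseline `a` and gain `b` in model ROS units; exogenous peroxide adds
`amplitude * exp(-decay * t)` with a default decay of 0.15/min, so a
bolus substantially dissipates within ~30 min (the decay constant is a
configuration default, not a measured value). The default IL-4 input
peaks at 100 ROS units near 20 min over a baseline of 4 units; the
DPI-pretreatment input has baseline 0.6 and a transient peaking at
~2.5 units, reflecting near-complete suppression of stimulus-induced
oxidation by the flavoprotein inhibitor. One ROS unit is nominally
1 nM H2O2; this convention is used only for reporting (under it the
default PTP oxidation constant 0.12 /(unit·min) corresponds to
~2×10^6 M⁻¹s⁻¹).

## The detailed systems model

Species: clamped IL-4, inactive/active receptor complex, SOCS and the
receptor·SOCS complex, two phosphatases P1 (acts on cytosolic pSTAT6)
and P2 (acts on the active receptor) with oxidized forms, cytosolic
and nuclear STAT6/pSTAT6, and explicit enzyme–substrate complexes for
the phosphorylation and dephosphorylation reactions (two-step mass
action: irreversible binding, then catalysis). SOCS production is the
single non-mass-action rate, `v_socs * S* / (km_socs + S*)` with `S*`
the total phosphorylated STAT6, modeling saturation of transcription;
SOCS binds the active receptor reversibly and makes it catalytically
inert, and P2-mediated receptor dephosphorylation releases SOCS.
STAT6 has a constant synthesis source and proteasomal degradation of
cytosolic pSTAT6 (MG132-sensitive), plus a slow constitutive
first-order turnover of unphosphorylated cytosolic STAT6
(0.001/min). The latter is needed for a well-posed resting state whose
phospho-balance responds to baseline ROS: with pSTAT6 degradation as
the only sink, the steady state pins basal pSTAT6 at
synthesis/degradation regardless of redox tone, contradicting the
observed ROS-dependence of baseline phosphorylation. Nuclear pSTAT6
is dephosphorylated first order (a lumped, non-oxidizable nuclear
phosphatase activity), and a small ligand-independent receptor
activation flux (0.00292/min) carries basal ROS into basal pSTAT6.

ROS enters as the measured-input profile `u(t)` multiplying the
oxidation fluxes `P1 -> P1ox` and `P2 -> P2ox` (cytosol only);
re-reduction is first order (constant cellular reducing capacity).

Conditions map onto the model as: CHX zeroes protein-synthesis fluxes
(STAT6 source and SOCS production); MG132 zeroes proteasomal pSTAT6
degradation; DPI swaps in the DPI-fit ROS profile; exogenous H2O2 adds
a 100-unit bolus decaying at 0.15/min. Every simulation starts from a
steady state pre-equilibrated at the condition's baseline ROS with no
ligand (long-time integration, horizon doubling from 10^4 min,
convergence when the RHS norm falls below 10^-9 relative); inhibitors
and ligand are applied at t = 0.

**Default parameters.** The shipped parameter set was calibrated (by
randomized search followed by local refinement) to satisfy the
qualitative phenotypes jointly: the IL-4 pSTAT6 trace shows exactly
two distinct peaks (t1 = 10 min, t2 = 40 min, h2/h1 ≈ 0.72); DPI
pretreatment lowers baseline phosphorylation and caps the peak at
~11% of the IL-4 peak; an H2O2 bolus with IL-4 raises the peak ~2.4x;
the same bolus alone moves pSTAT6 by <2% of the IL-4 rise; basal
pSTAT6 increases monotonically with baseline ROS; total phosphatase
oxidation peaks at ~20 min; and SOCS3 is induced ~2000-fold over its
basal trace. The crucial structural features of this regime are (i)
phosphatase capacity large relative to kinase flux, so the fully
reduced phosphatases crush signaling (hence DPI attenuation), and
(ii) re-reduction slow enough (0.154/min) that oxidation integrates
the ROS transient, placing the phosphatase-activity minimum — and the
second pSTAT6 peak — after the 20-min ROS maximum.

Integration uses LSODA with rtol 10^-6 / atol 10^-9 and a 0.5-min
reporting grid over 0–120 min, matching the experimental sampling
density. States are clipped at zero inside flux evaluation only;
conservation tests verify moiety totals (STAT6, P1, P2, receptor)
drift < 10^-6 relative over 120 min with turnover off.

## Fitting

The error function is

    e = sum_ijt ((y_ij(t) − e_ij(t)) / (e_ij(t) · σ_ij(t)))²

over conditions i, species j and sampled times t, where y is the
affinely scaled simulated observable, e the measured mean and σ its
standard error; observation scalings `y = α_x + β_x · x` are
per-species, condition-independent, and profiled out at every
evaluation by weighted linear least squares (the exact inner optimum
of the same objective, equivalent to fitting them as free parameters).
Training series are pSTAT6 under {IL-4, +MG132, +CHX}, total STAT6
under {IL-4, +MG132}, and SOCS3 under {IL-4, +CHX}; the redox
perturbations (DPI, exogenous H2O2) are held out for validation.

The optimizer is a (μ+λ) evolutionary strategy in log10 parameter
space: Gaussian mutation (default step 0.15 decades), elitist
selection of μ = 8 parents from λ = 40 offspring plus parents, and
reflecting bounds. When the best objective stagnates for 15
generations the mutation step is magnified 10× for 3 generations
(hyper-mutation) to escape local basins. Failed integrations receive
a penalty of 10× the worst feasible objective seen so far, keeping
selection well-defined without infinities. The best-ever objective is
non-increasing by construction.

The model is sloppy: many rate-constant combinations fit the training
data equally well, and prolonged fitting can chase replicate noise
into parameter drift that degrades extrapolation. The scaled
fit-and-predict experiments therefore use a modest budget (population
16, 40 generations, bounds ±0.3 decades around the perturbed start),
which recovers composite predictions — peak height and both peak
times — even when individual rate constants are not identifiable.
Held-out DPI and H2O2 pSTAT6 curves are typically predicted within
±3 SEM at 70–100% of time points across random draws of the noise and
of the perturbed start; the fixed-configuration regression test
requires at least 80% on both held-out conditions.

## Synthetic data

The generator simulates the detailed model at the shipped truth
parameters across {untreated, IL-4, IL-4+DPI, IL-4+H2O2, IL-4+CHX,
IL-4+MG132}, scales observables per species, and emulates replicate
flow-cytometry measurements: three replicates per point (the assay's typical
N), independent multiplicative Gaussian noise with a 5% coefficient of
variation (MFIs are positive and scale-dependent), reported as mean ±
SEM on the grid {0, 5, 10, 15, 20, 25, 30, 45, 60, 90, 120} min.
Scalings are anchored so the untreated readout sits at 1.0, matching
MFIs normalized by the untreated sample
(`(MFI_sample − MFI_bk)/(MFI_untreat − MFI_bk)`); consistent raw MFI
triples are emitted alongside. The noiseless IL-4 pSTAT6 truth must
show exactly two distinct peaks with t1 ≤ 25 < t2 ≤ 120 min, otherwise
generation fails loudly. Cumulative dye curves are the time integral
of each condition's ROS truth with a shared fluorescence gain, so the
IL-4 curve reproduces its generating Hill shape up to a small linear
baseline-oxidation drift.

What the generator does *not* emulate: single-cell fluorescence
distributions, cytometer artifacts (spillover, compensation),
day-to-day batch effects, or any mechanism absent from the generating
model. Passing the recovery and prediction tests therefore
demonstrates internal consistency of the pipeline under the stated
noise model, not correctness of the biology on real data.

## Problem sizes

The shipped analyses use 5,000 Monte-Carlo draws per topology for the
screen (the full-scale default is 50,000) and an evolutionary-strategy
budget of ~650 objective evaluations for the fit-and-predict loop;
both are the package's default desk-scale settings and can be raised
through the corresponding arguments.

## Known limitations

- The screen's topology ordering depends on the center calibration and
  the one-decade sampling box; it reproduces a characteristic pattern,
  not a calibration-free theorem.
- Under the shared-center calibration the *quantitative* feature-match
  stage does not separate the four passing topologies: their two-peak
  feature clouds give statistically indistinguishable match scores
  against the reference curve (~0.45–0.6 across seeds). Selection
  power here comes from the qualitative two-peak counts.
- Reduced models omit SOCS feedback and STAT6 turnover, so their late
  down-regulation relies on nuclear trapping alone.
- Nuclear and cytosolic compartments are treated as equal effective
  volumes (amounts, not concentrations).
- ROS units are arbitrary; the 1 unit ≈ 1 nM convention is a reporting
  convenience only.
- The DPI input profile's transient amplitude (~2.5 units) is a
  calibration choice consistent with strong suppression of dye
  oxidation; no absolute measurement pins it.
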