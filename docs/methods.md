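# Methods

## The model

The package simulates the circadian clock of *Synechococcus elongatus*
as two coupled oscillatory layers.

**Post-translational oscillator (PTO).** KaiC monomer-equivalents are
tracked in three pools — free hexamers (CH), KaiB-bound complexes (CB)
and free monomers (CP) — each resolved into the four phospho-states U
(unphosphorylated), T (Thr-432~P), D (doubly phosphorylated) and S
(Ser-431~P).  Transitions are strictly cyclic, U→T→D→S→U.  In the
hexamer pool the two phosphorylation steps and the S→U step carry
KaiA-dependent rate increments proportional to the free-KaiA saturation
factor `a/(K_half + a)`.  Free KaiA dimer concentration `a` is an
algebraic quantity obtained at each evaluation from the monotone mass
balance

    a + H·a/(K_dim + a) + S_B·a/(K_seq + a) = A/2,

where `H` is the hexamer concentration (CH total / 6), `S_B` the
S-state monomer-equivalents in KaiB-bound complexes (one sequestered
dimer per S monomer-equivalent; two KaiA monomers = one dimer per
binding site) and `A` total KaiA.  KaiB binds hexamers
composition-gated (weights favouring D/S-rich material) and complexes
dephosphorylate internally; S-state complexes are the KaiA
sequestrators that flip the system into its dephosphorylation phase.
Monomer exchange between hexamers and the free-monomer pool (rates
`c_U`, `c_D`, `c_S`; no T insertion) synchronises the hexamer
population and provides the dephosphorylation route for T-state hexamer
sites once KaiA is sequestered.  Monomers assemble into hexamers with a
fifth-power saturation in the monomer-pool total (a monomer joins only
when five partners are available, Michaelis constant `K_P`); hexamers
and complexes decompose back at `k_dis`.  New KaiC is synthesised into
monomeric U in proportion to kaiBC mRNA (`k_2bc`); all twelve KaiC
components degrade at a common `k_4bc`.

**Transcription/translation loop (TTFL).** kaiA mRNA is transcribed at
a constant rate and kaiBC mRNA at a basal rate modulated by two
thermodynamic fold-change factors: simple activation
`(1 + λ⁺x/K⁺)/(1 + x/K⁺)` by a phospho-species `x` of the hexamer pool
and simple repression `(1 + λ⁻y/K⁻)/(1 + y/K⁻)` by a phospho-species
`y` of the hexamer or complex pool, multiplied on the basal rate.  All
clock-output biochemistry between KaiC and the promoter is deliberately
lumped into the two fold-changes.  mRNAs decay at `k_3`, KaiA protein
is translated at `k_2` and decays at `k_4`.  This yields 15 ODEs: 12
KaiC components, two mRNAs and total KaiA.

**Feedback variants.** A `FeedbackSpec` names which phospho-species
activates (always from the hexamer pool: U, T, D, S, TD or P = T+D+S)
and which represses (hexamer or complex pool: U, T, D, S or P).  The
candidate table enumerates 16 hexamer-repressor wirings (Group I) and
16 complex-repressor wirings (Group II); three supplementary variants
with a combined S/U complex-pool repressor are available behind a flag.

## Calibration of the default parameter set

No rate constants for this system are shipped with any public data
source the package could read, so the defaults in
`kaiclock.params.default_pto()` / `default_ttfl()` are **calibrated
values, not measurements**.  They were obtained in three stages:

1. *Linear stability*: the 15-dimensional Jacobian at the coexistence
   fixed point was scanned for parameter directions that destabilise
   the leading oscillatory eigenpair.  Two ingredients proved necessary
   for a limit cycle with the strictly cyclic four-state scheme: the
   hexamer↔monomer exchange route (without it, T-state material has no
   dephosphorylation path once KaiA is gone and the loop is
   over-damped) and a strong KaiA-dependent S→U increment (free KaiA
   suppresses its own sequestrator, which makes the sequestration
   switch hysteretic).
2. *Period and phase shaping*: randomized log-normal search plus local
   refinement for a sustained cycle with ≈25 h period, a
   phosphorylated fraction swinging around one half, and the canonical
   phase order (U-KaiC peak in the early subjective day, kaiBC mRNA
   mid-day, phosphorylated KaiC early night).
3. *Mutant phenotypes*: basal phosphorylation rates were lowered until
   a simulated kaiA knockout relaxes to <5 % phosphorylated KaiC
   (KaiC without KaiA is a net autophosphatase), and the
   activation/repression constants placed so that knockout lowers
   kaiBC mRNA in U-repressor wirings but raises it when the repressor
   vanishes with the phosphorylation cycle.

The kaiBC transcription and KaiC translation rates are normalised so
the wild-type mean kaiBC mRNA is 1 (an exact invariance: scaling
`k_1bc` by f and `k_2bc` by 1/f leaves the KaiC dynamics unchanged).

## Conventions

**Dawn anchor.** A free-running constant-light (LL) simulation has no
external dawn, so absolute peak phases are a convention: after burn-in,
the recording window is anchored so that the UKaiC-fraction peak falls
1 h after the window start ("dawn").  This encodes the observation that
cells at dawn are maximally unphosphorylated; only the *relative*
phases (mRNA−U, P−U lags) are genuine model properties.

**Wild-type phenotype windows** (closed intervals): sustained rhythm,
period 24–26 h, kaiBC mRNA peak 6–13 h, UKaiC peak 0–7 h, PKaiC peak
7–15 h after dawn.  Sustained means the last/first peak-to-trough
amplitude ratio in the window is ≥ 0.95; below 0.05 counts as
arrhythmic.  The knockout floor for "~0 % phosphorylated" is 5 %.

**Perturbation protocols.** Knockout and overexpression rescale the
kaiA transcription rate or the KaiC translation rate from a trigger
time onward (continuous state at the switch).  The default trigger is
the first local minimum of kaiBC mRNA after dawn, matching how such
experiments are staged.

## Fitting and screening

The cost of a TTFL parameter set against an observed table is the
equally weighted sum of squared residuals of simulated kaiBC mRNA
(standardised to mean 1 over the comparison points), UKaiC fraction and
PKaiC fraction at the data times; integration failures score a large
finite penalty.  Optimisation is budgeted simulated annealing in
log10-parameter space inside a ±2-decade box (fold-changes clipped to
their validity ranges), geometric cooling, one coordinate perturbed per
move, repeated from three starts (start 0 at the reference values,
further starts seeded random points); everything is deterministic given
the seed.  PTO rates are held fixed during fitting.  Among the starts,
selection prefers fits whose own simulation passes the wild-type
phenotype windows, then lowest cost, then lowest start index.

The screen applies fit → phenotype classification to each of the 32
variants; good fits proceed to the mutant battery in funnel order:
(1) kaiA knockout (pass: rhythm abolished, mean kaiBC mRNA below the
wild-type mean, terminal phosphorylation at the floor), (2) kaiA
overexpression (pass: rhythm lost within the 10-fold scan grid *and*
kaiBC mRNA elevated at moderate overexpression), (3) KaiC
overexpression (pass: rhythm lost and mean kaiBC mRNA below 0.8× the
wild-type mean — "suppressed" needs a clear margin, otherwise variants
whose positive limb outweighs the negative one slip through on
rounding).

## Synthetic data

`generate_observed` emulates digitised Northern/Western blot series:
fundamental-plus-harmonic waveforms (harmonic ratio 0.2 — blot traces
are not sinusoids), 25 h period, mRNA standardised to mean 1 with
relative amplitude 0.6, U/P fractions about 0.5 with amplitude 0.3 and
nominal peaks at 3 h and 11 h, sampled every 4 h over 48 h, 5 %
relative Gaussian noise, clipped to valid ranges.  The U and P
channels are built from independent waveforms and renormalised to sum
exactly to 1, which shifts realised peaks up to ~1 h from nominal.
What these tables do *not* emulate: blot saturation and background
artefacts, correlated densitometry errors, day-to-day amplitude drift
and the unknown true sampling times of the original experiments — so
tests passing on synthetic tables show pipeline correctness, not that
the model explains any particular laboratory data set.
`generate_from_model` samples a forward simulation on the same grid for
parameter-recovery tests with known ground truth.

## Numerical choices

LSODA (stiff-capable) with rtol 1e-8 / atol 1e-10 for reference runs,
relaxed to 1e-6/1e-9 inside fitting loops; dense output every 0.1 h.
States are clipped to zero inside the right-hand side so the integrator
may probe slightly negative values without leaving the model's domain;
trajectories stay above −1e-9.  The free-KaiA balance is solved by
safeguarded Newton iteration (bracketed in [0, A/2]); the vectorised
reference implementation and the scalar hot-path transcription are
cross-checked to ~1e-12 in the test suite.  Burn-in is 240 h (≈10
cycles) and recording 120 h by default; fitting uses 160 h/60 h and the
screen 200 h/100 h to keep whole-table runs to minutes — window sizes
are stated with each result and classification windows always contain
at least three cycles.  Peak detection uses prominence-filtered local
maxima (20 % of span for period/phase estimation) with three-point
quadratic refinement; peak phases are averaged circularly.

## Known limitations

- The four-state cyclic scheme needs a strong KaiA-stimulated S→U
  hexamer clearance to oscillate.  Under KaiA overexpression this
  clearance empties the free S-hexamer pool, so the P-activator
  (T+D+S) and TD-activator variants become nearly indistinguishable
  and both lose rhythm at ~2–4-fold KaiA excess.  The experimental
  literature distinguishes these variants by a much higher
  (~17-fold) arrhythmicity threshold for the P-activator; this model
  family cannot reproduce that separation.
- With saturating activation the four U-repressor variants (T+, D+,
  TD+, P+ against U−) are dynamically nearly identical, so the
  selection funnel retains the U-repressor family rather than the
  TD+/U− wiring uniquely.  The phenotype windows used here are a
  coarser instrument than the judgement calls made when such screens
  are done against real data.
- KaiB expression dynamics are deliberately absent (KaiB variation has
  little effect on dephosphorylation at 30 °C); output-pathway
  components (SasA, RpaA/B, CikA, LabA) are lumped into the two
  fold-changes; no light–dark entrainment is modelled (LL only).
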