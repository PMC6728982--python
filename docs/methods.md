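# Methods

## Problem and model

Randomized trials collect many *non-systematic* adverse events (AEs):
harms reported spontaneously by participants rather than ascertained with
a uniform instrument. A complete listing (as in a clinical study report,
CSR) typically contains hundreds of distinct AE *types*; public reports of
the same trial usually contain far fewer, filtered by a **selection
criterion**. This package formalizes such criteria as a triple:

* **numerical threshold** `t` — a minimum incidence proportion
  (e.g. ≥ 2%);
* **participant-group scope** — whose incidence is thresholded:
  `any` (any single arm), `active` (the pooled test-intervention arm(s)),
  or `all` (all arms combined);
* **difference rule** — optionally, the active-arm incidence must be
  strictly higher than the comparator's (`higher`), or at least `r` times
  it (`ratio>=r`, observed value r = 2).

A term with per-arm counts `c_a` out of arm sizes `n_a` is reported under
criterion `(t, scope, diff)` iff the scoped proportion meets the
threshold *and* the difference rule holds, where the active and comparator
proportions used by difference rules are the pooled values
`Σ_active c_a / Σ_active n_a` and `Σ_comparator c_a / Σ_comparator n_a`.

Crossing the component values observed across trial sources — thresholds
{1, 2, 3, 5, 10}%, all three scopes, and difference rules
{none, higher, ratio ≥ 2} — gives the 45-criterion grid used throughout.

## Numerical choices

* **Exact rational comparison.** Proportions are `Fraction`s; `20/1000 ≥
  2/100` is decided exactly. Two report-author conventions are available
  as switches, both off by default: `rounded_percents` (round-half-up each
  proportion to a whole percent before comparing, as an author working
  from a printed table might) and `strict_thresholds` (use `>` instead of
  `≥`; every criterion quoted from real sources reads "≥").
* **Thresholds are inclusive** (`≥`), `higher` is strict (a tie carries no
  signal).
* **Zero-comparator ratio convention:** active incidence > 0 against
  comparator 0 passes the ratio clause ("at least twice as frequent" is
  vacuously exceeded); 0 against 0 fails it.
* **Dose arms.** "Participants receiving the test intervention" pools all
  arms flagged active; `active_arm=` restricts to one named arm, since
  sources describing multi-dose trials do not state which convention they
  used. `all` includes the placebo arm.
* **Denominators.** Arm sizes are caller-supplied safety-population
  sizes; the percent-reported denominator is the number of distinct AE
  types stored in the table (types with ≥ 1 affected participant).
* **Degenerate inputs.** An empty table is valid (0 types, percent
  reported defined as 0); terms never observed are not stored, so a
  0-vs-0 ratio contrast cannot arise on exact proportions (it can under
  `rounded_percents`, and fails there).

## Synthetic data generator

`SyntheticConfig` emulates a non-systematic AE corpus for one drug
programme: `n_terms` latent AE types with background (comparator-arm)
incidence drawn from a long-tailed law — default log₁₀-uniform on
[5×10⁻⁴, 0.2], i.e. equal mass per decade from rare to very common — of
which a fraction (`elevated_fraction`, default 0.1) is elevated in the
active arm(s) by a common risk ratio (default 2). Per arm and term,
counts are independent binomials; types with zero affected participants
anywhere are dropped, mirroring that CSR listings contain only observed
events. Defaults of 200 participants per arm and 300 latent types give
stored listings of ~230–250 types, the order of magnitude of a real CSR
AE table. Arm/term independence is deliberate: no within-participant
correlation across AE types, no ascertainment differences between arms,
no visit schedule or dropout. Passing tests therefore show that the
*selection logic* behaves as specified, not that the generator reproduces
every feature of real pharmacovigilance data.

Seeding: each trial's counts come from a dedicated
`numpy.random.SeedSequence(master_seed, spawn_key=(1, replicate, index))`
stream, and the shared truth from `spawn_key=(0,)`, so adding trials or
replicates never perturbs earlier draws. The elevated set is the first
`⌈elevated_fraction·n_terms⌉` types in label order; labels carry no other
meaning, so this is equivalent to a random subset and keeps ground truth
reproducible.

## Meta-analysis bias experiment

For k trials sharing one truth, each criterion censors every trial to its
"journal-article view". Per AE type the pooled risk ratio is computed
twice with the fixed-effect Mantel–Haenszel estimator

    RR_MH = [Σᵢ aᵢ n0ᵢ / Nᵢ] / [Σᵢ cᵢ n1ᵢ / Nᵢ],   Nᵢ = n1ᵢ + n0ᵢ,

over (a) all k trials and (b) only the trials whose censored report
contains the type — what a reviewer of public sources can actually pool
(availability bias). No continuity correction is applied: zero cells
contribute zero to the sums and a zero denominator leaves the estimate
undefined and flagged, since a correction would embed an analysis choice
the criteria themselves never reference. The risk-ratio (not odds-ratio)
scale matches how criteria are phrased ("twice as frequent"). A
fixed-effect estimator is the minimal standard choice; random-effects
pooling and selection-model corrections are out of scope.

Reported summaries per criterion: mean (selective − true) log-RR over
types reported at least once; mean (selective − complete) log-RR — exactly
zero for `thr=0%`, which censors nothing; the fraction of truly elevated
types ever reported; and the fraction of types never reported. The
qualitative contract is direction (conditioning on a positive contrast
selects positive noise, so under a global null the selective pooled
log-RR is biased upward) and exact determinism given a seed; magnitudes
are outputs of the simulation, not calibration targets.

## Problem sizes

Defaults used by the analysis scripts and acceptance script: 8-trial
corpus for criterion application; calibration over 200 replicate trials of
300 latent types (the stored-type count is checked against the analytic
expectation Σ_t [1 − Π_arms (1 − p)^n] within 3 Monte-Carlo standard
errors); bias experiments with k = 20 trials, 60 latent types,
150 participants/arm, 200 replicates. These sizes give stable Monte-Carlo
summaries (direction tests significant at α = 0.01) while the whole suite
runs in minutes on one core.

## External data

The per-term CSR AE listing of the Calabrese 2004 quetiapine trial
(316 distinct types; 126 pass ≥ 1% in any group, 67 pass ≥ 2% in any
group, 5 pass ≥ 10% of quetiapine-treated and twice placebo) lives in a
public Dryad deposit that is not redistributable inside this repository.
`tests/test_acceptance.py::test_calabrese_2004_reported_counts` computes
those counts when the table is exported to csv_long format at
`data/calabrese2004.csv`; without the file the test fails rather than
skips, so its status is always visible.

## Known limitations

* Criteria referencing statistical significance or seriousness are not
  modelled (never observed in the motivating corpus).
* AE-term grouping/coding (MedDRA etc.) is out of scope; term identity is
  whitespace/case-normalized verbatim text.
* The generator's independence assumptions understate the correlation
  structure of real AE data; bias magnitudes transfer qualitatively, not
  numerically.
* Counts are participants with ≥ 1 event; recurrent-event and
  time-to-event structure are not represented.
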