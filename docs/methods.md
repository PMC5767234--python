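# Methods

## Problem setting

Two basidiomycetes grown in liquid co-culture induce metabolite features
absent from (or far weaker in) either mono-culture. To attribute an induced
feature to its producer without knowing its structure, the mycelia are
separated after 10 days of co-culture and mono-cultured on ¹³C-glucose
(plus, in the main arm, the day-10 co-culture supernatant). A feature whose
isotopologue ladder shifts to heavier masses in one mono-culture is being
synthesized by that organism. `cocultrace` implements this analysis as a
pipeline of testable stages, together with a synthetic-data generator that
encodes the study design so the whole chain is verifiable by parameter
recovery.

## Isotope model

All isotope arithmetic uses an embedded table of IUPAC 2013 isotope masses
and representative abundances for C, H, N, O, S, P (`isotopes.py`). Mass
shifts are aggregated by nominal shift (unit Da): QTOF data are extracted
at unit isotopologue resolution, so fine isotopic structure (e.g. ¹⁵N vs
¹³C at the same nominal shift) is intentionally merged. Natural
isotopologue distributions are computed by convolving per-element
multinomial distributions (exponentiation-by-squaring for large atom
counts); truncation error at N+1 entries is < 10⁻⁶ for the molecule sizes
handled here.

The correction matrix for an N-carbon formula has column *j* equal to the
theoretical mass-shift distribution of a molecule with exactly *j* tracer
carbons: a deterministic shift of *j* convolved with the natural
distribution of the remaining N−j carbons and all heteroatoms. By default
natural ¹³C on unlabeled positions is part of the model
(`exclude_tracer=False`), matching the matrix-based correction convention
for tracer experiments; the flag is exposed.

## Labeling model and why incorporation = 100 p

The generator labels each carbon independently with probability *p*
(binomial model). Including residual natural abundance, each carbon is
heavy with probability q = p + (1−p)·0.0107, so the simulated ladder is
Binom(N, q) ⊛ natural(heteroatoms) — exactly Σⱼ vⱼ·C₍ⱼ₎ with
v = Binom(N, p). Non-negative least squares on noiseless input therefore
recovers v exactly, and the carbon-normalized incorporation
100 · Σ i·Mᵢ / N equals 100 p (binomial mean N p). This identity is the
backbone of the recovery tests: 19% / 25% for the 24-carbon reference
feature and 14% for orsellinic acid are reproduced to < 0.1 percentage
point through the full extraction + correction chain.

NNLS (scipy) rather than direct matrix inversion prevents negative
isotopologue fractions on noisy data; the inversion route survives as a
test oracle. The relative solve residual is recorded on every corrected
MID; residuals above 0.1 are logged as possible co-eluting isobaric
interference (see Limitations).

## Statistics

- Replicate structure: 3 biological × 2 analytical; analytical replicates
  are averaged within each biological replicate before any test, so n = 3
  per arm.
- Labeling calls: two-sided, pooled-variance two-sample t-test of the
  with-supernatant incorporation against the unlabeled baseline arm of the
  same feature and organism; labeled requires p < 0.05 **and** a mean
  excess over the baseline of ≥ 1% incorporation. The floor is applied to
  the excess, not the absolute mean, so a static artifact inflating both
  arms equally (e.g. an interfering co-eluting ladder) cannot produce a
  labeling call. The 1% default reflects the scale of residual correction
  error on noisy ladders; it is exposed in the configuration.
- Time-course classification: a t-test between the day-10 and day-20
  replicate incorporations; not significant → isotopic steady state,
  significant increase → still labeling, significant decrease → flagged
  anomalous.
- Producer assignment counts labeling at *any* timepoint, since slowly
  labeling features may only reach significance at the later sampling.

## Induction rules

Detection floor 10³ counts (the peak-detection threshold of the upstream
peak picker); "detected in the co-culture" requires exceeding the floor in
at least 2 of 3 biological replicates. Newly synthesized = detected in the
co-culture and below floor in both mono-culture group means; fold-increased
= co-culture group mean ≥ 5× the **larger** mono-culture mean (the
conservative choice). The classes are disjoint by construction.

## Compound-level merging

Features observed in both ionization modes (same formula, RT within
0.2 min, opposite polarity) are merged to one compound-level producer call.
Conflicting calls resolve to the more informative one
(both > single organism > unassigned; A-only vs B-only → both) with a
conflict note retained.

## Molecular networking

The modified cosine allows fragment matches either direct (±0.5 Da) or
shifted by the precursor mass difference. Intensities are square-root
scaled and unit-normalized; the one-to-one peak matching is built greedily
by descending intensity product. The greedy matching is a deterministic
approximation of the optimal assignment; tests verify it against an
exhaustive matching enumeration for small spectra and against an
independent implementation. Network construction keeps edges with
score ≥ 0.65 and ≥ 6 matched peaks, trims components above 50 nodes by
removing globally lowest-scoring edges (ties by lexicographic node ids —
the trimming rule used by the original web platform is unpublished, so
ours is simply documented and deterministic), and drops components smaller
than 2.

## The packaged scenario

The scenario roster is built from the study's induced-feature table (82
rows across both ionization modes, packaged as
`data/induced_features.tsv`), merged to compound level by the same
formula/RT rule. The published headline tallies are 74 induced compounds
(58 newly synthesized + 16 fold-increased), producers 20 A / 6 B / 5 both /
43 unassigned, with 12 of the 43 at high signal; the table itself merges to
73 compounds with 42 unassigned, and its intensity column is incomplete
(many "not detected" entries). The scenario therefore normalizes the
roster: one synthetic unlabeled newly-synthesized compound (id marked
`synthetic`) completes the totals, unprinted intensities default to
5 × 10³ (detectable, below the high-signal floor), and exactly 12
unassigned compounds are placed at or above the 10⁴ high-signal floor —
with a 2× margin, because "high signal" is a planted truth label and a
compound parked exactly at the decision floor would be classified by
measurement noise alone.

Fold-increased compounds keep their printed ratios; their co-culture
intensity is raised where needed so the implied mono-culture signal stays
safely above the detection floor (otherwise the planted fold class would
be indistinguishable from newly synthesized). Printed fold ratios are
treated as data and never adjusted: the 5.2-fold compound sits close to
the 5-fold threshold and is missed on a minority of noise realizations —
an honest property of the design, not a defect.

Enrichment trajectories: documented reference features are encoded
explicitly (19% → 25% for the 24-carbon glycoside-like feature in organism
A; 14% steady for orsellinic acid in organism B; compound 1 labeled by
both with the day-20 enrichment in B 1.3× that in A). The remaining
labeled features receive deterministic mid-range trajectories
(p = 0.10–0.20), 11 of the 31 still increasing between days 10 and 20 and
the rest at steady state, mirroring the reported time-course split. All
labeled features are supernatant-dependent (labeling requires the
co-culture supernatant), as the study's control arm indicated.

Noise is multiplicative log-normal with 5% relative SD (unit mean) applied
per sample and per isotopologue peak; biological and analytical replicate
noise are not separated. Background features (4,000 by default, mirroring
the recorded feature count) are equally intense in all three groups.

## What the generator does and does not emulate

Emulated: group structure, replicate design, detection floors, log-normal
intensity noise, binomial labeling trajectories over two timepoints and
two supernatant conditions, isotopologue ladders with natural-abundance
convolution, cross-polarity duplicate features, MS/MS families sharing
fragment backbones. Not emulated: chromatographic peak shapes, RT drift
and alignment error, adduct/in-source chemistry, ionization suppression,
gap-filling artifacts, heteroscedastic detector noise. Passing recovery
tests therefore demonstrates the correctness of the analysis chain on the
assumed measurement model, not robustness to every artifact of real
LC-MS data.

## Numerical choices

- ¹³C−¹²C ladder spacing 1.003355 Da; extraction tolerance 10 ppm, RT
  window ±0.2 min (the upstream aligner's gap-filling tolerances); peaks
  within tolerance of two ladder slots go to the nearer slot, ties toward
  lower shift.
- Intensities within an RT window are summed across spectra (apex picking
  is not modeled).
- Adducts: M, M+H, M−H only; proton-mass convention (electron mass
  included). Charge states > 1 are out of scope.
- MID normalization tolerance 10⁻⁹; noiseless correction round-trip
  verified to 10⁻⁸.
- All random draws flow through `numpy.random.Generator` seeded from the
  scenario seed plus fixed stream offsets, so every table is byte-identical
  across reruns and platforms.
- Simulation sizes used by the test suite and the acceptance script: the
  full 4,074-feature matrix for induction, and 74 features × 2 organisms ×
  (2 days × 2 conditions + baseline) × 6 replicates for labeling, which
  completes in a few seconds.

## Known limitations

- Isobaric ladder interference: co-eluting features whose m/z difference is
  close to a multiple of 1.003355 Da contaminate each other's ladders (the
  packaged roster contains one real instance: m/z 389.2072 picks up the
  intense m/z 399.2386 at slot 10, 5.5 ppm away). The correction residual
  flags such cases, and the baseline-matched t-test with the excess-
  enrichment floor prevents false labeling calls, but the reported apparent
  incorporation for such a feature is not meaningful.
- Published ppm errors for some reference masses are not reproducible from
  standard isotope masses under either adduct convention (e.g. the m/z
  490.3025 / C₂₄H₄₅NO₉ pair computes to 0.7 ppm, not 0.3); computed errors
  are reported as-is.
- The "unassigned" class conflates genuinely contact-dependent synthesis
  with features too weak to label-detect; the high-signal floor separates
  the two heuristically, and the not-evaluable case is reported distinctly
  for supernatant dependence.
- Producer calls assume clean mycelial separation; cross-contamination
  between mono-cultures is reported, not modeled.
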