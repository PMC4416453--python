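# Methods

## Model

All estimators assume a constant-rate linear birth–death process:
speciation rate λ and extinction rate μ per lineage per Myr, net
diversification r = λ − μ, extinction fraction (turnover) ε = μ/λ.  Ages are
Myr before present; logarithms are natural throughout — this is forced by
the crown estimator's no-extinction form, which must invert the expected
crown diversity 2·e^{rt}.

Conditioned on a single founder lineage leaving survivors at horizon t, the
number of its extant descendants is geometric with parameter

    β = (e^{rt} − 1) / (e^{rt} − ε),      α = ε·β  (extinction probability),

so P(N ≥ n | stem survival) = β^{n−1} and the expected size is
(e^{rt} − ε)/(1 − ε).  The crown conventions used here are stated
explicitly because they are frequently left implicit in the literature:

* **stem basis** conditions on ≥ 1 survivor from one founder;
* **crown basis** conditions on *both* basal lineages leaving survivors, so
  the clade size is the sum of two independent survival-conditioned
  geometrics: P(N = k) = (k−1)(1−β)²β^{k−2} and
  P(N ≥ n) = β^{n−2}[(n−1) − (n−2)β].

The simulator is the arbiter of these conventions: tail probabilities and
ensemble means are tested against it (20,000 replicates, 2–3 standard-error
tolerances), and the crown estimator is validated by parameter recovery on
simulated ensembles.

### Estimators

The method-of-moments rates invert expected diversity at fixed ε:

    stem:   r̂ = ln(n(1−ε) + ε)/t
    crown:  r̂ = (1/t)[ln( n(1−ε²)/2 + 2ε + ((1−ε)/2)√(n(nε²−8ε+2nε+n)) ) − ln 2]

The crown form reduces algebraically to (ln n − ln 2)/t as ε → 0 and is
identically zero at n = 2 for every ε, which is why the pipeline assigns
two-taxon clades a diversity of 2.01 (on both bases, for every ε in the
grid).  `expected_crown_diversity` is defined as the exact functional
inverse of the crown estimator; for ε > 0 it is recovered by monotone
root-finding (Brent, bracket [2, 20·e^{rt} + 10], expanded if needed),
which the round-trip tests pin to 1e−9 relative error.  Note that this
inverse is *not* 2(e^{rt} − ε)/(1 − ε): the estimator's internal
expectation differs from the mean of the two-founder convolution; the
convolution is what the tail probabilities and the simulator use, and the
envelope-containment test checks that the estimator's expectation always
lies inside the convolution-based 95% band.

### Confidence envelopes and classification

`diversity_limits` inverts the tail laws continuously: the lower bound
solves tail(n) = (1+conf)/2 and the upper solves tail(n) = (1−conf)/2 in a
continuous relaxation of n (closed-form for the stem basis, Brent for the
crown basis).  Bounds are therefore real-valued, ≥ 2 (crown) or ≥ 1 (stem).
Classification treats the band as a closed interval: a clade exactly on a
bound is "within".

One consequence of the continuous relaxation is worth knowing: the crown
lower bound is strictly greater than 2 whenever β > 0, so *every* two-taxon
clade classifies "below" the envelope, however young.  For old two-taxon
clades (Sideroxylon, Canarina) this is the intended extinction signal; for
young ones (e.g. the Cicer crown age of 3.4 Ma) the deficit is marginal
(lower bound ≈ 2.1) and should be read with the tail probability, which the
classification table reports alongside the position.  Discrete
integer-quantile bounds would instead return 2 at young ages; the
continuous behavior is kept because it matches the reference envelope
construction and is what the calibration test quantifies (the law-implied
outside fraction at the simulated study conditions is ≈5.7%, not exactly
5%, precisely because integer clade sizes meet continuous bounds).

The reference envelope uses, per ε, the highest family-level rate in the
table on the configured basis; with the packaged fixture this is Asteraceae
(n = 25,000 at a 47.5 Ma crown, r̂ ≈ 0.199/Myr at ε = 0) at every ε.

### Clade probabilities, gaps, stages

Clade-size probabilities are P(N ≥ n_clade) under the *encompassing* row's
rate, recomputed per ε, over the clade's own age — reported raw; no
multiple-testing correction is applied, matching standard practice for this
descriptive diagnostic.  Stem–crown gaps (stem − crown age) above 10 Myr
are flagged as candidates for historically high extinction.  Stage binning
uses International Chronostratigraphic Chart boundaries
(Burdigalian 20.44–15.97 … Pleistocene 2.58–0.0117 Ma) shipped as an
editable TSV, with half-open [older, younger) intervals.  The low-level
`assign_stage` has a boundary-snap flag tolerance of 0 by default; the
pipeline `timeline` uses 0.3 Myr, because disjunction ages are recorded at
0.1–0.5 Ma precision ("ca." dates), so ages like 7.5 Ma — 0.25 Myr older
than the Messinian's 7.246 Ma bound — are surfaced as boundary cases rather
than silently labeled Tortonian.  A side effect is that 5.5 and 7.0 Ma
rows, which sit within 0.25 Myr of boundaries, also carry the flag; their
stage labels are unaffected.

## Simulator

`bd_sim` performs exact next-event (Gillespie) simulation with
piecewise-constant rates.  Extinction pulses are (older, younger, μ_pulse)
intervals in Ma measured backward from the present; pulse edges are handled
as rate change-points (waiting times truncated and redrawn at each
boundary — exact for a Markov process), never by time discretization.
Conditioning on stem or crown survival is by rejection with an explicit cap
(10⁶ attempts by default; exceeding it raises a named error).  Crown
conditioning starts from two founders, each required to leave survivors;
because both founders survive, a crown-conditioned replicate's crown age
equals its stem age (the horizon) by construction.

Two backends share this model:

* a per-replicate event loop recording the full genealogy, used whenever
  pulses, trees or crown ages are needed; survivor trees are emitted as
  ultrametric newick with branch lengths in Myr (extinct lineages pruned);
* a vectorized counts-only loop (numpy) for large constant-rate ensembles;
  crown conditioning there pairs independently conditioned founders, which
  is distributionally identical.

A chi-square goodness-of-fit test ties the simulated size distribution to
the geometric law, and a cross-backend test ties the two loops to each
other.  All randomness flows through one integer-seeded numpy generator;
identical seed + scenario gives identical output, with no time-based
seeding anywhere.

### What the generator emulates — and what it does not

Synthetic clades emulate the study conditions of the meta-analysis:
constant (or pulse-modulated) rates, complete sampling of extant species,
and exact clade ages.  Real chronogram data violate all three in various
degrees (rate heterogeneity across lineages, missing taxa, dating error
with HPD intervals).  Passing tests therefore demonstrate that the
estimators and envelopes are internally consistent and correctly calibrated
*under the birth–death model*, not that the model captures any particular
empirical clade; the fixture analysis inherits whatever error its input
ages and richness values carry.

## Problem sizes

Simulation-backed tests use 20,000 replicates for moment/tail validation
(binomial standard errors small enough for 2–3 SE assertions), 2,000 for
parameter recovery and envelope calibration, and 3,000 per pulse level for
the gap diagnostic; parameter-recovery ensembles run to a 30 Myr horizon so
that the median-of-estimates bias of the crown estimator (which shrinks as
r·t grows; ≈ +15% at r·t = 3 under ε = 0.9) stays well inside the 20%
recovery band.  The whole suite completes in a few seconds on one CPU.

## Fixture table

`data/rf_lineages.tsv` encodes the 21 dated disjunctions (5 E–S, 16
W–E(&S)) with their nesting chain up to 12 plant families, plus the four
crown/stem age pairs explicitly reported (Cicer 3.4/12.2, Camptoloma
5.5/10.2, Campylanthus 7.5/20.0, Sideroxylon 17.4/47.3 Ma).  Twenty of the
21 splits are individually dated in the source results; the 21st is encoded
as a second (Southern-Africa) split within *Euphorbia* sect. *Aphyllis* at
5.0 Ma — a documented package convention, marked as such in its
`source_note`.  Species richness values are not fixed by the chronograms;
rows carry field-standard estimates with per-row notes marking every
non-reported value as replaceable.  Classifications that depend on those
richness values (which clades sit below/above the envelope) are exactly
reproducible from the shipped table but should be re-derived if richness
estimates are revised.

## Known limitations

* Constant-rate birth–death only: no time-variable or trait-dependent
  likelihood models, no fossilized birth–death, no diversity dependence.
* ε = 1 (critical process) and r < 0 (declining diversity) are rejected
  with explicit errors, not clamped.
* Tail probabilities require integer clade sizes; the 2.01 adjustment
  exists only for rate estimation.
* Chronograms must be rooted, binary at the root, and ultrametric within
  tolerance (default 1e−4 of tree height); non-contemporaneous tips are
  rejected rather than rescaled, and posterior/HPD annotations are ignored.
* Statistical power to flag young, species-poor clades is intrinsically
  low: a two-species clade at 3 Ma is barely distinguishable from the
  reference expectation (see the classification caveat above).
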