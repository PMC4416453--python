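# randflora

Birth–death diversification meta-analysis of **Rand Flora** disjunctions —
the biogeographic pattern in which unrelated plant lineages show similar
disjunct distributions along the continental margins of Africa and adjacent
islands (Macaronesia–NW Africa, Horn of Africa–S Arabia, E Africa,
S Africa).

The package is aimed at plant biogeographers and macroevolution researchers
who have dated phylogenies (chronograms) for disjunct clades and want to
ask: *given its age, is this clade as species-rich as a background
diversification rate predicts, or does its poverty point to climate-driven
extinction?*

## What it computes

For a clade of `n` extant species and age `t` (crown or stem, in Myr), under
a constant-rate birth–death process with net diversification `r = λ − μ` and
extinction fraction `ε = μ/λ`, the method-of-moments estimators are

```
stem basis:   r̂ = ln(n(1−ε) + ε) / t
crown basis:  r̂ = (ln n − ln 2) / t                      (ε = 0)
              r̂ = (1/t)·[ln( n(1−ε²)/2 + 2ε
                    + ((1−ε)/2)·√(n(nε² − 8ε + 2nε + n)) ) − ln 2]   (ε > 0)
```

evaluated at the conventional extinction scenarios ε ∈ {0, 0.5, 0.9}.
Two-taxon clades, whose crown estimate is identically zero, are assigned a
diversity of 2.01. The size of a surviving lineage's descendance is
geometric with parameter `β = (e^{rt} − 1)/(e^{rt} − ε)`, which yields
clade-size tail probabilities (`P(N ≥ n | survival) = β^{n−1}` on the stem
basis; the two-founder convolution tail on the crown basis) and 95%
expected-diversity envelopes through time.

Modules:

* `randflora.bd_moments` — the closed forms above: estimators, expected
  diversity, tail probabilities, confidence envelopes.
* `randflora.bd_sim` — an exact event-driven birth–death simulator
  (conditioned on stem/crown survival, with episodic extinction pulses):
  the Monte Carlo oracle for the closed forms and the generator of
  synthetic clades and ultrametric newick trees.
* `randflora.chrono_io` — chronogram input (newick/NEXUS, BEAST annotations
  tolerated) and MRCA/stem/disjunction age extraction.
* `randflora.rf_pipeline` — the end-to-end analysis over a packaged table of
  21 dated Rand Flora disjunctions nested in their encompassing clades up to
  family level: rate tables, the fastest-family (Asteraceae) reference
  envelope, clade classification, clade-size probabilities, stem–crown gap
  diagnostics and geological-stage binning.

## Worked example

```python
from randflora import bd_moments as bdm, rf_pipeline as rp

# Sideroxylon W-E disjunction: 2 species, crown age 17.4 Ma
est = bdm.crown_rate(bdm.two_taxon_adjustment(2), 17.4, 0.0)
print(f"Sideroxylon crown r (eps=0): {est.r_hat:.6f} per Myr")

table = rp.default_lineage_table()
envs = rp.reference_envelope(table, epsilons=(0.0,))
env = envs[0.0]
print(f"reference family: {env.reference}, r = {env.r_ref:.4f} per Myr")

cls = rp.classify_clades(table, envs).set_index("row_id")
print("Sideroxylon W-E position:", cls.loc["D20", "position"])

gaps = rp.stem_crown_gap(table).set_index("row_id")
print(f"Sideroxylon stem-crown gap: {gaps.loc['D20', 'gap_myr']:.1f} Myr")

print("Sideroxylon stage:", rp.timeline(table).set_index("row_id").loc["D20", "stage"])
```

prints

```
Sideroxylon crown r (eps=0): 0.000287 per Myr
reference family: Asteraceae, r = 0.1986 per Myr
Sideroxylon W-E position: below
Sideroxylon stem-crown gap: 29.9 Myr
Sideroxylon stage: Burdigalian
```

That is the package's core story in miniature: at 17.4 Ma a clade
diversifying at the Asteraceae reference rate is expected to hold roughly
9–175 species (the 95% band), so a two-species clade sits *below* the
envelope — significantly less diverse than expected — and its 29.9 Myr
stem–crown gap is flagged as a signature of historical extinction, while
its age bins into the Burdigalian stage of the Early Miocene.

The same operations are exposed on the command line:

```
randflora rates --basis both --epsilon 0,0.5,0.9
randflora classify --conf 0.95
randflora gaps --flag-gap 10
randflora timeline
randflora simulate --lam 0.3 --mu 0.15 --time 10 --condition crown_survival --reps 100 --seed 1
randflora extract --tree chronogram.nwk --side-a west.txt --side-b east.txt
```

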