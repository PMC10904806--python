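# Methods

This note records what `phylorisk` computes, the modelling assumptions
behind each stage, and the numerical and design choices that are not
forced by the mathematics.

## 1. Expected loss of phylogenetic diversity

Let a rooted tree have branches `b` with lengths `L_b` (MY), and let
each species `i` carry an extinction probability `q_i`. Treating
extinctions as independent, a branch survives iff at least one
descendant species survives, so

```
E[loss] = Σ_b  L_b · Π_{i ∈ desc(b)} q_i .
```

`pd_metrics.expected_pd_loss` computes the inner products in log space:
a post-order pass accumulates `S_b = Σ_{i ∈ desc(b)} log q_i` on a flat
array representation of the tree (`phylogeny.TreeIndex`), then sums
`L_b · exp(S_b)`. This is O(n), exact to floating point, and immune to
underflow on trees with 10⁴–10⁵ tips where the naive product is 0.
`proportion_threatened` is the same quantity as a percentage of total
PD. Independence of extinctions is an assumption, not a theorem; the
clumped category assignment in the generator (§6) exists precisely to
exercise the metrics under spatially correlated risk, but the loss
formula itself never models correlation.

## 2. Species scores

For species `i` with terminal branch length `TBL_i`:

```
ED2_i   = TBL_i + Σ_{ancestral branches b} L_b · Π_{j ∈ desc(b), j ≠ i} q_j
EDGE2_i = q_i · ED2_i
```

`edge_scores.species_scores` evaluates all scores in two O(n) sweeps:
the post-order `S_b` pass from §1, then a pre-order accumulation of
`Σ L_b exp(S_b)` along root-to-tip paths; dividing each branch term by
`q_i` removes the focal species from the product. Scores therefore
require `0 < q_i < 1` strictly — the sampling curve guarantees this by
clamping at `1 − 1e-9` — and satisfy the identity

```
EDGE2_i = E[loss] − E[loss | q_i = 0]
```

(the expected history that securing species `i` would avert), which the
test suite checks directly against two independent implementations.

## 3. Risk weightings and uncertainty

Three category→probability tables are shipped (`data/risk_weights.csv`):
a 50-year and a 500-year quantification, and the EDGE2 weighting whose
medians form an exact geometric sequence with ratio 2 (LC 0.060625 …
CR 0.97).

Uncertainty is modelled on a continuous *rank axis*: LC…CR sit at ranks
0…4 and each category owns the band `[rank − ½, rank + ½]`. A sampled
weight is `curve(r)` with `r` uniform in the species' band, where
`curve` interpolates `log q` linearly between the category medians and
extends the end segments with the adjacent slope. Consequences, all
tested:

- the median of a category's draws is its tabulated value;
- draws never leave `(0, 1)` (upper clamp `1 − 1e-9`, so the 500-year
  CR weight prints as 1 but branch products stay informative);
- at any fixed within-band quantile the five categories stay ordered,
  and the 500-year curve dominates the 50-year curve everywhere.

**Data Deficient / Not Evaluated** species draw `r` uniformly over the
whole axis `[−0.5, 4.5]`: 60% of that range lies at or above the lower
edge of the Vulnerable band (rank 1.5), so ~60% of DD draws are
threatened-level and the DD median equals the VU value. **EW** is
sampled from the CR band by default (`ew_as_cr=True`) — extinct in the
wild is treated as maximal surviving risk; **EX** species carry no
forward risk and must be pruned before weighting (the API raises rather
than guessing). Per-replicate draws consume randomness in sorted
species-name order, so results are independent of input record order.

## 4. Congeneric imputation

Species present in the taxonomy but absent from the tree are grafted
near their congeners. For each missing species, in random order:

- if the genus is monophyletic, candidate attachment edges are the
  genus crown edges, the congener pendant edges, and (optionally) the
  genus stem edge; if it is not monophyletic, only congener pendant
  edges are used, which cannot worsen the paraphyly;
- an edge is chosen uniformly, an attachment height uniformly along it,
  and the new pendant extends to the present, preserving
  ultrametricity to < 1e-6 MY;
- earlier grafts are eligible hosts for later ones, so large missing
  genera fill in realistically.

Species whose genus has no tip in the tree are reported as skipped, not
silently dropped. Placement is re-randomised every replicate, so
downstream medians marginalise over placement uncertainty.

## 5. Family-level assessment

Per family: species counts, data-sufficient counts (DD and NE excluded),
"fully threatened" flags computed both over all species and over
data-sufficient species only, monotypic status, mean species EDGE2
(mean, not median — a family's score should feel its one extreme
species), and median stem age across replicate trees (age of the parent
of the family's MRCA; undefined when the family spans the root).

A family is flagged an **EDGE Lineage** when (a) all its
data-sufficient species are threatened, (b) its mean EDGE2 strictly
exceeds the across-family median — strict, so in degenerate
all-identical pools nothing is flagged — and (c) at least half its
species are assessed (`min_assessed = 0.5`, inclusive).

**Trend null.** Whether monotypic families are declining more than
expected is tested against a matched null: each resample draws, without
replacement, the monotypic set's exact (clade × category) composition
from the full trend-labelled pool, realised exactly via a multivariate
hypergeometric draw per stratum. Observed per-trend counts are compared
with the null by a two-sided one-sample t-test (p reported unadjusted;
degenerate zero-variance classes reported as NaN with a flag). The
acceptance suite confirms the null covers truly random monotypic sets
at its nominal rate.

## 6. Synthetic data generator

The generator exists so every pipeline stage can be exercised, at any
scale, with no external data. It emulates the *structure* of a
time-calibrated vertebrate dataset, not any real taxon:

- pure-birth (optionally birth–death) trees per clade, pendant edges
  extended by one extra exponential waiting time (the simulator stops
  at the n-th birth, which would otherwise leave zero-length pendants),
  rescaled to a fixed crown age (default 250 MY);
- genera and families cut at fixed fractions of the crown age (0.15 /
  0.40), guaranteeing genera nest within families;
- Red List categories i.i.d. from configurable frequencies, or
  phylogenetically clumped: with probability λ a species copies its
  nearest already-assigned neighbour's category (patristic distance);
  a DD/NE overlay, population trends, and a possibly-extinct tag on a
  fraction of CR species;
- replicate trees jitter each node's age *gap* above its oldest child
  by a log-normal factor (median 1), so topology, tip set and
  ultrametricity are preserved exactly and per-gap medians are
  unbiased — the suite checks that median terminal branch lengths
  across 1000 replicates recover the generating tree within 2%.

What it does **not** emulate: realistic diversification-rate variation,
non-ultrametric uncertainty in tip dates, taxonomic error, or spatial
structure in threat beyond the clumping knob.

## 7. Pipeline and reproducibility

`pipeline.run_all` chains the stages: simulate → prune a fraction of
species to "missing" → jitter replicate trees → per replicate
(re-impute, draw weights, score species) → aggregate. Aggregation takes
per-species medians across replicates, ranks by descending median EDGE2
(ties broken by name, stable mergesort), and flags EDGE species:
threatened and above the potential-zone threshold (EDGE2 ≥ clade median
in ≥ 95% of replicates). The capture curve reports the fraction of
summed median EDGE2 held by the top-ranked species; `lost_history` sums
median TBL over possibly-extinct and EX species.

Every stage draws from a child of a single `numpy.random.SeedSequence`,
spawned in a fixed order, so one integer seed makes the entire run —
tree simulation through bootstrap CIs — bitwise reproducible; the
acceptance suite runs the demo configuration (8 clades, ≤ 500 tips, 100
replicates, < 1 min) twice and compares every output table exactly.
A `manifest.json` records config, seed, stage timings and SHA-256
digests of the written inputs.

## 8. Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| crown age | 250 MY | deep, vertebrate-order-like timescale |
| genus / family cut | 0.15 / 0.40 × crown age | yields realistic genus/family sizes |
| category frequencies | LC .55, NT .12, VU .13, EN .10, CR .08, EW .01, EX .01 | threatened share ≈ 1/3 of assessed |
| DD / NE fraction | 0.06 / 0.02 | minority of table, enough to matter |
| possibly-extinct among CR | 0.17 | small tail of likely-lost species |
| replicates | 1000 (full), 100 (demo) | stabilises medians vs. runtime |
| jitter noise σ | 0.05 | ±10% node-age spread at 2σ |
| imputed fraction | 0.10 | typical missing-species share |
| scheme | edge2 | the prioritisation weighting |
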