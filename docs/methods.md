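# Methods

## Problem and scope

When two divergent strains are crossed, each alternative-splicing (AS) event
in the F1 hybrids can track one parent, sit between them, or escape the
parental range altogether.  This package implements the post-alignment half
of that analysis for a reciprocal-cross RNA-seq design with two parental
chicken strains — Cornish Game (CG, broiler) and White Leghorn (WL, layer) —
and their reciprocal hybrids CL (CG sire x WL dam) and LC (WL sire x CG
dam): PSI quantification from rMATS-style junction counts, parental
divergence testing, nine-way inheritance classification, cross-group
consensus, and summary statistics.  Read alignment, event discovery, and
functional enrichment are out of scope; the input is the junction-count
table an rMATS run produces.

## PSI quantification

For a record with inclusion-junction count `ijc`, skipping-junction count
`sjc` and effective lengths `l_i`, `l_s`:

    PSI = (ijc / l_i) / (ijc / l_i + sjc / l_s)        (length-normalised, default)
    PSI = ijc / (ijc + sjc)                            (raw-count convention)

The length-normalised form is the rMATS `IncLevel` convention and the
default because the inclusion isoform exposes more junction positions than
the skipping isoform; the raw form is exposed because the classification
literature often states the formula without lengths.  The two agree exactly
whenever `l_i = l_s`.  PSI is missing (NaN) when `ijc + sjc = 0`; missing
values propagate so that an event lacking a defined group mean is skipped in
exactly the comparisons that need that group, not globally.

Filtering follows the study design: an event is kept only if the mean total
junction count over replicates is at least `min_mean_total = 10` in **every**
(strain, sex) cell of the tissue (the threshold is interpreted per replicate
group, which is the stricter of the plausible readings), and only autosomal
events are analysed — chicken Z/W dosage compensation is incomplete, so
sex-chromosome events confound sex with inheritance.  MT and unplaced
scaffolds are dropped conservatively.  The two filters commute.

## Parental divergence test

Replicate inclusion counts are modelled as beta-binomial,
`ijc ~ BetaBin(total, mu, rho)`, with `mu` the strain's inclusion level and
`rho` the intra-class correlation capturing biological overdispersion
(`rho = 0` is exactly binomial).  Divergence between CG and WL in a tissue
is a likelihood-ratio test with 1 df:

* null: one shared `mu`, `rho` free;
* alternative: `mu_CG != mu_WL`, shared `rho`.

`mu` is maximised on [1e-4, 1 - 1e-4] by golden-section search (vectorised
across the dispersion grid); `rho` is profiled on the fixed grid
{0, 0.01, ..., 0.5} with two nested 21-point local refinements.  The
alternative is additionally evaluated at the null's refined `rho` so the
nested model can never outscore it through refinement asymmetry; the
statistic is clamped at 0 with a 1e-6 tolerance guard.  P-values use the
chi-square(1) survival function, and Benjamini–Hochberg controls the FDR
across events within a tissue (`significant` means FDR < 0.05).

**Known limitation — small-sample calibration.**  With 3 replicates per
strain the dispersion MLE is biased low and the chi-square reference is
anticonservative under real overdispersion: at rho = 0.05 and depth 50 the
empirical type-I error at nominal 0.05 is ≈ 0.11, converging toward nominal
as replicates grow (≈ 0.08 at 6, ≈ 0.06 at 12 replicates).  With `rho`
pinned to 0 on binomial data the test is exactly calibrated, which isolates
the cause to dispersion estimation, not the implementation.  Users wanting
the original rMATS statistics can inject an external per-event p-value table
(`test="external"`); only the BH step is then recomputed.

## Inheritance classification

Each parentally divergent event with a defined hybrid group mean is
classified per comparison group — MC (CG/WL/CL males), FC (females),
MR (CG/WL/LC males), FR (females) — from the triple of group-mean PSI values
(p1 = CG, p2 = WL, h = hybrid).  Similarity is the symmetric fold-ratio

    sim(x, y)  :=  (max(x, y) + eps) / (min(x, y) + eps) <= fold

with `fold = 1.25` and pseudocount `eps = 0.01` guarding PSI near zero (the
ratio is otherwise unbounded as PSI -> 0).  The decision table:

* similar to both parents → **conserved** (precedence: this wins even though
  each single-parent condition also holds);
* similar to exactly one parent → **dominant** toward it, subtype *up* if
  that parent is the higher parent, *down* otherwise;
* similar to neither, strictly between the parents → **additive**, subtype
  by which parent is higher (CG>WL vs CG<WL);
* similar to neither, at or above both → **over-dominant**; at or below
  both → **under-dominant**.

Boundary ties resolve toward "similar" (`<=`/`>=` as written), making the
nine categories exhaustive and mutually exclusive; an exhaustive sweep of
the unit cube at 0.01 resolution verifies this against an independently
coded scalar decision table, and parent-relabelling maps each category to
its mirror.  Conserved requires similarity to *both* parents — the only
reading consistent with the 1 + 2 + 4 + 2 = 9 category arithmetic.

The **Fisher variant** replaces the fold-ratio with two two-sided Fisher
exact tests on replicate-pooled counts (hybrid vs each parent), BH-adjusted
per (tissue, group, parent-comparison) family; "similar" means adjusted
p >= 0.05, and between/outside placement uses pooled PSI point estimates.
The same decision table then applies.  At deep coverage the two methods
agree on the large majority of calls per mode; at low coverage Fisher is
more conservative (low power → "similar").

**Consensus rule.**  Within a tissue, a non-conserved collapsed mode
(additive / dominant-CG / dominant-WL / transgressive) is promoted to the
gene (or event) level when the same mode is called in at least
`consensus_min = 2` of the available groups; ties between two qualifying
modes emit no call.  The threshold is 2 because the liver design has only
two groups (hybrid-female liver samples are absent) yet still yields
consensus genes; it is configurable.

## Summary statistics

`tabulate` produces the per-(tissue, group) counts of the nine categories.
Percentages divide by the per-tissue number of events that entered
classification (the merge-step count — e.g. 1030/1950/754 in the reference
study), not by per-row classified sums: rows classify fewer events when a
group mean is missing, and the merge-step denominator is the only reading
that reproduces the reference percentages.  Reported values are rounded
half-up on exact rationals.

Cross-tissue comparisons use the tie-corrected Kruskal–Wallis H on per-group
proportions, with an exact permutation p-value (full enumeration of ordered
partitions) when the total observation count is <= 10 and the chi-square
approximation otherwise.  Within-tissue contrasts (up- vs down-dominance,
over- vs under-dominance, CG- vs WL-dominance) use Mann–Whitney U with full
enumeration of the permutation distribution (ties handled by midranks) when
both sides have <= 8 observations, and the tie-corrected normal
approximation otherwise.  These sample sizes (2–4 groups per tissue) make
the exact paths the ones that actually run.

## Synthetic data generator

The generator emulates the reference design: 4 strains x 2 sexes x 3
replicates (optionally two CL females and no hybrid-female liver samples),
three tissues, five event types in realistic proportions.  Per event a true
PSI triple is planted by constructive rejection sampling so that the
noiseless classification returns the requested category with a safety
margin: "similar" relations sit at fold-ratio <= fold/fold_margin and
"different" relations at >= fold*fold_margin (`fold_margin = 1.15`, which
must lie in (1, fold] for the similar side to be feasible).  Non-conserved
events separate the parents by at least `parental_separation = 0.3`
(mirroring events that would pass divergence testing); parental PSI is
drawn uniformly on [0.05, 0.95].

Counts per sample: total depth ~ negative binomial with mean
`depth_mean = 100` and dispersion 0.1 (Poisson at 0); inclusion counts ~
beta-binomial around the truth with `rho = 0.05`.  Truth PSI lives on the
length-normalised scale, so the count-level inclusion fraction is its
length-weighted image — the pipeline's normalised PSI is then an unbiased
estimate of the planted value.  Effective lengths are drawn once per event
(inclusion ~ U{50..300}, skipping ~ U{30..150}) to exercise the
normalisation toggle; 5% of events are planted below the low-count threshold
and 3% on the Z chromosome to exercise the filters.  The two hybrids share
one true PSI (no parent-of-origin effect) unless an offset is configured.
Identical seeds give byte-identical output files.

What the generator does **not** emulate: correlated events within genes,
PSI distributions concentrated near 0/1, mapping biases, library-size
differences between samples, or genuine parent-of-origin effects.  Passing
recovery tests therefore demonstrates correctness of the pipeline's logic
under its own noise model, not performance on arbitrary real data.

## Recovery under the study's noise conditions

A power consideration that shapes what recovery rates are attainable: the
1.25-fold "similar" band around a parent at PSI p has half-width roughly
0.2–0.25 x (p + 0.01), i.e. ≈ 0.10–0.13 at p = 0.5, while the standard
deviation of a 3-replicate group mean at depth 100 and rho = 0.05 is
sqrt(p(1-p)(1 + 99 * 0.05) / 300) ≈ 0.07 at p = 0.5 — and the biological
component alone (sqrt(rho * p(1-p) / 3) ≈ 0.065) does not shrink with
depth.  Similarity relations at mid-range PSI are therefore decided at
barely 1.5–2 standard errors, and per-(event, group) call accuracy plateaus
near 75–80% under these conditions; the cross-group consensus raises
accuracy among called events to the mid-80s.  This is a property of the
1.25-fold criterion with 3 replicates, not of the implementation: with
rho → 0 and depth 10 000 recovery approaches 100%, and noiseless planted
triples recover exactly.

## Problem sizes used in validation

The packaged validation runs use: an exhaustive 101^3 grid for the
classifier; all 2x2 tables with row sums <= 30 for Fisher exactness; a
2 000-event single-tissue simulation for pipeline recovery; 1 000 null and
2 x 150 alternative events for divergence calibration and power; and an
800-event deep-coverage (depth 300) simulation for threshold-vs-Fisher
agreement.
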