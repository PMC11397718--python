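# Methods

## Statistics

**Uniformity and distinctness.** For a trait measured on replicate
grains of each taxon, the intraspecific uniformity statistic is the
mean within-taxon coefficient of variation,
`c.v.bar = (1/n) Σᵢ Sᵢ/X̄ᵢ`, where `Sᵢ` and `X̄ᵢ` are the sample
standard deviation (ddof 1) and mean of taxon *i*'s replicates and
*n* is the number of taxa entering the average. The interspecific
distinctness statistic is `c.v. = S′/X̄′`, the CV of the per-taxon
means. Both are compared to a 15% threshold: `c.v.bar ≤ 15%` reads
"stable within taxa", `c.v. ≥ 15%` reads "discriminates among taxa".
Sample (ddof 1) standard deviations are used throughout. Taxa whose
trait mean is exactly zero (perforation-free exines give PD = 0 on
every replicate) are excluded from the uniformity average — their
within-taxon CV is 0/0 — and the exclusion count is reported.
Verdicts at the threshold carry a 1e-10 slack so a statistic that is
exactly 15% up to floating-point representation counts as boundary
(boundary = uniform, and boundary = distinct).

**ANOVA and compact letters.** Between-taxon differences are tested
with one-way ANOVA on replicate values; group-level summaries use
Tukey HSD (statsmodels) on per-taxon means — the units of a group
comparison are taxa, whereas a taxon comparison uses replicates.
Letters are assigned by the insert-and-absorb algorithm: start with
one column containing all groups, split every column containing both
members of a significant pair, drop columns that become subsets of
another. The resulting display satisfies, exactly: two groups share a
letter iff their pairwise p ≥ α. Groups are sorted by descending mean
(ties lexicographically) before insertion, so "a" marks the top
group. If every observation in every group is identical the
comparison is degenerate and all groups share one letter.

**Erdtman classes.** Size classes on the polar axis: small < 25.1 µm
≤ medium ≤ 50 µm < large (medium inclusive on both ends). Shape
classes on P/E: subprolate [1.14, 1.33), prolate [1.33, 2.00],
perprolate > 2.00; values below 1.14 return an out-of-catalogue flag
rather than raising, since real panels occasionally contain rounder
grains.

**Derived ratios.** P/E, P/E′ and E′/E are computed per taxon. The
default convention divides per-taxon means (`ratio_of_means`);
`mean_of_ratios` pairs replicates by replicate id and averages the
per-replicate ratios. With constant replicates the two coincide. E′
is treated as an independently measured interior diameter, never
derived from P or E; likewise S is a measured area, not P×E.

## Clustering

Taxa are clustered on six features — P, E, E′/E, RW, FW, PD — chosen
to span size, shape and ornamentation while avoiding near-duplicate
ratios. Features are per-taxon means, z-scored feature-wise (ddof 0);
without standardization the µm²-scale area and sub-µm ridge widths
would contribute incomparably to Euclidean distance. Default linkage
is Ward on Euclidean distance; UPGMA (average) and complete linkage
are selectable. The dendrogram is cut top-down by repeatedly
splitting the highest remaining merge (valid because merge heights
are non-decreasing for these linkages): first into `k_top` groups,
then the largest group's own subtree into `k_sub` subgroups — a
nested cut, not a global `k_top + k_sub − 1` cut. Group letters are
presentation only: assigned by ascending size (ties by dendrogram
leaf order) so the largest group always carries the last letter; the
partition itself is the contract. Features constant across taxa (up
to a scale-aware 1e-12 tolerance for representation noise) raise an
error naming the feature.

## Pedigree scores

A cultivar **aggregates** if its cluster label equals that of at
least one known parent ("any" rule; an "all" rule is available). At
`six_group` resolution the largest group is replaced by its
subgroups. Progeny with no known, clustered parent are not evaluable
and leave the denominator. Coarsening labels can only merge them, so
the four-group percentage is always ≥ the six-group percentage on the
same partition.

**PD progression** counts a cultivar whose perforation density
exceeds that of at least one comparator parent. Parent slots can be
`unknown` (unnamed) or `untested` (named but never measured) — these
are distinct states preserved from input. In `exclude_unknown` mode
both are dropped; in `assume_lower` mode they are assumed to carry
lower PD than the progeny, so the comparison auto-succeeds, making
assume-lower an upper bound of exclude-unknown (a progeny scored "no"
under assume-lower must have all parents measured and failing, hence
scores "no" under exclude-unknown too).

**Section aggregation** uses modal-label membership: each section's
modal cluster label is found and the statistic is the share of
sectioned species sitting in their section's modal label; ties accept
either label and are logged. The counting rule behind this statistic
is genuinely open — modal membership is the simplest rule that makes
"a section is concentrated" precise.

**Hybridization frequency** divides the number of crosses a species
appears in (once per cross, even if it fills both slots) by the total
number of crosses. Classes default to high ≥ 20%, medium ≥ 5%.
Concordance between two frequency tables is Pearson r (and r²) over
shared species.

The shipped 28-cultivar parentage panel transcribes published
breeding-route records. Eleven of its rows lack the printed route and
cluster-label cells in the available source; all 28 rows carry the
four per-cultivar yes/no indicators. `panel_aggregation` therefore
recomputes indicators from the row-local labels where present —
raising if a recomputed indicator ever contradicted a recorded one —
and takes the recorded indicator otherwise; the headline percentages
are straight shares over the 28 evaluable rows. Per-row labels are
kept exactly as printed, including one internal inconsistency in the
source's group assignment of a parent species across rows.

## Trend correlations

Pearson r between an ordinal coding and per-taxon trait means, with
two-sided p from `t = r√((n−2)/(1−r²))` on n−2 df. Section order
codes sections 1 (ancient) → 5 (derived) over species only; rank
order codes species 1, cultivar 2, which makes r the point-biserial
coefficient and its p identical (to 1e-10, asserted in tests) to a
pooled-variance two-sample t-test. Correlations run on per-taxon
means because replicates of one taxon pseudo-replicate a
between-taxon question; a replicate-level option exists and logs a
warning. Raw p-values are reported by default; Holm adjustment is
available behind a flag.

## Synthetic generator

The generator emulates the study conditions the analyses assume, with
defaults frozen to a realistic *Malus*-like panel: 23 species + 84
cultivars, 30 replicates per indicator, species trait means uniform
inside the observed spans (P 29.44–52.35 µm, E 20.95–29.64 µm,
S 560.25–1108.89 µm², RW 0.13–0.25 µm, FW 0.04–0.28 µm,
PD 0–11.18 µm⁻²), E drawn through the shape ratio so P/E stays inside
its observed 1.22–2.21 span and E′/E inside 0.80–0.87, 32.7% of
species with perforation-free exines (PD mean exactly 0), aberrant
rates uniform over 0–95.6%, within-taxon CV 0.10 for size/ridge
traits and 0.20 for the patchier FW and PD.

Replicates are `max(0, Normal(mean, cv·mean))`; truncation at zero
rather than a log-normal keeps the CV interpretation simple and is
adequate at cv ≤ 0.25 (at much higher cv it biases the realized CV
downward — documented, not corrected). No within-taxon distribution
family is implied by the statistics themselves; normality is an
assumption of the generator only.

Cultivars inherit `w·parentA + (1−w)·parentB` (w = 0.5 by default;
single-parent crosses use the known parent alone) plus relative
Gaussian noise (`progeny_noise_sd`, default 5% — a relative scale
keeps one knob meaningful across traits spanning four orders of
magnitude), and PD is additionally multiplied by the drift factor δ
(default 1.5 ≥ 1, reproducing the low-to-high progression of
perforation density across generations as a ratio-style effect).
About 35% of routes get an unnamed second parent, matching the
visible share in the reference panel. A weak additive section effect
(−0.8 µm per section step, applied to P, E and S only — size is the
only trait with a reported section trend) emulates the
large-to-small drift along sections without forcing significance at
a 23-species panel.

Randomness flows from one integer seed through per-stage
`numpy.random` sub-streams (taxa, pedigree, replicates), so identical
configs are byte-identical and stages do not perturb one another.

`generate_family_study` builds the stress-test for pedigree scoring:
families of two parent species plus midparent cultivars, with family
centres spaced `separation` (default 3) within-family standard
deviations apart on every trait axis, each trait grading the families
in its own random order so any two families differ on several axes.
Parent scatter and midparent noise each get half the within-family
budget, keeping taxon means inside the advertised separation.

What the generator does **not** emulate: measurement error structure
of real SEM work (operator effects, grain orientation), correlations
among traits beyond the built-in P/E and E′/E coupling, aberrant-
grain morphology classes, or polyploidy effects. Passing tests on
synthetic data therefore demonstrate correctness of the statistics
and the pipeline, not that real panels will show the same effect
sizes.

## Problem sizes and numerical choices

The test suite and acceptance script run at the study's native scale
where that is cheap (23 + 84 taxa, 30 replicates) and at reduced
scale where many repetitions are needed: CV recovery uses 50 taxa ×
30 replicates, null calibration of the section-trend test 1000
replicates of a 23-species panel, the clustering oracle all-pairs
brute force at n ≤ 8, and family-aggregation recovery 100 seeded runs
of 4 families × 7 taxa with 10 replicates. Ties in the dendrogram cut
are broken by merge height then cluster size; CLD letter order by
descending group mean then label; modal-label ties accept both
labels. Degenerate inputs (empty pedigrees, all-zero traits,
constant features, single-taxon groups) raise typed errors or report
missing values rather than guessing.

## Known limitations

- The uniformity average weights every taxon equally regardless of
  replicate count; ragged tables are accepted (≥ 2 replicates) with a
  logged warning but no reweighting.
- Tukey HSD assumes homoscedastic groups; for strongly heteroscedastic
  traits (PD) the letters are indicative, not exact.
- Section aggregation's modal rule is one of several defensible
  counting rules; alternatives can change the percentage by a few
  points on small panels.
- The clustering is a single deterministic partition; no bootstrap
  support values are computed.
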