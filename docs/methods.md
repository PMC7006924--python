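# Methods

## Search-database construction

Transcript contigs (alphabet A/C/G/T/N, case-insensitive) are translated
with the standard genetic code in frames +1/+2/+3 and, on the reverse
complement, −1/−2/−3. Stop codons split each frame's translation into
segments rather than being translated through as `*`: search engines
require stop-free entries, and a minimum identifiable peptide of six
residues implies segment-level filtering, so the default `min_len` is 6.
Codons containing N translate to `X` instead of breaking the segment,
preserving flanking context for the search engine; trailing partial codons
are dropped. Entry ids follow `source|transcript|frame|segment-index` so
provenance stays machine-parsable.

"Nonredundant" is implemented as exact full-sequence duplicate removal
(first occurrence kept, dropped ids logged). No similarity clustering is
attempted — the convention behind published "nonredundant" six-frame
databases is ambiguous, and exact collapse is the only choice that cannot
merge genuinely distinct entries. Because the convention for counting
database entries is equally ambiguous, the build summary reports both
contigs × 6 frame translations and the stop-split segment count.

## Reporter-ion quantification

Quantifiability gates, applied jointly in one pass over PSMs, all strict
as stated: identification score ≥ 1.3 (the 95%-confidence cutoff of the
Paragon "unused" score; inclusive, per that software's convention),
peptide unique to one protein, peptide length ≥ 6, summed reporter
signal-to-noise over the 8 channels strictly > 9. Each rejection reason is
tallied; filtering is idempotent.

Aggregation of reporter intensities across a protein's spectra is **sum**
by default (intensity-weighted, the behavior of summing reporter areas),
with median exposed as an alternative; the upstream software's internal
aggregation is not documented, so both plausible conventions are
available. The denominator is the arithmetic mean of the two
ambient-control channel aggregates; every channel's ratio divides by it,
making ratios invariant under global intensity scaling and the two control
ratios average exactly 1. Channels with zero aggregate get ratio 0 and are
excluded from log-ratio lists (counted per record); proteins whose both
control aggregates are zero are excluded with a logged reason, never
silently dropped. A control-concordance report flags proteins whose two
control channels disagree by more than |log₂| = 1 — a diagnostic default,
configurable, and never used to drop data automatically.

Per-peptide log₂ ratios (peptide aggregate over that peptide's own control
mean) are retained per channel; they are the inputs to the replicate
tests. Out of scope by design: peak picking, isotope-impurity correction,
and protein inference beyond discarding shared peptides.

## Differential abundance

Per protein × treated replicate channel, the peptide-level log₂ ratios are
tested two-sided against 0. The default is a one-sample t-test; a Wilcoxon
signed-rank alternative is exposed. The test producing replicate p-values
is a genuinely open design point — the original workflow's internal test
is undocumented — so both are first-class and the choice is a parameter.
Degenerate inputs do not crash: fewer than two ratios → p = 1 flagged
`untestable`; identical ratios → p = 1 flagged `degenerate_variance`.

Replicate p-values are pooled with Fisher's combined probability
(χ² = −2 Σ ln pᵢ, df = 2k, upper-tail chi-square). The fold change is the
geometric mean of replicate ratios (mean in log₂ space), appropriate for
multiplicative quantities. Support gates — ≥ 3 distinct peptides
(minimum across runs) and 4 testable replicate channels — are eligibility
filters applied before significance; failing proteins are reported
`ns`/`insufficient_support` rather than omitted. Status uses strict
inequalities: up iff FC > 1.5 and p < 0.05; down iff FC < 0.5 and
p < 0.05. No multiple-testing correction is applied across proteins,
matching the published procedure. Note that consistent small p-values
reinforce under Fisher's method (combined p decreases with k) only for
p₀ ≲ e⁻¹; replicated weak evidence (e.g. p = 0.5) dilutes instead — the
suite asserts both behaviors.

The packaged 61-protein result table (fold change and p per treatment,
symbiont flag; checksum-verified) is reanalyzed by re-applying exactly
these thresholds per treatment and partitioning the two significant sets;
this reproduces every headline count (15 = 14 up + 1 down for brevetoxin;
52 = 37 up + 15 down for live cells; 6 shared; union 61; unique splits
8/1 and 32/14; 3 symbiont-derived). The table's p-values are stored
verbatim and only thresholded, so their exact provenance does not affect
the reanalysis.

## Ecological statistics

- **Flume preference**: the sample unit is the larva; its two side-swapped
  2-min periods (24 observations each at 5-s intervals) are pooled, so a
  side-sticking larva scores exactly 50%. Proportions are reported in
  percent.
- **KS two-sample**: D = sup|ECDF₁ − ECDF₂|; exact enumeration p when
  min(n, m) ≤ 5 (both exact and asymptotic reported there), asymptotic
  otherwise.
- **Two-way ANOVA**: balanced fixed-effects layout, Type-I sums of squares
  (orthogonal under balance, hence equal to Type II/III); unbalanced or
  empty cells are errors naming the cells. A constant response defines
  F := 0 (the 0/0 ratio carries no evidence of effect). Verified against
  statsmodels `anova_lm` in the suite. Tukey's HSD uses statsmodels'
  studentized-range implementation.
- **Scheirer–Ray–Hare**: responses replaced by mid-ranks (ties averaged);
  the same balanced two-way SS decomposition is computed on ranks;
  H = SS_effect / MS_total with MS_total = SS_total/(N−1), referred to
  chi-square with the effect's df. Computing MS_total from the actual rank
  variance applies the canonical tie correction; with a single-level
  second factor the statistic equals tie-corrected Kruskal–Wallis to
  1e-9, which the suite asserts against scipy.
- **Mann–Whitney U**: exact null distribution for groups of ≤ 8 without
  ties, normal approximation with continuity correction otherwise;
  Bonferroni adjustment is min(1, p × m).
- **Arcsine square root**: percentages are converted to proportions before
  transforming.

## Synthetic data: what it emulates and what it does not

The PSM generator mirrors the experimental design: two independent 8-plex
runs (tags 113–121), controls on 113/117, methanol carrier on 114/118,
brevetoxin on 115/119, live cells on 116/121, replicates 1–2 and 3–4 in
runs 1 and 2. The intensity model is the standard one for isobaric data:
protein baselines log-normal (log₂ mean 10, sd 1.5), peptide ionization
offsets (log₂ sd 1.2), multiplicative biological noise per
protein × replicate channel (CV 10%) and measurement noise per reading
(CV 20%), spiked treatment effects as multiplicative fold changes
(default 1.5 — the smallest change the gates can call, making recovery a
boundary test), S/N as intensity over a constant run noise floor (300,
set so a realistic minority of low-intensity spectra fail the S/N gate),
identification scores Normal(4, 2) truncated at 0 (≈ 9% below the 1.3
cutoff), 1–12 peptides per protein with 1–3 spectra each, and 5% of
peptides shared between two proteins. Defaults use 500 proteins, a
desk-scale subset of the ~1,290 quantified in the emulated study.

The generator does **not** simulate raw spectra, chromatography, isotope
impurity between adjacent reporter channels, ratio compression from
co-isolation, or missing channels. Passing tests therefore demonstrate
the correctness of the filtering/quantification/testing chain under the
assumed noise model, not robustness to those instrument-level artifacts —
on real data, ratio compression in particular biases fold changes toward
1, and the spike-recovery results here should be read as an upper bound.

In the exact noise-free limit the generator's ratios are exactly 1 (no
spike) or exactly the spiked fold change; peptide ratios are then
identical within a channel, so the degenerate-variance rule (p = 1) makes
spiked proteins non-significant by construction. The noise-free check
accordingly asserts exact fold-change recovery, not status recovery.

Flume trials draw each 5-s observation Bernoulli(p_cue); phenotype
responses are Gaussian around treatment × time cell means (n = 5 units
per cell, matching the assay design), clipped to [0, 1] for proportions.

## Problem sizes and numerical choices

The acceptance computation uses 500 proteins for spike recovery (~70
spiked calls evaluated), 2000 null replicates for the factorial
type-I-error estimates (4 treatments × 2 times × 5 units, standard
Gaussian response), and 100 larvae for the flume baseline; the whole run
completes in under a minute on one CPU. p-values from degenerate tests are
clamped into (0, 1] before Fisher pooling (log 0 is undefined); the tiny
positive floor is the double-precision minimum. Partition identities
(|A ∪ B| = |A| + |B| − |A ∩ B|, unique sets disjoint from shared) are
asserted property-style on random inputs.

## Known limitations

Exact-duplicate collapse only (no <100% identity clustering); no
MeOH-treatment reference table is packaged (its values are not printed in
the emulated study's main text, though the reanalysis supports any table
with the same columns); printed F/H statistics of the behavioral assays
are not reproducible because the underlying field data are unpublished,
so the factorial tests are validated by oracle equivalence and simulated
type-I error instead.
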