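# Methods

This note documents the models, statistics, and design choices behind
`epipersist`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Coordinates and tiling

All coordinates are 0-based half-open (BED convention) internally;
1-based formats (Bismark coverage) are converted at the reader boundary.
Analyses run on dense fixed-width tilings — 2 kb for ChIP signal, 100 bp
for methylation — with tile ids 0..T−1 in chromosome order. The final
tile of each chromosome keeps the remainder width; downstream coverage
filters remove unreliable tiles, so nothing is gained by dropping it.
Because 100 divides 2,000, every methylation tile maps into exactly one
ChIP tile by containment. Strand is ignored throughout: all tile
statistics are unstranded.

Distance from a tile to a feature is 0 on any overlap (half-open
semantics: [0,100) and [100,200) do *not* overlap) and otherwise the
smallest absolute distance from the tile midpoint to a feature edge.
The midpoint-to-edge convention is a package decision — distance-to-
feature plots in the literature rarely state their metric — chosen so
tests can assert exact values. Queries on chromosomes without features
return an explicit no-neighbor sentinel (−1), never a silent zero, and
are excluded (with their count reported) from distance tests.

## ChIP tile signal and changed tiles

Signal per tile is `max(0, chip·10⁶/L_chip − input·10⁶/L_input) ·
(L_chip/10⁶)`: both libraries scaled to reads per million, input
subtracted with negatives clamped to zero, then re-scaled by the inverse
of the ChIP RPM factor so that signal stays on the ChIP count scale and
between-region variation is not damped. The implementation folds the
algebra to `max(0, chip − input·L_chip/L_input)`, which is identical and
makes the all-zero-input identity (signal == raw counts) exact in floating
point.

log2FC uses a pseudocount (default 1.0 on the count scale) so zero-signal
tiles stay finite without distorting high-signal tiles. The per-tile
p-value is the exact conditional binomial test: given n = case + control
counts, the case count is Binomial(n, f/(1+f)) under the null, with f the
library-size ratio. The test is applied to the **raw ChIP counts**, not
to the input-subtracted signal: the conditional-binomial model is exact
for Poisson counts, whereas subtracted signal carries additional input
noise that inflates the test badly (in within-genotype null comparisons,
testing subtracted signal called roughly a third of all tiles). q-values
are Benjamini–Hochberg per comparison.

A tile is called changed when |log2FC| > 0.5 and q < 0.1 **in both
biological replicates** with consistent sign, and is excluded when the
same rule fires in either within-genotype comparison (control vs control,
mutant vs mutant) — the within-genotype criterion reuses the main rule,
a package decision where the original analysis does not state one.

The metagene anchors on the top 5% of tiles ranked by **control** signal
(ties broken by tile id); ranking on the control avoids selection-induced
regression to the mean in the mutant. For each offset within ±flank
tiles the mean ± SE of log2FC and the median signal are reported; offsets
crossing a chromosome boundary are dropped for that anchor.

## Differential methylation

Per-CpG methylated/total counts are summed within 100-bp tiles per
sample; opposite-strand CpG records are merged by the reader when a
strand column is present. A tile enters the universe only if **every**
sample covers it with ≥ 10 reads (the tool convention behind "covered by
at least 10 reads"); this retained-tile universe is the denominator of
every overlap statistic downstream.

The per-tile test is the likelihood-ratio (G) test of the group term in a
binomial regression against the intercept-only model. Within-group ML
fits are the pooled group proportions, so the deviance equals the G
statistic of the pooled 2×2 table; the replicate structure enters through
the dispersion model. Three dispersion options:

- `none` — plain binomial LRT;
- `scale` — G divided by a single global quasi-binomial factor (median
  per-tile Pearson X²/df, floored at 1);
- `shrink` (default) — G divided by a per-tile factor moderated toward
  the global one with a prior weight of 4 pseudo-degrees of freedom,
  `phi_t = max(1, (4·phi0 + X²_t)/(4 + S − 2))`, chi-square reference.

The default matters. With beta-binomially overdispersed replicates (the
generator's default, rho = 0.02), the uncorrected test is strongly
anti-conservative: on a 5,000-tile null simulation roughly 6% of tiles
reach q < 0.05 and thousands of false DMRs appear in planted runs. The
global scale restores calibration but lets individual tiles with large
between-replicate disagreement leak through, which surfaces as residual
sperm×soma overlap under label permutation. The moderated per-tile scale
— the empirical-Bayes practice of few-replicate count methods — penalises
exactly those tiles while keeping full power elsewhere (measured at the
default conditions: null q<0.05 fraction 0.2%, planted recovery ~90%,
permutation overlap at the hypergeometric expectation; across seeds,
planted-tile detection runs ~78–89%, mean ~85%). q-values are
Benjamini–Hochberg; DMR status is q < 0.05.

Tiles overlapping known strain-variant positions (C>T/G>A differences
that confound bisulfite conversion) are removed from DMR sets. Clustered
significant tiles (single linkage, start-to-start distance < 1 kb) are
thinned to one uniformly-chosen representative per cluster of ≥ 2 — a
*feature-characterization* step, so a multi-tile region is not weighted
repeatedly in distance/enrichment/motif analyses. Thinning is **not**
applied before the persistence intersection: thinning each tissue
independently could pick different representatives of the same cluster
and destroy genuinely shared tiles. The "more than two tiles … one was
selected" phrasing of the source protocol is internally inconsistent for
pairs; clusters of size ≥ 2 are thinned, with `min_cluster_size`
configurable.

## Persistence

Sperm and soma DMR sets live on the same 100-bp grid, so intersection is
exact tile identity. The shared count k is tested against
Hypergeometric(N, K, n) over the intersection of the two covered
universes: expectation K·n/N, upper-tail p computed by log-gamma
summation with logsumexp, accurate for tails far beyond double-product
underflow (the motivating analysis prints p ≈ 1e-121). Shared DMRs are
classified by the signs of their two deltas; per-region "positive
correlation" is operationalized as sign concordance, and the
concordant-hypermethylated subset is the persistent set. Pearson R (with
a t-test on n−2 df) is computed over the deltas of *all* shared DMRs.
Cross-tissue recurrence builds the 2×2 of persistent-set × tissue-DMR
membership over the covered universe — the table construction is a
package decision — and reports overlap fraction, odds ratio (infinite
when the tissue set contains the whole persistent set; reported, not an
error), Fisher p, and the delta correlation on the overlap.

## Fisher and the other shared statistics

The two-sided Fisher test uses the point-probability definition: the sum
of probabilities of all same-margin tables whose point probability does
not exceed the observed one. For grand totals ≤ 1000 the comparison runs
on exact integer weights C(r1,x)·C(r2,c1−x), so ties (e.g. the symmetric
[[3,0],[0,3]] table, p = 0.1 exactly) contribute exactly rather than
through a float epsilon; larger tables use scipy's implementation.
Mann–Whitney uses midrank ties, exact enumeration for small tie-free
samples (both ≤ 20) and the tie-corrected normal approximation otherwise.
Benjamini–Hochberg is the plain step-up rule; it replaces the SLIM
q-values of the original RRBS tooling (undocumented there), and this
deviation is recorded in every output header and the run manifest. The
one-sample proportion test is the normal score test without continuity
correction.

## Motif enrichment

PWMs (MEME minimal format, read via Biopython) are scanned as log-odds
against a uniform base background (configurable to the observed 0-order
composition), on both strands; windows containing N are discarded; a tile
is a hit when its best window reaches `score_fraction` (default 0.8) of
the motif's maximum achievable score. Enrichment of hits in a query tile
set against the covered-tile control set is a two-sided Fisher test per
motif, Bonferroni-corrected over the number of motifs tested. This is a
transparent re-statement of binding-site enrichment testing — hit
classification plus Fisher — rather than a replication of any specific
scanner's internal ranking; results are therefore comparable in kind, not
in exact p, to published scanner outputs.

## The synthetic-data generator

The generator is a pure function of its config (seed included): same
seed, same bytes. Defaults define a desk-scale study that completes in
well under a minute per stage on one CPU:

- **Genome**: two 2-Mb chromosomes → 2,000 ChIP tiles, 40,000 methylation
  tiles. Small enough for minutes-scale end-to-end runs, large enough
  that BH thresholds and overlap expectations behave like genome-scale
  ones.
- **ChIP**: control intensity log-normal (σ = 0.6) with 5% of tiles as
  high-signal peaks (×8); mutant multiplies peaks by d = 0.6 and adds
  g = 0.3 × median intensity elsewhere — the flattening. Counts are
  Poisson per replicate (2 per genotype, nominal depth 10⁶); input is
  flat. Peaks default to single tiles so the metagene flanks are
  background tiles; domain length is configurable.
- **RRBS**: CpGs placed Bernoulli at 0.05/bp (~5 per covered tile) —
  reduced-representation libraries cover CpG-dense fragments, so covered
  tiles carry several CpGs; modeling genome-average density (~1–2 per
  100 bp) would misstate per-tile coverage, which is what powers the
  test. Tile baselines Beta(6.5, 3.5) (mean 65%, matching the ~65%
  global methylation of sperm); per-sample proportions beta-distributed
  around the tile value (rho = 0.02); per-CpG totals negative-binomial
  (mean 30, size 10); 3 + 3 samples per tissue. 150 planted sperm DMR
  tiles (hyper:hypo 14:1, echoing the strong hypermethylation bias of
  germline DMRs), shifted ±30 percentage points (clipped to [2%, 98%]),
  placed with ≥ 2 kb separation, half preferentially inside ChIP-changed
  tiles; 80% carry the same shift in soma (Bernoulli per tile), plus 100
  soma-specific planted DMRs.
- **Features**: TSS, CpG islands, repeats, gene bodies uniform; 80% of
  200 enhancers placed within 500 bp of persistent-truth tiles; 200
  1-bp strain variants uniform (a configurable fraction can be targeted
  into planted DMR tiles to exercise masking; default 0).
- **Sequences**: i.i.d. background at GC 0.42; one 8-bp consensus
  (per-base mutation rate 0.05) embedded in 40% of persistent-truth
  tiles and 2% of other tiles; decoy PWMs never embedded.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no read-level artifacts (mapping bias, PCR
duplicates, bisulfite-conversion error), no genuine genomic sequence
(CpG islands and repeats are position tracks, not sequence features), no
correlated methylation along the genome beyond tile boundaries, no
embryonic reprogramming dynamics (persistence is a per-tile Bernoulli
flag, not a mechanism), and no cell-type heterogeneity within a tissue.
Recovery percentages on synthetic data are statements about the
statistical machinery under the stated noise model, not about biological
sensitivity.

## Numerical and procedural choices

- Hypergeometric tails: log-gamma summation + logsumexp; overflow-free by
  construction; exact-rational enumeration agreement to 1e-12 relative
  error verified for all draws with N ≤ 30.
- Ties in top-k selections (metagene anchors, top-changed regions) break
  by tile id — deterministic.
- Degenerate inputs fail loudly: all-zero 2×2 tables, empty samples,
  zero-variance correlations, empty persistent sets, zero pseudocount
  with zero signal, CpGs outside the layout (named in the error).
- Both-counts-zero in the conditional binomial returns p = 1 by
  convention.
- Run outputs contain no timestamps; the manifest records config, seeds,
  SHA-256 digests per stage, and standing method notes (BH vs SLIM, the
  coverage and thinning interpretations), so reruns are byte-identical
  and auditable.
- Seeding: every stage derives its generator from the config seed via
  SeedSequence with a fixed stage key; thinning uses its own stream so
  adding a stage never shifts another stage's draws.

## Known limitations

- With 3 replicates per group, per-tile dispersion is barely estimable;
  the moderated scale is a pragmatic compromise, not a full beta-binomial
  likelihood. Very strong per-tile overdispersion can still slip through.
- The conditional binomial treats ChIP counts as Poisson; biological
  replicate variability beyond Poisson is handled only through the
  two-replicate consistency rule, not the per-tile test.
- Percent-scale delta planting interacts with the [2%, 98%] clip: planted
  shifts at high baselines are attenuated, which is why detection
  averages ~85% rather than ~100% at the default conditions.
- Exact Fisher enumeration is O(min(margin)); above a grand total of 1000
  the scipy fallback's float tie handling applies (irrelevant at that
  scale).
- The persistence analysis matches tiles by identity; it will not connect
  signals that straddle tile boundaries between the two tissues.
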