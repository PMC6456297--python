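# epipersist

Tile-based analysis of histone-mark redistribution in the germ line and of
DNA-methylation changes that persist into offspring somatic tissue.

## The problem

Loss of a germline chromatin regulator — the motivating case is the
H3K27me3 demethylase KDM6A in mouse spermatogenesis — does not simply add
or remove a mark. It *redistributes* it: the highest-signal regions lose
H3K27me3 while the rest of the genome gains it ("flattening"), and the
regions most perturbed become prone to DNA hypermethylation in mature
sperm. A subset of these hypermethylated regions can then be found, with
the same direction of change, in somatic tissues of the next generation —
candidate carriers of an inherited epigenetic state with phenotypic
consequences (e.g., tumor susceptibility).

`epipersist` implements the complete quantitative chain needed to make
such claims from count data, for epigenomicists who have tile-level ChIP
counts and per-CpG bisulfite counts and need reproducible, calibrated
statistics:

1. **ChIP tile signal** on 2-kb tiles: reads-per-million scaling, input
   subtraction clamped at zero, re-scaling by the inverse of the ChIP RPM
   factor; per-tile s = max(0, c·10⁶/L_c − i·10⁶/L_i) · L_c/10⁶.
2. **Changed-tile calls**: log2FC = log2((s_case+c)/(s_ctrl+c)), an exact
   conditional-binomial p per tile on the raw counts, BH q-values, and the
   replicate rule |log2FC| > 0.5 & q < 0.1 in *both* replicates, excluding
   tiles called within genotype. A top-5% metagene profiles the
   flattening.
3. **Differential methylation** on 100-bp tiles: per-CpG counts summed per
   tile, tiles kept only with ≥ 10 reads in every sample, then a binomial
   likelihood-ratio (G) test of the group term with a per-tile moderated
   quasi-binomial dispersion (empirical-Bayes shrinkage toward the global
   median), FDR < 0.05, strain-variant masking and random thinning of
   clustered tiles.
4. **Persistence**: sperm and soma DMR sets intersected by tile identity;
   the overlap k tested against Hypergeometric(N, K, n) with expectation
   K·n/N (log-space tail, stable to p ~ 1e-300); shared DMRs classified by
   sign concordance — the concordant-hypermethylated subset is the
   *persistent* set; Pearson R of the two effect sizes; cross-tissue
   recurrence as Fisher odds ratios.
5. **Feature and motif association**: distance-to-nearest-feature
   distributions vs the covered-tile background (Mann–Whitney), overlap
   fractions and windowed proximity (Fisher), and PWM scanning (log-odds,
   both strands, hit at 80% of the maximum score) with per-motif Fisher
   enrichment against the full covered-tile control set, Bonferroni
   corrected.
6. **Synthetic data**: a seeded generator for every input format the
   pipeline reads, with planted truth (flattened ChIP landscape,
   concordant hypermethylated DMRs, enhancers placed near persistent
   tiles, strain variants, motif-bearing tile sequences), so the whole
   chain is testable end to end without any download.

## Worked example

`python examples/05_full_pipeline.py` simulates the default desk-scale
study (two 2-Mb chromosomes; 2 ChIP replicates per genotype; two tissues ×
3 + 3 RRBS samples; 150 planted sperm DMR tiles of which 80% persist in
soma) and runs every stage:

```
covered-tile universe: 39639
sperm DMRs: 261
soma DMRs: 395
shared DMRs: 91 (expected 2.6, hypergeometric p = 2.87e-116)
delta correlation: R = 0.863, p = 4.09e-28
concordant-hyper: 88 (97%)
concordant-hypo: 3 (3%)
discordant: 0 (0%)
persistent DMRs (concordant-hyper): 88

planted sperm DMR tiles detected: 83%
planted persistent tiles recovered: 79%
metagene log2FC at the top-signal tiles: -0.69; one tile away: +1.37  (loss at peaks, gain alongside)
top motif: planted_TF (adjusted p = 3.8e-19)
```

Reading this: 91 tiles were significantly differentially methylated in
both tissues where ~2.6 would be expected by chance over the 39,639-tile
covered universe; nearly all are hypermethylated in both (the planted
persistence signal); the metagene shows the flattening signature (loss at
the highest-signal tiles, gain in their flanks); and the motif embedded in
persistent-truth tiles is the only one enriched against the full covered
control set.

The other examples (`examples/01..04`) walk through single capabilities:
tile signal arithmetic, DMR calling, persistence classification, motif
enrichment. The same stages are scriptable from a shell via the thin
`epipersist` CLI (`simulate`, `run-all`, `validate`, `chip-signal`,
`dmr`).

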