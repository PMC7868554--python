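# locus2gene

Statistical prioritization of candidate genes in disease-associated loci,
with downstream *trans*-regulation analysis — built for GWAS + eQTL
integration studies in which a genotyped cohort with expression data (an
eQTL panel) is combined with case/control GWAS summary statistics to decide
**which gene in each associated region is likely causal, in which direction
its expression acts on risk, and which distant genes it regulates**.

The package implements a complete, reusable pipeline:

1. **Regions** — greedy LD clumping of GWAS hits (p < 5×10⁻⁶, r² > 0.5,
   ±250 kb), exclusion of the extended MHC interval, ±1 Mb flanks merged
   into non-overlapping associated regions, and overlap-based candidate
   genes.
2. **eQTLs** — single-variant cis mapping in a ±1.5 Mb window, plus exact
   forward-stepwise selection of conditionally independent cis instruments
   (entry at p < 5×10⁻⁶, LD collinearity guard).
3. **Prioritization** — four lines of evidence per gene:
   - *MR-IVW*: with instruments *j*, Wald ratios θ̂ⱼ = β_Y(j)/β_X(j),
     se(θ̂ⱼ) = se_Y(j)/|β_X(j)|, combined as
     θ̂ = Σwⱼθ̂ⱼ / Σwⱼ with wⱼ = se(θ̂ⱼ)⁻², se(θ̂) = (Σwⱼ)^(−1/2);
     Cochran's Q heterogeneity and a weighted-median sensitivity estimate
     with bootstrap SE; Bonferroni control across testable genes
     (0.05/162 ≈ 3.1×10⁻⁴ at the reference scale).
   - *Colocalization*: Wakefield log-ABF = ½[log(1−r) + rZ²] per variant
     and trait (r = W/(W+V)), enumerated over H0–H4 with priors
     p1 = p2 = 10⁻⁴, p12 = 10⁻⁵; a gene colocalizes when PP(H4) > 0.9.
   - *LD overlap*: r² > 0.8 between the top independent eQTL and the top
     GWAS variant of the region.
   - *External co-regulation evidence* (e.g. a DEPICT FDR < 0.05 call),
     consumed as a per-gene column.
   A gene is prioritized with ≥ 1 significant line, and receives an effect
   direction (+/−/?) from a six-rule procedure over the top variants with an
   MR override.
4. **Co-regulation clusters** — Fisher-Z profile correlations against a
   gene × component co-regulation matrix, Ward clustering cut at k = 4.
5. **Trans-mediation** — trans-eQTLs (p < 5×10⁻⁸) whose variant lies in an
   associated region and whose gene lies outside all regions, filtered by
   co-expression (|r| > 0.1) with the region's prioritized genes, tested
   with the Freedman–Schatzkin statistic
   T = (β_unadj − β_adj) / √(se_u² + se_a² − 2·se_u·se_a·√(1−ρ²)),
   where ρ = corr(dosage, mediator expression); Bonferroni per pair.
6. **Gene-set permutation DE statistic** — for a knockdown validation
   experiment, the median |T| of a gene set is compared against
   random same-size sets in a control and a knockdown contrast; the ratio of
   exceedance percentages (control ÷ knockdown) is the set's fold-change in
   differential expression, immune to within-set co-expression.

A first-class synthetic-cohort generator (`locus2gene.syndata`) plants
block-LD genotypes, cis effects, a master-regulator mediation chain,
liability-threshold GWAS phenotypes, shared/distinct colocalization
scenarios, and shifted DE gene sets — so every stage has a ground-truth
recovery test.

## Worked example

Generate a small synthetic cohort with planted truth and run the full
pipeline:

```bash
locus2gene fixture --scale tiny --seed 1 --out demo
locus2gene run --config demo/config.yaml
```

```
regions: 3  candidate genes: 3  prioritized: 2
```

The consolidated evidence table (`demo/results/evidence.tsv`) shows the
planted architecture recovered:

```
gene_id         region_id   mr_ivw  coloc  ld_overlap  depict_external  lines_of_evidence  direction
cis_distinct_b  region_002  NT      false  false       NT               0                  +
cis_shared_a    region_001  NT      true   true        true             3                  +
mediator_gene   region_003  true    true   true        NT               3                  +
```

`cis_shared_a` (its eQTL and GWAS signals share one causal variant) is
prioritized with three lines of evidence; `cis_distinct_b` (planted with
*different* causal variants for expression and disease) is correctly not
colocalized (PP(H3) ≈ 0.98) and gets no line of evidence; the master
regulator is prioritized via MR (three independent instruments), and the
mediation scan (`mediation_summary.tsv`) flags all five of its planted
trans targets:

```
mediator_gene  n_pairs  n_significant  mean_z_diff
mediator_gene  5        5              10.51907894
```

Positive `mean_z_diff` means the trans-association Z scores collapse once
the mediator's expression is adjusted for — the signature of a genuine
mediated effect.  Finally, the permutation DE statistic on the planted
knockdown set (`permde.json`): the set's observed median |T| is beaten by
57.1% of random sets in the control contrast but only 0.02% in the
knockdown contrast, a fold-change of 2854 — the knockdown hit exactly this
gene set.

All stage outputs are plain TSV/BED/JSON plus a `manifest.yaml` recording
every threshold used; two runs with the same config are byte-identical.

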