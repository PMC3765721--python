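# teexon

Quantification and statistical analysis of the expression (retention) of
**transposable-element-derived exons** (TE exons) in mRNA from bulk RNA-seq
data.

Roughly 44% of the human genome derives from transposable elements (Alu, L1,
MIR, L2, ...), and the *exonization* of TE sequence is a major source of novel
exons. Most TE exons are alternatively spliced and weakly retained, so their
expression is hard to measure and highly variable across tissues. `teexon`
implements an exon-level pipeline that makes this measurable and testable:

1. **Exon classes.** Annotated gene exons are split into constitutive non-TE
   exons (**C1**), cassette non-TE exons (**C2**, present in a known
   alternative-exon table) and annotated TE exons (**C3**, exact-coordinate
   matches of an exonized-TE table). TE-table entries without an annotated
   counterpart are the un-annotated TE exons (**C4**). For every C4 exon a
   decoy exon (**C5**) of equal length is simulated immediately downstream in
   the intron; C5 expression estimates the pre-mRNA/DNA background.
2. **Rescaled RPKM.** For exon *i* of gene *g* with read count
   *n<sub>i</sub>*, exon length *L<sub>i</sub>* (bp) and *N* filtered reads,

   RPKM<sub>i</sub> = n<sub>i</sub> / (L<sub>i</sub>/10³ · N/10⁶),
   expr(g) = mean of RPKM over g's annotated (C1–C3) exons,
   rescaled RPKM<sub>i</sub> = min(RPKM<sub>i</sub> / expr(g), 10).

   The rescaled RPKM proxies the exon's inclusion rate in the host gene's
   transcripts; by construction a gene's annotated exons average to 1.
   Genes are called *expressed* per sample when expr(g) reaches the 0.95
   nearest-rank quantile of 500 *fictional genes* assembled from 4–40 C5
   decoys each; all statistics are restricted to expressed genes.
3. **Class statistics.** Per sample and class: the un-expressed ratio R, and
   mean M / SD of the rescaled RPKMs of exons with ≥ 1 read, plus a stepwise
   test ladder (Mann–Whitney for C1–C2, C2–C3, C3–C4; paired Wilcoxon
   signed-rank for C4–C5).
4. **Two-step hurdle regression.** With location indicators **R**
   (CDS baseline; UTR3, UTR5), family indicators **F** (Alu baseline; ERV1,
   ERVL, L1, L2, MaLR, MER1, MER2, MIR), ℓ = log₁₀ exon length (ELN) and
   c = TE nucleotide proportion (RTE):

   - Model-1 (logistic): logit P(z<sub>i</sub> = 1) = μ + **R**α + **F**β + γℓ<sub>i</sub> + φc<sub>i</sub>, where z indicates ≥ 1 read;
   - Model-2 (OLS): log₁₀ y<sub>j</sub> = μ\* + **R**α\* + **F**β\* + γ\*ℓ<sub>j</sub> + φ\*c<sub>j</sub> + e<sub>j</sub> over the exons with y<sub>j</sub> > 0.

   The same design is reused for cross-sample summary fits on the per-exon
   median (m) and coefficient of variance (v), whose Kendall correlation
   quantifies the level-vs-variability relationship.
5. **Enrichment.** TE exons with rescaled RPKM > 0.25 in ≥ 2 samples are
   *highly expressed*; per TE family, a Fisher exact test probes whether high
   expression is associated with C2H2 zinc-finger (ZNF) host genes.

A fully parameterized synthetic-data generator (`teexon.simulate`) produces
annotations, covariates, 26 group-labelled pseudo-samples and
hurdle-structured counts with recorded ground truth, so every stage is
testable without external downloads.

## Worked example

```python
from teexon import simulate, quantify, class_stats, hurdle, variability

ds = simulate.simulate_dataset(simulate.GeneratorConfig(seed=1))
samples = [quantify.quantify_sample(ds.annotation, sample_id=c,
                                    counts=ds.counts[c],
                                    total_filtered_reads=int(ds.library_sizes[c]))
           for c in ds.counts.columns]

tab = class_stats.class_summary_table(samples, ds.annotation)
print(tab[tab.sample_id == "Brain"][["exon_class", "R", "M", "SD", "p_step"]])
```

```
exon_class     R     M    SD  p_step
        C1 0.031 1.089 0.162     NaN
        C2 0.089 0.949 0.146     0.0
        C3 0.229 0.633 0.804     0.0
        C4 0.493 0.189 0.351     0.0
        C5 0.824 0.011 0.015     0.0
```

Reading the table: going down the ladder C1 → C5 the fraction of exons with
no reads (R) rises from 3% to 82% while the mean retention (M) of the
detected exons falls from ≈ 1 (constitutive exons, the normalization anchor)
to ≈ 0.01 (intronic decoys); every step is highly significant (`p_step`).
The hurdle fit on the same sample recovers the planted genomic-factor
effects:

```python
fit = hurdle.two_step_fit(samples[-2], ds.annotation)   # the "Brain" sample
print(fit.n1, fit.n2)                                   # 1381 756
print(fit.model2.loc[["UTR5", "MIR", "log10ELN", "RTE"]].round(3))
```

```
          estimate     se    p
UTR5         0.445  0.035  0.0
MIR          0.544  0.049  0.0
log10ELN    -0.313  0.071  0.0
RTE         -0.964  0.077  0.0
```

i.e. 5′UTR location and MIR ancestry raise the expression level of a TE exon,
while exon length and the TE nucleotide proportion depress it. Across
samples, the per-exon median and CV are negatively associated:

```python
mat  = variability.build_expression_matrix(samples, ds.annotation,
                                           ds.samples).subset_classes("C3", "C4")
disp = variability.dispersion_summary(mat, min_samples=13)
print(variability.kendall_tau(disp["m"], disp["v"]))    # tau = -0.588, p = 3.5e-212
```

A thin CLI wraps the same pipeline: `teexon simulate --out data/ --seed 1`
writes a dataset directory, and `teexon analyze --dataset data/ --out res/`
writes the class-summary, coefficient, dispersion and enrichment tables.

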