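# markernom

Multi-omics biomarker nomination and immunohistochemistry (IHC) diagnostic
validation, built as a reusable, tested pipeline with a synthetic-data
generator that plants a known ground truth.

## The problem

Rare fusion-driven tumors often lack a fast, specific diagnostic marker:
diagnosis falls back on molecular testing. One way out is to nominate a
single surrogate marker gene by intersecting independent omics evidence,
then validate an antibody read-out on a large case/mimic cohort. The
pipeline implements that strategy end to end for a cohort design with one
target entity (e.g. a fusion-defined sarcoma such as DSRCT) against a panel
of morphological mimics:

1. **Transcriptomic gate** — one-vs-rest differential expression per gene:
   log2FC = mean(target) − mean(rest), two-sided Mann-Whitney p (exact
   enumeration with midranks when both groups ≤ 8, tie-corrected normal
   approximation otherwise), Benjamini-Hochberg adjustment; pass when
   log2FC > 2.5 and P<sub>adj</sub> < 0.01.
2. **Regulatory gate** — fusion-factor ChIP peaks assigned to every gene
   whose strand-aware TSS lies within 100 kb of a peak edge.
3. **Proteomic gate** — knockdown-vs-control Welch t per protein and cell
   line, BH within line; a protein is concordant when |log2FC| > 1.0 and
   P<sub>adj</sub> < 0.01 with the same sign in every line.
4. **Nomination** — the triple intersection, prioritized by median
   target-entity expression with pairwise rank-sum comparisons.
5. **Signatures** — an anchor-gene correlation set (top-*n* Pearson
   correlates within the target entity) and a knockdown-derived
   fusion-activated set; samples and single cells scored by single-sample
   GSEA, ES = Σ<sub>i</sub> [P<sub>in</sub>(i) − P<sub>out</sub>(i)] with
   member weights rank<sup>α</sup> (α = 0.25); preranked GSEA with a seeded
   gene-sampling permutation null, NES = ES / mean|ES<sub>null</sub>| of
   matching sign.
6. **Super-enhancers** — ROSE-style stitching (gap ≤ 12.5 kb) and the
   rank-signal tangent cutoff: regions sorted ascending by signal,
   x<sub>i</sub> = i/n, y<sub>i</sub> = s<sub>i</sub>/s<sub>max</sub>,
   cutoff at argmax (x<sub>i</sub> − y<sub>i</sub>).
7. **Methylation** — CpGs in a gene ± flank window, PCA embedding,
   silhouette of target vs rest, rank-sum hypomethylation test.
8. **IRS diagnostics** — immunoreactive score = staining intensity (0–3) ×
   banded positive-cell proportion (0–4); sensitivity/specificity at every
   integer cutoff and the workflow rule "compatible with the target entity
   iff IRS > 1".

Every stage runs on a bundled synthetic multi-omics generator whose
defaults plant two biomarker genes (+4 log2 one-vs-rest shift, −2 log2 on
knockdown, a bound enhancer peak), a 50-gene coexpression module, a heavy-
tailed H3K27ac landscape, target-specific CpG hypomethylation, and an IHC
cohort whose target samples score 6–12 while mimics score ≈ 0.

## Worked example

```bash
markernom run-all --seed 42 --outdir demo/
```

prints

```
candidates: G0890, G1100
super-enhancers: 29
signature correlation r = 0.962
specificity at IRS>1: 97.6%
```

The two candidates are exactly the planted biomarkers (the triple
intersection removed all 2,000 − 2 background genes); 29 stitched enhancer
regions exceed the tangent cutoff, covering all 12 planted super-enhancer
regions plus the legitimate tail of the exponential background; the
anchor-correlation and knockdown signatures — both tracking the same
planted program — correlate at r = 0.96 across the 80-sample cohort; and on
the 61-case / 249-mimic IHC cohort with 2% contamination, the IRS > 1 rule
is 97.6% specific while every cutoff ≤ 6 keeps 100% sensitivity.

Stage-level subcommands (`simulate`, `deg`, `dep`, `annotate-peaks`,
`se-call`, `nominate`, `signature`, `ssgsea`, `gsea`, `methyl`,
`irs-curve`) expose the same operations on plain TSV/BED/GMT files; the
same functions are importable from Python:

```python
from markernom import generate_multiomics, deg_one_vs_rest

bundle = generate_multiomics(seed=42)
table, passing = deg_one_vs_rest(bundle.expression, "DSRCT")
```

## Layout

```
src/markernom/
  config.py       pipeline configuration + run log
  containers.py   ExpressionMatrix, PeakSet, GeneSet, IRSRecord, ...
  io.py           TSV / BED / GMT readers and writers
  synthdata.py    planted-truth multi-omics generator
  diffomics.py    rank-sum test, BH, DEG / DEP gates
  regulatory.py   peak-to-gene assignment, stitching, SE cutoff
  nominate.py     triple intersection + prioritization
  signatures.py   anchor / knockdown signatures, ssGSEA, preranked GSEA
  methylome.py    CpG selection, PCA separation, hypomethylation test
  diagnostics.py  IRS, diagnostic curves, workflow rule
  pipeline.py     run-all orchestration
  cli.py          click entry points
```

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
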