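# ahisplex

Pigmentation phenotyping of low-coverage and ancient genomes from
reference-based diploid genotypes.

Most ancient-DNA samples are sequenced at 0.1–2× genome coverage, far too
sparse for the diploid genotype calls that forensic eye/hair/skin-colour
prediction systems require.  The practical route is genotype *imputation*:
infer diploid genotypes of the 41 pigmentation markers from the sparse
pseudo-haploid observations plus a phased haplotype reference panel, then
feed them to the 41-marker prediction model.  `ahisplex` provides the
tooling around that route for bioinformaticians working on archaeogenetic
or degraded forensic samples:

* **translate** — convert reference-based VCF genotypes of the 41 markers
  into probe-based allele counts.  The assay reports the count (0/1/2) of
  a *probe-counted* allele expressed on the strand the PCR probe was
  designed on, so reverse-strand probes need a reverse-complement mapping;
  matching against the marker catalog is positional (normalized
  chrom/pos/ref/alt), never by ID string.
* **pvalues** — evaluate the 14 phenotype probabilities (3 eye + 4 hair
  colour + 2 hair shade + 5 skin) with a multinomial-logistic model
  `p_k = exp(η_k) / Σ_j exp(η_j)`, `η_k = α_k + Σ_i β_ki·x_i`, where `x_i`
  is the probe allele count; missing markers drop out of the linear
  predictor, and hair is not predicted at all when all 11 MC1R markers are
  missing.  Coefficients are user-supplied configuration; a clearly
  synthetic demo model ships for testing.
* **classify** — map the 14 p-values to categorical phenotypes (3 eye / 8
  hair / 12 skin categories) with a versioned, data-driven rule file that
  encodes darker-tone precedence; every call carries a `rule_trace` for
  audits.  The web service's downloaded batch-result file is accepted as an
  alternative p-value source.
* **windows** — build the imputation target regions: ±2.5 Mb around each
  marker, merged, extended to ≥5 Mb minimum, emitted as BED.
* **evaluate** — genotype concordance with the two error notions used in
  imputation validation (*total error*: any diploid mismatch; *opposite
  error*: HOMREF↔HOMALT flips), replicate phenotype concordance, red-hair
  false-positive/negative rates, per-site imputation variability, and
  flagging of sample×marker combinations whose error stays ≥15% at high
  coverage (the signature of reference-panel bias).
* **simulate** — a fully synthetic harness: an LD-bearing mosaic haplotype
  panel, diploid individuals, Poisson pseudo-haploid reads with optional
  C>T/G>A damage noise, and a deliberately naive panel-based imputer used
  as a test oracle (not a scientific substitute for a production engine
  such as GLIMPSE2, which can be hooked in as an external command).

## Worked example

Simulate a small cohort around the bundled GRCh38 catalog and run the
pipeline (the demo model is synthetic — the phenotypes below validate the
machinery, not any real individual):

```
$ ahisplex simulate --preset small --seed 7 --out fixtures
wrote fixtures/panel.vcf and fixtures/truth.vcf (410 sites, 10 individuals)

$ ahisplex run --vcf fixtures/truth.vcf --out results
upload_csv: results/HISplex41_upload.csv
pvalue_csv: results/pvalues.csv
phenotype_tsv: results/phenotypes.tsv
run_log: results/run_log.json

$ cat results/phenotypes.tsv
sampleid  eye     hair    skin            rule_trace
ind000    blue    blonde  pale/darker     eye:argmax=blue;hair:base=blond;skin:base=pale;skin:darker_tail=0.574>=0.3
ind001    blue    brown   pale/darker    eye:argmax=blue;hair:base=brown;skin:base=pale;skin:darker_tail=0.549>=0.3
ind003    blue    brown   dark            eye:argmax=blue;hair:base=brown;skin:base=dark
...
```

`HISplex41_upload.csv` holds each sample's 41 probe allele counts (the
file a batch phenotyping service consumes), `pvalues.csv` the 14
probabilities per sample plus the missing-marker count, and
`phenotypes.tsv` one categorical call per trait with the fired rules —
e.g. `ind000` is called `pale/darker` because the darker-tone tail mass
0.574 exceeded the 0.3 modifier threshold.

The imputation regions:

```
$ ahisplex windows --out regions.bed
wrote regions.bed (10 windows, 55,427,376 bp)
$ head -3 regions.bed
5   31451587   36458854
6   0          5000000
9   10209304   19358083
```

## Layout

```
src/ahisplex/
  catalog.py     marker catalog + per-build translation tables (data in data/)
  translate.py   VCF genotypes -> probe allele counts (upload CSV)
  model.py       14-p-value multinomial-logistic engine
  classify.py    rule-driven eye/hair/skin classification
  windows.py     slop/merge/extend imputation windows, BED I/O
  metrics.py     total/opposite error, concordance, red-hair confusion
  simulate.py    synthetic panel, pseudo-haploid reads, naive imputer
  workflow.py    pipeline orchestration + external imputation hook
  cli.py         `ahisplex` subcommands
docs/methods.md  model, assumptions, parameter choices, limitations
docs/formats.md  file format schemas (catalog TSV, model/rules YAML, ...)
```
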