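# Methods

## The problem

Forensic pigmentation phenotyping predicts eye, hair and skin colour from
diploid genotypes at 41 autosomal markers.  Ancient and degraded samples
rarely support direct diploid calling: coverage is low (0.1–2×), fragments
are short, and post-mortem deamination injects C>T / G>A transitions.  The
workable route is reference-panel imputation of the 41 markers from sparse
pseudo-haploid data, followed by the standard prediction model.  This
package implements everything around the imputation engine itself: allele
translation, the probability model, rule-based classification, imputation
window construction, and the validation machinery, plus a synthetic
harness that exercises the whole path offline.

## Marker catalog and strand-aware translation

Each marker is defined by per-build coordinates (GRCh37/hg19 and
GRCh38/hg38 families; chromosome naming dialect is normalized at load),
forward-strand ref/alt alleles, the probe strand, the probe-counted
allele, a variant class, a global minor allele frequency and trait tags.
The probe-based count of a diploid call is the number of alleles equal to
the counted allele mapped onto the forward strand (reverse-complemented
for reverse-strand probes).  The single red-hair-associated duplication
(rs312262906) is treated as a biallelic variant whose alt is the
duplication; VCF spellings are reconciled by prefix-first variant
normalization so anchor-base and left-aligned indel representations
compare equal.  VCF matching is by normalized (chrom, pos, ref, alt) with
the rsid as a cross-check only, because ID fields are unreliable;
multiallelic records are decomposed and only the catalog alt is counted.
Genotypes with one missing allele are conservatively treated as missing.

The shipped catalog is a curated fixture assembled from the published
41-marker system; the code treats it strictly as data and validates it on
load (41 unique rsids, unique sites per build, counted-allele/strand
consistency, exactly 11 MC1R-tagged markers, seven of them with global
MAF < 1.5%).  rs201326893 carries a per-build "may be absent" flag for
GRCh38-based joint call sets — a warning, not an error.

## The 14-p-value model

Four independent multinomial-logistic groups: eye (blue, intermediate,
brown), hair colour (blond, brown, red, black), hair shade (light, dark),
skin (very pale, pale, intermediate, dark, dark-black) — 14 probabilities.
With reference category η = 0,

    η_k = α_k + Σ_i β_ki · x_i,     p_k = exp(η_k) / Σ_j exp(η_j),

where x_i is the probe allele count.  The maximum η is subtracted before
exponentiation (overflow guard).  Missing markers are dropped from the
linear predictor — the published system accepts partial input, but its
exact missing-data algebra is not public, so this rule is isolated in one
function and the number of missing markers is always reported next to the
probabilities.  When all 11 MC1R markers are missing the system does not
predict hair at all: both hair groups are undefined and flagged, never
silently uniform.  The same applies to any group whose referenced markers
are all missing.

Published coefficient sets are entered by the user in the documented YAML
schema; the bundled `demo_model.yaml` is synthetic (plausible signs,
invented magnitudes) and exists only so the test suite and examples can
run end to end.  Some sources label the eye categories blue/brown/black
rather than blue/intermediate/brown; category labels are configuration in
both the model and rules files, so either dialect can be transcribed.

## Classification rules

Eye colour is the argmax of its three probabilities.  Hair combines the
hair-colour argmax with dark-shade thresholds into 8 categories; red takes
precedence whenever it attains the maximum.  Skin picks the base tone by
argmax and then a lighter/darker modifier from the probability *tail mass*
lying strictly lighter or darker than the base, giving 12 categories.
Two deliberate choices encode the scheme's darker-tone precedence and make
it testable:

* exact ties resolve to the darker category;
* the darker modifier fires on tail mass (≥ 0.3 by default) rather than on
  the runner-up category alone.  Because the darkest category is always in
  the darker tail, shifting probability mass onto it can never lighten a
  call — a property the suite checks over random simplex points.

The full decision tree of the official manual is not in the open
literature, so the rule engine is data-driven: a versioned YAML file
supplies orders, thresholds and display labels, validated for totality at
load time (never at classify time).  The shipped `rules_default.yaml` is
an explicit approximation pending transcription from the manual; its
thresholds (dark-shade mild/strong/black = 0.5/0.7/0.9, darker tail 0.3,
lighter tail 0.6) were chosen once for plausible behaviour on the demo
model and are not fitted to anything.  Every call records the fired rules
(`rule_trace`) so misclassifications can be traced to a specific rule.

## Imputation windows

Reference-panel imputation needs flanking-marker context, so each marker
position is extended by 2.5 Mb on both sides, overlapping or book-ended
intervals are merged, and any merged window under 5 Mb (markers near
telomeres or centromeres get clipped) is extended away from the clipped
end — or symmetrically when unclipped — until it reaches 5 Mb or exhausts
the chromosome; a chromosome shorter than 5 Mb becomes one whole-chromosome
window.  Marker positions are 1-based internally; BED output is 0-based
half-open.  On the shipped GRCh38 catalog this yields 10 disjoint windows
(55.4 Mb): nine marker clusters each merge into one window per chromosome,
and chromosome 15 splits into the OCA2/HERC2 cluster and the SLC24A5
locus.  Merging is verified against a per-base union oracle on toy
chromosomes.

## Validation metrics

*Total error* counts every imputed diploid genotype differing from truth;
*opposite error* counts only HOMREF↔HOMALT flips, the class with maximal
phenotypic impact under any inheritance model, so opposite ≤ total by
construction (asserted).  Truth-missing sites are excluded from
denominators; a missing test genotype at a defined truth site is a total
error.  Red-hair confusion pools individual×replicate comparisons:
FN = truth-red comparisons classified non-red over truth-red comparisons,
FP symmetric.  Imputation variability is 1 − modal-genotype frequency per
sample×marker across replicates.  Reference-bias flagging marks
sample×marker combinations whose mean error across the high coverages
(original, 2×, 1×) is ≥ 15% — errors that persist when data is plentiful
point at the panel, not at missingness — and reports the fraction of all
errors the flagged set carries.  `ReplicateDesign` encodes the standard
layout: coverages 10×/2×/1×/0.5×/0.1×, 10 downsampling × 10 imputation
replicates.

## Synthetic harness

The generator emulates the study ingredients without downloads:

* **Panel** — haplotypes are Li-Stephens-style mosaics over a few founder
  haplotypes; a per-site switch rate of 0.02 (default for catalog-embedded
  panels) produces strong adjacent-site LD, while a rate of 1.0 reproduces
  the independent-sites expectation r² ≈ 1/(n_hap − 1).  Catalog-embedded
  panels place the 41 markers at their true coordinates among common
  filler SNPs (5 kb spacing) and use each marker's global MAF (floored at
  0.03 so rare alleles exist in small panels) as its panel frequency.
* **Individuals** — pairs of panel haplotypes (optionally recombined
  mosaics).  With exact copies, the truth haplotypes are present in the
  panel — the regime in which the naive imputer must recover truth
  exactly, the keystone correctness test.
* **Observations** — reads per site ~ Poisson(coverage), each read drawing
  one of the two chromosomes uniformly: the pseudo-haploid regime.  The
  fraction of covered sites is 1 − e^(−c) (9.5% at 0.1×, 39.3% at 0.5× —
  the looser "half the markers at 0.5×" reading found in some descriptions
  is not what the Poisson model gives).  Damage noise flips a C-read to T
  (G to A) with probability `pmd_rate` when the flip lands on the site's
  allele pair — a per-read simplification of fragment-end damage curves,
  sufficient to exercise the error and robustness paths.
* **Naive imputer** — scores every unordered panel haplotype pair by the
  count of reads incompatible with the pair's genotype (a read conflicts
  only with an opposite homozygote), keeps the k = 5 best pairs (score
  ties broken by a seeded random order — the source of replicate-to-
  replicate imputation variability), and reports the per-site majority
  genotype, ties resolving to HET; an individual with no reads falls back
  to the per-site Hardy–Weinberg argmax.  This is a desk-scale test oracle
  for the package's own machinery, *not* a reimplementation of, or
  substitute for, a production imputation engine; real analyses hook such
  an engine in via the workflow's external-command template.

What the harness does not model: recombination maps, fragment-length and
end-position damage profiles, contamination mixtures, reference-genome
errors.  Passing tests therefore demonstrate the correctness of
translation, modelling, classification and metric code and the qualitative
coverage/error behaviour — not the quantitative accuracy of any real
imputation engine on real ancient data.

## Numerical and design choices

* All randomness flows through explicit integer seeds (numpy Generator /
  SeedSequence); identical seeds give byte-identical outputs, which the
  end-to-end test asserts.
* Softmax is computed with max-subtraction; group probabilities sum to 1
  within 1e-9 (property-tested).
* Upload CSV dialect (column spellings `<rsid>_<counted allele>`, sample
  column, NA token) lives in `data/upload_dialect.yaml`, since the hosted
  service's exact header spelling is not reproduced in the open
  literature.
* Degenerate inputs fail loudly: wrong marker count, duplicate rsids or
  sites, non-finite coefficients, non-total rule files, contig-free VCFs,
  undefined trait groups at classification.
* Problem sizes in the test suite and acceptance script (panels of 40–200
  haplotypes, 300–10,000 sites, 3×3 replicate grids over 0.1×/0.5×/2×)
  were chosen as the smallest sizes at which the checked effects are
  statistically unambiguous.

## Known limitations

* The bundled demo model must never be used for real prediction; the
  published coefficient set has to be supplied by the user.
* The default rule thresholds approximate, not transcribe, the official
  manual's decision tree.
* The curated catalog coordinates are configuration data; users should
  verify them against their reference builds before production use, and
  rs201326893 may be absent from GRCh38-based joint reference sets.
* The naive imputer's error rates (several percent at low coverage on
  synthetic panels) are far above what a production engine achieves; they
  are meaningful only for exercising the metric and classification paths.
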