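# File formats

## Marker catalog TSV (`src/ahisplex/data/markers_<family>.tsv`)

One file per build family (`grch37` covers GRCh37 and hg19, `grch38`
covers GRCh38 and hg38; the chromosome-name dialect — `16` vs `chr16` —
is applied at load time).  Tab-separated with header:

| column          | type / values                                  |
|-----------------|------------------------------------------------|
| rsid            | marker identifier, unique                      |
| chrom           | chromosome name (plain dialect)                |
| pos             | 1-based position on the family's build         |
| ref_allele      | forward-strand reference allele                |
| alt_allele      | forward-strand alternate allele (for the single-base duplication: ref doubled) |
| probe_strand    | `forward` \| `reverse`                         |
| counted_allele  | allele symbol the probe counts, probe strand   |
| variant_class   | `snp` \| `single_base_dup`                     |
| global_maf      | float in [0, 0.5]                              |
| trait_tags      | comma-joined subset of `eye,hair,skin,mc1r`    |
| may_be_absent   | comma-joined build names, may be empty         |

Validation on load: exactly 41 rows, unique rsids and (chrom, pos) sites,
counted allele maps onto ref or alt on the forward strand, exactly 11
`mc1r` tags.

## Chromosome lengths TSV (`chrom_lengths_<family>.tsv`)

Columns `chrom`, `length` (bp, > 0); one row per chromosome carrying
markers.

## Upload dialect (`upload_dialect.yaml`)

`sample_column`, `na_token`, `probe_column_pattern` — the spellings used
by the probe-count upload CSV.  Probe columns are
`<rsid>_<counted_allele>` in catalog order; missing counts are written as
the NA token.

## Model coefficients YAML

```yaml
version: <tag>
groups:
  eye:                       # also: hair_colour, hair_shade, skin
    categories: [blue, intermediate, brown]
    reference: blue          # category with eta = 0
    coefficients:
      intermediate:          # one block per non-reference category
        intercept: -2.0
        rs12913832_T: 1.2    # probe-name -> dosage coefficient
      brown: { ... }
```

All four groups are required (3/4/2/5 categories); every probe must exist
in the catalog; coefficients must be finite.

## Classification rules YAML

```yaml
version: <tag>
eye:
  order_light_to_dark: [blue, intermediate, brown]
  labels: {blue: blue, ...}
hair:
  order_light_to_dark: [blond, red, brown, black]
  red_category: red
  shade_dark_category: dark
  thresholds: {mild: 0.5, strong: 0.7, black: 0.9}
  labels:
    blond: {base: blonde, mild: dark-blonde/blonde, strong: dark-blonde/brown}
    ...
skin:
  order_light_to_dark: [very_pale, pale, intermediate, dark, dark_black]
  darker_tail_threshold: 0.3
  lighter_tail_threshold: 0.6
  labels:
    pale: {lighter: pale/lighter, base: pale, darker: pale/darker}
    ...
```

Totality is checked at load: every category needs a base label, the red
category must be in the colour order, thresholds must be known names.

## p-value CSV (native dialect)

`sampleid`, then `p_<group>_<category>` for all 14 probabilities in fixed
group order (eye, hair_colour, hair_shade, skin), then
`n_missing_markers` and `hair_available` (0/1).  Undefined groups are NA
cells.  The classifier also accepts the web batch-download dialect
(`sampleid`, `PBlueEye`, `PIntermediateEye`, ..., `PDarkBlackSkin`).

## Phenotype TSV

`sampleid`, `eye`, `hair`, `skin`, `rule_trace` (fired rules joined by
`;`).  Hair is `unavailable` when all 11 MC1R markers were missing;
undefined groups yield `undefined`, never a silent default.

## Genotype call TSV (evaluate inputs)

`sample`, `rsid`, `gt_class` (`HOMREF|HET|HOMALT|MISSING`) plus optional
grouping columns (`coverage`, `replicate`, `source`, ...).

## Workflow config YAML

Keys mirror `WorkflowConfig`: `build`, `catalog_path`, `rules_path`,
`model_path`, `chrom_lengths_path`, `external_impute_command` (template
with `{input}`/`{output}` and optional `{region}`, or `none`), `out_dir`,
`seed`, `log_level`.  CLI flags override config values.
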