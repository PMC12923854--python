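"""Strand-aware genotype -> probe-count translation and the upload file."""

import itertools

import pysam
import pytest

from ahisplex.catalog import MarkerDef, counted_allele_forward, probe_name
from ahisplex.translate import (
    ConfigurationError,
    GenotypeCall,
    GTClass,
    HisplexRow,
    TranslationError,
    read_upload_csv,
    translate_genotype,
    upload_header,
    vcf_to_rows,
    write_upload_csv,
)

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def snp(rsid="rsX", ref="A", alt="G", strand="forward", counted=None, chrom="1", pos=100):
    counted = counted if counted is not None else (alt if strand == "forward" else COMP[alt])
    m = MarkerDef(rsid, chrom, pos, ref, alt, strand, counted, "snp", 0.2)
    m.validate()
    return m


def call(marker, alleles, sample="s1"):
    return GenotypeCall.from_alleles(sample, marker.rsid, alleles, marker)


def test_forward_het_counts_one():
    m = snp(ref="A", alt="G", strand="forward", counted="G")
    assert translate_genotype(call(m, ("A", "G")), m) == 1


def test_reverse_strand_homalt_counts_two():
    # forward ref=C alt=T; probe on reverse strand counts A (= complement of T)
    m = snp(ref="C", alt="T", strand="reverse", counted="A")
    assert counted_allele_forward(m) == "T"
    assert translate_genotype(call(m, ("T", "T")), m) == 2


def test_missing_genotype_is_na():
    m = snp()
    assert translate_genotype(call(m, ()), m) is None


def test_dup_marker_het_counts_one():
    dup = MarkerDef("rs312262906", "16", 89919344, "A", "AA", "forward", "A",
                    "single_base_dup", 0.00078)
    dup.validate()
    c = GenotypeCall.from_alleles("s1", dup.rsid, ("A", "AA"), dup)
    assert c.gt_class == GTClass.HET
    assert translate_genotype(c, dup) == 1


def test_foreign_allele_raises_with_context():
    m = snp(ref="A", alt="G")
    bad = GenotypeCall("s1", m.rsid, GTClass.HET, ("A", "T"))
    with pytest.raises(TranslationError, match=r"s1/rsX.*'T'"):
        translate_genotype(bad, m)


def test_rsid_mismatch_rejected():
    m = snp()
    with pytest.raises(TranslationError, match="does not match"):
        translate_genotype(GenotypeCall("s1", "rsY", GTClass.HOMREF, ("A", "A")), m)


def _brute_force_count(marker, alleles):
    """Independent mapper: complement the counted allele if the probe is on
    the reverse strand, then count equal alleles."""
    target = marker.counted_allele
    if marker.probe_strand == "reverse":
        target = COMP[target]
    return sum(1 for a in alleles if a == target)


def test_dosage_conservation_exhaustive():
    """Enumerate strand x ref/alt pair x counted x genotype x allele order."""
    bases = "ACGT"
    n_checked = 0
    for ref, alt in itertools.permutations(bases, 2):
        for strand in ("forward", "reverse"):
            for counted_fwd in (ref, alt):
                counted = counted_fwd if strand == "forward" else COMP[counted_fwd]
                m = snp(ref=ref, alt=alt, strand=strand, counted=counted)
                for pair in itertools.product((ref, alt), repeat=2):
                    got = translate_genotype(call(m, pair), m)
                    assert got == _brute_force_count(m, pair)
                    # dosage conservation in alt units
                    n_alt = sum(1 for a in pair if a == alt)
                    expected = n_alt if counted_fwd == alt else 2 - n_alt
                    assert got == expected
                    # phase / allele order invariance
                    assert got == translate_genotype(call(m, pair[::-1]), m)
                    n_checked += 1
    assert n_checked == 12 * 2 * 2 * 4


# --- VCF extraction ---------------------------------------------------------

def make_vcf(path, catalog, sample_gts, skip_rsids=(), multiallelic=None,
             dup_anchor=False, contig_prefix=""):
    """Write a small VCF holding the catalog sites.

    *sample_gts*: {sample: {rsid: (i, j) allele-index pair or None}}.
    *multiallelic*: rsids whose record carries a decoy first ALT, making the
    catalog alt the second ALT (allele index 2).
    """
    multiallelic = set(multiallelic or ())
    header = pysam.VariantHeader()
    for chrom in sorted({m.chrom for m in catalog}, key=lambda c: (len(c), c)):
        header.contigs.add(contig_prefix + chrom, length=2_000_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    samples = list(sample_gts)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for m in sorted(catalog, key=lambda m: ((len(m.chrom), m.chrom), m.pos)):
            if m.rsid in skip_rsids:
                continue
            if dup_anchor and m.variant_class == "single_base_dup":
                # anchor-base spelling one position left: e.g. CA -> CAA
                alleles = ("C" + m.ref_allele, "C" + m.alt_allele)
                start = m.pos - 2
            else:
                alleles = (m.ref_allele, m.alt_allele)
                start = m.pos - 1
            if m.rsid in multiallelic:
                decoy = next(b for b in "ACGT" if b not in (m.ref_allele, m.alt_allele[0]))
                alleles = (alleles[0], decoy, alleles[1])
            rec = vcf.new_record(contig=contig_prefix + m.chrom, start=start,
                                 alleles=alleles, id=".")
            for s in samples:
                gt = sample_gts[s].get(m.rsid)
                rec.samples[s]["GT"] = gt if gt is not None else (None, None)
            vcf.write(rec)
    return path


def _expected_count(marker, n_alt):
    target_is_alt = counted_allele_forward(marker) == marker.alt_allele
    return n_alt if target_is_alt else 2 - n_alt


def test_vcf_all_sites_called_no_nas(tmp_path, catalog38):
    gts = {"s1": {m.rsid: (0, 1) for m in catalog38}}
    vcf = make_vcf(tmp_path / "a.vcf", catalog38, gts)
    rows = vcf_to_rows(vcf, catalog38, "GRCh38")
    assert len(rows) == 1
    assert sum(v is None for v in rows[0].counts.values()) == 0
    for m in catalog38:
        assert rows[0].counts[probe_name(m)] == _expected_count(m, 1)


def test_vcf_missing_sites_become_na(tmp_path, catalog38):
    skipped = [m.rsid for m in catalog38[:20]]
    gts = {"s1": {m.rsid: (0, 0) for m in catalog38}}
    vcf = make_vcf(tmp_path / "b.vcf", catalog38, gts, skip_rsids=skipped)
    rows = vcf_to_rows(vcf, catalog38, "GRCh38")
    nas = [p for p, v in rows[0].counts.items() if v is None]
    assert len(nas) == 20
    assert {p.split("_")[0] for p in nas} == set(skipped)


def test_vcf_half_missing_gt_is_na(tmp_path, catalog38):
    target = catalog38[0]
    gts = {"s1": {m.rsid: (0, 1) for m in catalog38}}
    vcf = make_vcf(tmp_path / "c.vcf", catalog38, gts)
    # rewrite the target record with a half-missing genotype
    text = (tmp_path / "c.vcf").read_text().replace("0/1", "./1", 1)
    (tmp_path / "c2.vcf").write_text(text)
    rows = vcf_to_rows(tmp_path / "c2.vcf", catalog38, "GRCh38")
    assert sum(v is None for v in rows[0].counts.values()) == 1


def test_multiallelic_decomposition(tmp_path, catalog38):
    target = next(m for m in catalog38 if m.variant_class == "snp")
    gts = {"s1": {target.rsid: (0, 2)}}  # catalog alt is the SECOND alt
    vcf = make_vcf(tmp_path / "d.vcf", [target], gts, multiallelic=[target.rsid])
    rows = vcf_to_rows(vcf, [target], "GRCh38")
    assert rows[0].counts[probe_name(target)] == _expected_count(target, 1)


def test_dup_anchor_representation_matches(tmp_path, catalog38):
    dup = next(m for m in catalog38 if m.variant_class == "single_base_dup")
    gts = {"s1": {dup.rsid: (1, 1)}}
    vcf = make_vcf(tmp_path / "e.vcf", [dup], gts, dup_anchor=True)
    rows = vcf_to_rows(vcf, [dup], "GRCh38")
    assert rows[0].counts[probe_name(dup)] == 2


def test_chr_prefixed_vcf_still_matches(tmp_path, catalog38):
    gts = {"s1": {m.rsid: (1, 1) for m in catalog38}}
    vcf = make_vcf(tmp_path / "f.vcf", catalog38, gts, contig_prefix="chr")
    rows = vcf_to_rows(vcf, catalog38, "GRCh38")
    assert sum(v is None for v in rows[0].counts.values()) == 0


def test_contig_mismatch_is_configuration_error(tmp_path, catalog38):
    weird = [MarkerDef("rsZ", "Z", 100, "A", "G", "forward", "G", "snp", 0.1)]
    gts = {"s1": {"rsZ": (0, 1)}}
    vcf = make_vcf(tmp_path / "g.vcf", weird, gts)
    with pytest.raises(ConfigurationError, match="no catalog contig"):
        vcf_to_rows(vcf, catalog38, "GRCh38")


# --- upload CSV -------------------------------------------------------------

def test_upload_csv_round_trip_and_na_token(tmp_path, catalog38):
    header = upload_header(catalog38)
    r1 = HisplexRow("s1", {p: 1 for p in header[1:]})
    r2 = HisplexRow("s2", {p: 2 for p in header[1:]})
    r2.counts[header[1]] = None
    out = tmp_path / "up.csv"
    write_upload_csv([r1, r2], out, catalog38)
    lines = out.read_text().splitlines()
    assert len(lines) == 3
    assert lines[2].split(",")[1] == "NA"
    again = read_upload_csv(out, catalog38)
    assert [r.sample_id for r in again] == ["s1", "s2"]
    assert again[0].counts == r1.counts
    assert again[1].counts == r2.counts
    # byte stability
    out2 = tmp_path / "up2.csv"
    write_upload_csv([r1, r2], out2, catalog38)
    assert out.read_bytes() == out2.read_bytes()
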