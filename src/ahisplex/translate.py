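"""Reference-based genotypes -> probe-based allele counts (the upload file).

A diploid VCF genotype carries two forward-strand alleles.  The assay
instead reports how many copies of the probe-counted allele a sample
carries, with the counted allele written on the probe's own strand.  The
translation maps the counted allele onto the forward strand
(reverse-complementing for reverse-strand probes), then counts matching
alleles in the call: 0, 1 or 2, with missing genotypes becoming NA.

Matching of VCF records against the catalog is positional — normalized
(chrom, pos, ref, alt) tuples, with the rsid kept only as a cross-check —
because VCF ID fields are unreliable.  Multiallelic records are decomposed
and only the catalog alt allele is considered.  The single-base duplication
marker accepts both anchor-base and left-aligned indel spellings via
variant normalization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import pysam
import yaml

from .catalog import (
    MarkerDef,
    counted_allele_forward,
    normalize_chrom,
    probe_name,
)

__all__ = [
    "GTClass",
    "GenotypeCall",
    "HisplexRow",
    "TranslationError",
    "ConfigurationError",
    "NA_TOKEN",
    "SAMPLE_COLUMN",
    "translate_genotype",
    "vcf_to_rows",
    "write_upload_csv",
    "read_upload_csv",
    "upload_header",
]

# the upload-file dialect (header spellings, NA token) is data, not code
with (resources.files("ahisplex.data") / "upload_dialect.yaml").open() as _fh:
    _DIALECT = yaml.safe_load(_fh)
NA_TOKEN = str(_DIALECT["na_token"])
SAMPLE_COLUMN = str(_DIALECT["sample_column"])


class TranslationError(ValueError):
    """A call allele cannot be reconciled with the marker definition."""


class ConfigurationError(ValueError):
    """Input file and catalog/build disagree (e.g. no shared contigs)."""


class GTClass:
    HOMREF = "HOMREF"
    HET = "HET"
    HOMALT = "HOMALT"
    MISSING = "MISSING"

    ALL = (HOMREF, HET, HOMALT, MISSING)


@dataclass(frozen=True)
class GenotypeCall:
    """One sample x marker diploid genotype on the forward strand."""

    sample_id: str
    rsid: str
    gt_class: str
    alleles: tuple = ()        # ordered pair of forward-strand allele strings
    source: str = "truth"      # truth | imputed | external

    @staticmethod
    def from_alleles(sample_id, rsid, alleles, marker: MarkerDef, source="truth"):
        """Build a call, deriving the genotype class from the allele pair."""
        if not alleles:
            return GenotypeCall(sample_id, rsid, GTClass.MISSING, (), source)
        if len(alleles) != 2:
            raise TranslationError(
                f"{sample_id}/{rsid}: expected a diploid allele pair, got {alleles!r}"
            )
        n_alt = 0
        for a in alleles:
            if a == marker.ref_allele:
                continue
            if a == marker.alt_allele:
                n_alt += 1
            else:
                raise TranslationError(
                    f"{sample_id}/{rsid}: allele {a!r} matches neither ref "
                    f"{marker.ref_allele!r} nor alt {marker.alt_allele!r}"
                )
        gt_class = (GTClass.HOMREF, GTClass.HET, GTClass.HOMALT)[n_alt]
        return GenotypeCall(sample_id, rsid, gt_class, tuple(alleles), source)


@dataclass
class HisplexRow:
    """One sample's 41 probe-based allele counts (the upload record)."""

    sample_id: str
    counts: dict = field(default_factory=dict)  # probe column name -> 0/1/2/None


def translate_genotype(call: GenotypeCall, marker: MarkerDef):
    """Count copies of the probe allele in a diploid call; MISSING -> None."""
    if call.rsid != marker.rsid:
        raise TranslationError(f"call rsid {call.rsid} does not match marker {marker.rsid}")
    if call.gt_class == GTClass.MISSING:
        return None
    target = counted_allele_forward(marker)
    count = 0
    for allele in call.alleles:
        if allele not in (marker.ref_allele, marker.alt_allele):
            raise TranslationError(
                f"{call.sample_id}/{call.rsid}: allele {allele!r} matches neither ref "
                f"{marker.ref_allele!r} nor alt {marker.alt_allele!r}"
            )
        if allele == target:
            count += 1
    return count


def _normalize_variant(pos: int, ref: str, alt: str):
    """Minimal (pos, ref, alt) representation: trim shared prefix, then suffix.

    Trimming the prefix first (down to an empty ref for pure insertions)
    makes the anchor-base spelling ``pos-1 CA>CAA`` and the left-aligned
    spelling ``pos A>AA`` of the single-base duplication compare equal.
    """
    ref, alt = ref.upper(), alt.upper()
    while ref and alt and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        pos += 1
    while ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
    return pos, ref, alt


def _marker_key(marker: MarkerDef):
    return _normalize_variant(marker.pos, marker.ref_allele, marker.alt_allele)


def vcf_to_rows(vcf_path, catalog, build: str = "GRCh38"):
    """Extract and translate the catalog markers from a (multi-sample) VCF.

    Returns one :class:`HisplexRow` per sample.  Markers absent from the VCF,
    or with (half-)missing genotypes, become NA.  Matching is by normalized
    (chrom, pos, ref, alt); multiallelic records are decomposed and only the
    catalog alt is considered.
    """
    by_site = {}
    for m in catalog:
        by_site.setdefault((m.chrom, m.pos), []).append(m)

    with pysam.VariantFile(str(vcf_path)) as vcf:
        header_contigs = {normalize_chrom(c) for c in vcf.header.contigs}
        catalog_contigs = {m.chrom for m in catalog}
        if header_contigs and not (header_contigs & catalog_contigs):
            raise ConfigurationError(
                f"no catalog contig found in VCF header (VCF: {sorted(header_contigs)}, "
                f"catalog build {build}: {sorted(catalog_contigs)})"
            )
        samples = list(vcf.header.samples)
        rows = {s: HisplexRow(s, {probe_name(m): None for m in catalog}) for s in samples}

        for rec in vcf:
            chrom = normalize_chrom(rec.chrom)
            candidates = []
            for m in catalog:
                if m.chrom != chrom:
                    continue
                # positional pre-filter keeps the scan cheap; exact matching below
                if abs(m.pos - rec.pos) <= max(len(rec.ref), 2):
                    candidates.append(m)
            for marker in candidates:
                matched_alt = None
                mkey = _marker_key(marker)
                for alt in rec.alts or ():
                    if _normalize_variant(rec.pos, rec.ref, alt) == mkey:
                        matched_alt = alt
                        break
                if matched_alt is None:
                    continue
                target = counted_allele_forward(marker)
                alt_is_target = target == marker.alt_allele
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or len(gt) != 2 or any(a is None for a in gt):
                        continue  # stays NA (half-missing treated as missing)
                    count = 0
                    for idx in gt:
                        allele = rec.alleles[idx]
                        if allele == matched_alt:
                            count += alt_is_target
                        elif allele == rec.ref:
                            count += not alt_is_target
                        # other alts of a multiallelic record never match the probe allele
                    rows[s].counts[probe_name(marker)] = count
    return [rows[s] for s in samples]


def upload_header(catalog) -> list:
    """Fixed upload-file header: sample column + 41 probe columns in catalog order."""
    return [SAMPLE_COLUMN] + [probe_name(m) for m in catalog]


def write_upload_csv(rows, path, catalog) -> None:
    """Write the probe-count upload CSV (byte-stable for identical input)."""
    header = upload_header(catalog)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            extra = set(row.counts) - set(header[1:])
            if extra:
                raise TranslationError(f"{row.sample_id}: unknown probe columns {sorted(extra)}")
            writer.writerow(
                [row.sample_id]
                + [NA_TOKEN if row.counts.get(col) is None else row.counts[col]
                   for col in header[1:]]
            )


def read_upload_csv(path, catalog):
    """Inverse of :func:`write_upload_csv`."""
    expected = upload_header(catalog)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != expected:
            raise ConfigurationError(
                f"{path}: unexpected upload header; expected {expected[:3]}... "
                f"got {(header or [])[:3]}..."
            )
        for rec in reader:
            counts = {}
            for col, value in zip(header[1:], rec[1:]):
                counts[col] = None if value == NA_TOKEN else int(value)
            rows.append(HisplexRow(rec[0], counts))
    return rows
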