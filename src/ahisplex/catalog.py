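"""Marker catalog: the 41 pigmentation markers and per-build translation tables.

The HIrisPlex-S assay reports, for every marker, the number of copies
(0/1/2) of a *probe-counted* allele expressed on the strand the PCR probe
was designed on.  Reference-based genotype data (VCF) expresses alleles on
the forward strand of a named genome build instead.  This module loads the
catalog that bridges the two representations: per-build coordinates,
forward-strand ref/alt alleles, the probe strand and the probe-counted
allele for each of the 41 markers, together with its variant class
(SNP or the single-base duplication rs312262906), its global minor allele
frequency and trait tags (eye / hair / skin / mc1r).

The catalog is data, not code: it ships as a TSV per build family and is
validated on load.  Chromosome naming follows the build dialect
("16" for GRCh37/GRCh38, "chr16" for hg19/hg38); internally names are
normalized to the plain dialect.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "MarkerDef",
    "ChromLengths",
    "CatalogError",
    "BUILDS",
    "normalize_chrom",
    "build_chrom",
    "revcomp",
    "counted_allele_forward",
    "probe_name",
    "load_catalog",
    "load_chrom_lengths",
    "default_catalog_path",
    "default_chrom_lengths_path",
    "mc1r_subset",
    "write_catalog",
]

#: build name -> (build family, chromosome-name dialect)
BUILDS = {
    "GRCh37": ("grch37", "plain"),
    "hg19": ("grch37", "chr"),
    "GRCh38": ("grch38", "plain"),
    "hg38": ("grch38", "chr"),
}

EXPECTED_MARKER_COUNT = 41
EXPECTED_MC1R_COUNT = 11

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class CatalogError(ValueError):
    """Malformed, incomplete or inconsistent marker catalog."""


@dataclass(frozen=True)
class MarkerDef:
    """One HIrisPlex-S marker on one genome build."""

    rsid: str
    chrom: str                 # normalized (plain) chromosome name
    pos: int                   # 1-based position on the requested build
    ref_allele: str            # forward strand
    alt_allele: str            # forward strand
    probe_strand: str          # "forward" | "reverse"
    counted_allele: str        # probe-strand symbol the assay counts
    variant_class: str         # "snp" | "single_base_dup"
    global_maf: float
    trait_tags: frozenset = field(default_factory=frozenset)
    may_be_absent: frozenset = field(default_factory=frozenset)  # build names

    def validate(self) -> None:
        if self.pos < 1:
            raise CatalogError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        if self.probe_strand not in ("forward", "reverse"):
            raise CatalogError(f"{self.rsid}: bad probe_strand {self.probe_strand!r}")
        if not 0.0 <= self.global_maf <= 0.5:
            raise CatalogError(f"{self.rsid}: global_maf {self.global_maf} outside [0, 0.5]")
        if self.variant_class == "snp":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise CatalogError(f"{self.rsid}: SNP alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise CatalogError(f"{self.rsid}: SNP ref and alt alleles identical")
        elif self.variant_class == "single_base_dup":
            if self.alt_allele != self.ref_allele * 2:
                raise CatalogError(
                    f"{self.rsid}: single-base duplication alt must duplicate ref "
                    f"({self.ref_allele!r} -> {self.alt_allele!r})"
                )
        else:
            raise CatalogError(f"{self.rsid}: unknown variant_class {self.variant_class!r}")
        # the counted allele must land on ref or alt once mapped to the forward strand
        fwd = counted_allele_forward(self)
        if fwd not in (self.ref_allele, self.alt_allele):
            raise CatalogError(
                f"{self.rsid}: counted allele {self.counted_allele!r} "
                f"({self.probe_strand} strand) maps to {fwd!r} on the forward strand, "
                f"which is neither ref {self.ref_allele!r} nor alt {self.alt_allele!r}"
            )


def normalize_chrom(name: str) -> str:
    """Strip a ``chr`` prefix so both naming dialects compare equal."""
    return name[3:] if name.lower().startswith("chr") else name


def build_chrom(name: str, build: str) -> str:
    """Render a normalized chromosome name in the dialect of *build*."""
    _require_build(build)
    plain = normalize_chrom(name)
    return f"chr{plain}" if BUILDS[build][1] == "chr" else plain


def revcomp(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise CatalogError(f"cannot reverse-complement {seq!r}") from exc


def counted_allele_forward(marker: MarkerDef) -> str:
    """The probe-counted allele expressed on the reference forward strand.

    For the single-base duplication the probe counts the duplication itself,
    i.e. the alt allele, regardless of strand (a homopolymer duplication is
    its own reverse complement).
    """
    if marker.variant_class == "single_base_dup":
        return marker.alt_allele
    if marker.probe_strand == "reverse":
        return revcomp(marker.counted_allele)
    return marker.counted_allele


def probe_name(marker: MarkerDef) -> str:
    """Upload-dialect column name for a marker: ``<rsid>_<counted_allele>``."""
    return f"{marker.rsid}_{marker.counted_allele}"


@dataclass(frozen=True)
class ChromLengths:
    """Chromosome name -> length (bp) for one named build."""

    build: str
    lengths: dict

    def __getitem__(self, chrom: str) -> int:
        key = normalize_chrom(chrom)
        if key not in self.lengths:
            raise KeyError(f"chromosome {chrom!r} not in length table for {self.build}")
        return self.lengths[key]

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self.lengths


def _require_build(build: str) -> None:
    if build not in BUILDS:
        raise CatalogError(
            f"unknown build {build!r}; expected one of {sorted(BUILDS)}"
        )


def default_catalog_path(build: str) -> Path:
    _require_build(build)
    family = BUILDS[build][0]
    return Path(str(resources.files("ahisplex.data") / f"markers_{family}.tsv"))


def default_chrom_lengths_path(build: str) -> Path:
    _require_build(build)
    family = BUILDS[build][0]
    return Path(str(resources.files("ahisplex.data") / f"chrom_lengths_{family}.tsv"))


_CATALOG_COLUMNS = [
    "rsid", "chrom", "pos", "ref_allele", "alt_allele", "probe_strand",
    "counted_allele", "variant_class", "global_maf", "trait_tags", "may_be_absent",
]


def load_catalog(path=None, build: str = "GRCh38") -> list:
    """Load and validate the 41-marker catalog for *build*.

    Fails loudly (naming the offending row) on duplicates, malformed rows or
    a wrong marker count.
    """
    _require_build(build)
    if path is None:
        path = default_catalog_path(build)
    markers = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing_cols = set(_CATALOG_COLUMNS) - set(reader.fieldnames or [])
        if missing_cols:
            raise CatalogError(f"{path}: missing columns {sorted(missing_cols)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                marker = MarkerDef(
                    rsid=row["rsid"],
                    chrom=normalize_chrom(row["chrom"]),
                    pos=int(row["pos"]),
                    ref_allele=row["ref_allele"].upper(),
                    alt_allele=row["alt_allele"].upper(),
                    probe_strand=row["probe_strand"],
                    counted_allele=row["counted_allele"].upper(),
                    variant_class=row["variant_class"],
                    global_maf=float(row["global_maf"]),
                    trait_tags=frozenset(t for t in row["trait_tags"].split(",") if t),
                    may_be_absent=frozenset(
                        b for b in (row.get("may_be_absent") or "").split(",") if b
                    ),
                )
                marker.validate()
            except (KeyError, ValueError) as exc:
                raise CatalogError(f"{path} line {lineno}: {exc}") from exc
            markers.append(marker)

    rsids = [m.rsid for m in markers]
    dupes = {r for r in rsids if rsids.count(r) > 1}
    if dupes:
        raise CatalogError(f"duplicate rsid(s) in catalog: {sorted(dupes)}")
    if len(markers) != EXPECTED_MARKER_COUNT:
        raise CatalogError(
            f"expected {EXPECTED_MARKER_COUNT} markers, found {len(markers)}"
        )
    sites = [(m.chrom, m.pos) for m in markers]
    dupe_sites = {s for s in sites if sites.count(s) > 1}
    if dupe_sites:
        raise CatalogError(f"markers share a (chrom, pos) site: {sorted(dupe_sites)}")
    n_mc1r = sum(1 for m in markers if "mc1r" in m.trait_tags)
    if n_mc1r != EXPECTED_MC1R_COUNT:
        raise CatalogError(f"expected {EXPECTED_MC1R_COUNT} mc1r-tagged markers, found {n_mc1r}")
    return markers


def write_catalog(markers, path) -> None:
    """Serialize a catalog back to TSV (round-trips with :func:`load_catalog`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CATALOG_COLUMNS)
        for m in markers:
            writer.writerow([
                m.rsid, m.chrom, m.pos, m.ref_allele, m.alt_allele, m.probe_strand,
                m.counted_allele, m.variant_class, m.global_maf,
                ",".join(sorted(m.trait_tags)), ",".join(sorted(m.may_be_absent)),
            ])


def load_chrom_lengths(path=None, build: str = "GRCh38") -> ChromLengths:
    _require_build(build)
    if path is None:
        path = default_chrom_lengths_path(build)
    lengths = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                chrom = normalize_chrom(row["chrom"])
                length = int(row["length"])
            except (KeyError, ValueError) as exc:
                raise CatalogError(f"{path} line {lineno}: {exc}") from exc
            if length <= 0:
                raise CatalogError(f"{path} line {lineno}: non-positive length {length}")
            lengths[chrom] = length
    return ChromLengths(build=build, lengths=lengths)


def mc1r_subset(catalog) -> list:
    """The 11 MC1R markers that drive red-hair prediction."""
    return [m for m in catalog if "mc1r" in m.trait_tags]
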