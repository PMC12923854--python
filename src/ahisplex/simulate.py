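"""Synthetic data: LD-bearing haplotype panels, diploid individuals,
pseudo-haploid low-coverage observations, and a naive panel-based imputer.

The generator emulates the ingredients of a low-coverage validation study
without any download: a phased reference panel whose haplotypes are
Li-Stephens-style mosaics of a few founders (which induces linkage
disequilibrium between neighbouring sites), diploid test individuals drawn
from the panel, and read-level observations at a chosen mean coverage.
Reads per site are Poisson(coverage); each read samples one of the two
chromosomes uniformly — the pseudo-haploid regime in which, at 1x and
below, most covered markers are represented by a single allele.  Optional
post-mortem-damage noise flips a C-allele read to T (G to A) when the flip
lands on the site's ref/alt pair.

The naive imputer is a deliberately simple test oracle — select the k panel
haplotype pairs most consistent with the observed reads and report the
per-site majority genotype — and is NOT a stand-in of scientific quality
for a production imputation engine.  All randomness flows through explicit
seeds; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .catalog import probe_name
from .translate import GTClass

__all__ = [
    "HaplotypePanel",
    "Individuals",
    "ReadObservations",
    "SimulationError",
    "simulate_panel",
    "panel_from_catalog",
    "sample_individuals",
    "downsample_observations",
    "full_observations",
    "naive_impute",
    "genotypes_to_calls",
    "write_panel_vcf",
    "write_truth_vcf",
    "hw_argmax_genotypes",
]

_BASES = np.array(["A", "C", "G", "T"])
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SimulationError(ValueError):
    pass


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes over sorted biallelic sites."""

    chrom: np.ndarray        # site chromosome names (str)
    pos: np.ndarray          # 1-based positions, sorted within chromosome
    ref: np.ndarray          # forward-strand ref allele per site
    alt: np.ndarray          # forward-strand alt allele per site
    haplotypes: np.ndarray   # (n_hap, n_sites) uint8 in {0, 1}
    mosaic_switch_rate: float
    rsid: np.ndarray = None  # optional per-site marker id ("" for filler)

    def __post_init__(self):
        if self.rsid is None:
            self.rsid = np.array([""] * self.n_sites, dtype=object)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != self.n_sites:
            raise SimulationError("haplotype matrix shape does not match site list")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise SimulationError("haplotype matrix entries must be 0/1")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def af(self) -> np.ndarray:
        """Empirical alt-allele frequency per site."""
        return self.haplotypes.mean(axis=0)


@dataclass
class Individuals:
    """Diploid truth individuals with their (hidden) source haplotypes."""

    sample_ids: list
    haplotypes: np.ndarray   # (n, 2, n_sites) uint8
    panel: HaplotypePanel

    @property
    def genotypes(self) -> np.ndarray:
        """(n, n_sites) alt-allele dosage in {0, 1, 2}."""
        return self.haplotypes.sum(axis=1)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class ReadObservations:
    """Pseudo-haploid read counts per (individual, site).

    ``c0``/``c1`` count reads observing the ref/alt allele after noise;
    ``n_damaged`` counts reads whose allele was flipped by the damage model.
    A site with c0 + c1 == 0 is uncovered.
    """

    c0: np.ndarray           # (n, n_sites) int
    c1: np.ndarray
    n_damaged: np.ndarray
    coverage: float
    pmd_rate: float
    seed: int

    @property
    def covered(self) -> np.ndarray:
        return (self.c0 + self.c1) > 0


def _mosaic(founders: np.ndarray, n_out: int, switch_rate: float,
            rng: np.random.Generator) -> np.ndarray:
    """Copy *n_out* haplotypes as founder mosaics with per-site switching."""
    n_founders, n_sites = founders.shape
    source = np.empty((n_out, n_sites), dtype=np.int64)
    source[:, 0] = rng.integers(0, n_founders, size=n_out)
    switches = rng.random((n_out, n_sites - 1)) < switch_rate
    jumps = rng.integers(0, n_founders, size=(n_out, n_sites - 1))
    for s in range(1, n_sites):
        stay = ~switches[:, s - 1]
        source[:, s] = np.where(stay, source[:, s - 1], jumps[:, s - 1])
    return founders[source, np.arange(n_sites)]


def simulate_panel(n_hap: int, n_sites: int, mosaic_switch_rate: float = 0.05,
                   seed: int = 0, chrom: str = "1", n_founders: int = 8,
                   pos: np.ndarray = None, ref=None, alt=None,
                   founder_af: np.ndarray = None) -> HaplotypePanel:
    """Simulate a phased panel of founder-mosaic haplotypes on one chromosome.

    Low switch rates give strong adjacent-site correlation (LD); a rate of
    0.5 per site is effectively independent copying.  Monomorphic sites are
    re-polarised by flipping one haplotype so every frequency stays in (0,1).
    """
    if n_hap < 4 or n_sites < 2:
        raise SimulationError("need n_hap >= 4 and n_sites >= 2")
    if not 0.0 <= mosaic_switch_rate <= 1.0:
        raise SimulationError("mosaic_switch_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if founder_af is None:
        founder_af = rng.uniform(0.1, 0.9, size=n_sites)
    founders = (rng.random((n_founders, n_sites)) < founder_af).astype(np.uint8)
    haps = _mosaic(founders, n_hap, mosaic_switch_rate, rng).astype(np.uint8)
    # keep every site polymorphic in the panel
    for s in np.flatnonzero((haps.sum(axis=0) == 0) | (haps.sum(axis=0) == n_hap)):
        haps[rng.integers(0, n_hap), s] ^= 1
    if pos is None:
        pos = np.sort(rng.choice(np.arange(1, n_sites * 1000 + 1), size=n_sites,
                                 replace=False))
    if ref is None or alt is None:
        ref_idx = rng.integers(0, 4, size=n_sites)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
        ref = _BASES[ref_idx]
        alt = _BASES[alt_idx]
    return HaplotypePanel(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        haplotypes=haps,
        mosaic_switch_rate=mosaic_switch_rate,
    )


def panel_from_catalog(catalog, n_hap: int = 200, fillers_per_marker: int = 40,
                       filler_spacing: int = 5_000,
                       mosaic_switch_rate: float = 0.02,
                       seed: int = 0) -> HaplotypePanel:
    """A multi-chromosome panel embedding the catalog sites among fillers.

    Catalog sites take their catalogued ref/alt alleles and use the global
    MAF as the panel alt frequency (floored so rare alleles exist in the
    panel at all); fillers are random common SNPs around each marker.
    Chromosomes are simulated independently, then concatenated.
    """
    rng = np.random.default_rng(seed)
    pieces = []
    by_chrom = {}
    for m in sorted(catalog, key=lambda m: (m.chrom, m.pos)):
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom in sorted(by_chrom, key=lambda c: (0, int(c)) if c.isdigit() else (1, c)):
        markers = by_chrom[chrom]
        pos, ref, alt, rsid, af = [], [], [], [], []
        for m in markers:
            lo = max(1, m.pos - fillers_per_marker // 2 * filler_spacing)
            offsets = lo + np.arange(fillers_per_marker) * filler_spacing
            for p in offsets:
                if p != m.pos:
                    pos.append(int(p))
                    r = rng.integers(0, 4)
                    a = (r + rng.integers(1, 4)) % 4
                    ref.append(str(_BASES[r]))
                    alt.append(str(_BASES[a]))
                    rsid.append("")
                    af.append(rng.uniform(0.15, 0.85))
            pos.append(m.pos)
            ref.append(m.ref_allele)
            alt.append(m.alt_allele)
            rsid.append(m.rsid)
            af.append(min(max(m.global_maf, 0.03), 0.97))
        order = np.argsort(pos, kind="stable")
        pos = np.asarray(pos)[order]
        keep = np.concatenate(([True], np.diff(pos) > 0))  # drop duplicate positions
        sub_seed = int(rng.integers(0, 2**31 - 1))
        piece = simulate_panel(
            n_hap=n_hap,
            n_sites=int(keep.sum()),
            mosaic_switch_rate=mosaic_switch_rate,
            seed=sub_seed,
            chrom=chrom,
            pos=pos[keep],
            ref=np.asarray(ref, dtype=object)[order][keep],
            alt=np.asarray(alt, dtype=object)[order][keep],
            founder_af=np.asarray(af)[order][keep],
        )
        piece.rsid = np.asarray(rsid, dtype=object)[order][keep]
        pieces.append(piece)
    return HaplotypePanel(
        chrom=np.concatenate([p.chrom for p in pieces]),
        pos=np.concatenate([p.pos for p in pieces]),
        ref=np.concatenate([p.ref for p in pieces]),
        alt=np.concatenate([p.alt for p in pieces]),
        haplotypes=np.concatenate([p.haplotypes for p in pieces], axis=1),
        mosaic_switch_rate=mosaic_switch_rate,
        rsid=np.concatenate([p.rsid for p in pieces]),
    )


def sample_individuals(panel: HaplotypePanel, n: int, seed: int = 0,
                       recomb_switch_rate: float = 0.0) -> Individuals:
    """Draw diploid individuals as pairs of panel haplotypes.

    With the default zero recombination rate each gamete is an exact copy of
    a panel haplotype (the regime in which the naive imputer can recover the
    truth exactly); a positive rate makes each gamete a mosaic over the
    whole panel.
    """
    if n < 1:
        raise SimulationError("need n >= 1 individuals")
    rng = np.random.default_rng(seed)
    gametes = np.empty((n, 2, panel.n_sites), dtype=np.uint8)
    if recomb_switch_rate > 0:
        flat = _mosaic(panel.haplotypes, 2 * n, recomb_switch_rate, rng)
        gametes[:] = flat.reshape(n, 2, panel.n_sites)
    else:
        picks = rng.integers(0, panel.n_hap, size=(n, 2))
        gametes[:] = panel.haplotypes[picks]
    ids = [f"ind{i:03d}" for i in range(n)]
    return Individuals(sample_ids=ids, haplotypes=gametes, panel=panel)


def downsample_observations(individuals: Individuals, coverage: float,
                            pmd_rate: float = 0.0, seed: int = 0) -> ReadObservations:
    """Poisson(coverage) pseudo-haploid reads with optional damage noise."""
    if coverage <= 0:
        raise SimulationError("coverage must be > 0")
    if not 0.0 <= pmd_rate < 1.0:
        raise SimulationError("pmd_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    panel = individuals.panel
    n, n_sites = individuals.n, panel.n_sites
    depth = rng.poisson(coverage, size=(n, n_sites))
    # reads drawing the alt allele: each read picks one of the two chromosomes
    p_alt = individuals.genotypes / 2.0
    alt_reads = rng.binomial(depth, p_alt)
    ref_reads = depth - alt_reads
    n_damaged = np.zeros_like(depth)
    if pmd_rate > 0:
        ref_s, alt_s = panel.ref, panel.alt
        # C>T / G>A flips only where they land on the site's allele pair
        ref_flips = np.array([
            (r == "C" and a == "T") or (r == "G" and a == "A")
            for r, a in zip(ref_s, alt_s)
        ])
        alt_flips = np.array([
            (a == "C" and r == "T") or (a == "G" and r == "A")
            for r, a in zip(ref_s, alt_s)
        ])
        flip_from_ref = rng.binomial(ref_reads, pmd_rate * ref_flips[None, :])
        flip_from_alt = rng.binomial(alt_reads, pmd_rate * alt_flips[None, :])
        ref_reads = ref_reads - flip_from_ref + flip_from_alt
        alt_reads = alt_reads - flip_from_alt + flip_from_ref
        n_damaged = flip_from_ref + flip_from_alt
    return ReadObservations(c0=ref_reads, c1=alt_reads, n_damaged=n_damaged,
                            coverage=coverage, pmd_rate=pmd_rate, seed=seed)


def full_observations(individuals: Individuals) -> ReadObservations:
    """Noise-free observation of both chromosomes at every site."""
    g = individuals.genotypes
    return ReadObservations(c0=(2 - g).astype(np.int64), c1=g.astype(np.int64),
                            n_damaged=np.zeros_like(g, dtype=np.int64),
                            coverage=float("inf"), pmd_rate=0.0, seed=0)


def hw_argmax_genotypes(panel: HaplotypePanel) -> np.ndarray:
    """Per-site most probable genotype under Hardy-Weinberg panel frequencies."""
    p = panel.af
    probs = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    return probs.argmax(axis=0).astype(np.uint8)


def _pair_index(n_hap: int):
    i, j = np.triu_indices(n_hap)
    return i, j


def naive_impute(obs: ReadObservations, panel: HaplotypePanel, k: int = 5,
                 seed: int = 0) -> np.ndarray:
    """Impute diploid genotypes from sparse reads via best panel pairs.

    For each individual, score every unordered panel haplotype pair by the
    number of observed reads inconsistent with the pair's diploid genotype
    (a read conflicts only with an opposite homozygote), keep the *k*
    best-scoring pairs (score ties broken by a seeded random ordering, which
    is what makes imputation replicates vary), and report the per-site
    majority genotype among them, ties resolving to HET.  Individuals with
    no reads at all fall back to the per-site Hardy-Weinberg argmax.

    Returns an (n, n_sites) array of alt dosages in {0, 1, 2}.
    """
    if panel.n_hap < 1:
        raise SimulationError("empty panel")
    rng = np.random.default_rng(seed)
    i_idx, j_idx = _pair_index(panel.n_hap)
    H = panel.haplotypes
    G = (H[i_idx] + H[j_idx]).astype(np.uint8)          # (n_pairs, n_sites)
    A0 = (G == 0).astype(np.float32)
    A2 = (G == 2).astype(np.float32)
    n, n_sites = obs.c0.shape
    if n_sites != panel.n_sites:
        raise SimulationError("observation sites do not match panel sites")
    hw_fallback = hw_argmax_genotypes(panel)
    tiebreak = rng.random(len(i_idx))
    out = np.empty((n, n_sites), dtype=np.uint8)
    for ind in range(n):
        c0 = obs.c0[ind].astype(np.float32)
        c1 = obs.c1[ind].astype(np.float32)
        if c0.sum() + c1.sum() == 0:
            out[ind] = hw_fallback
            continue
        score = A0 @ c1 + A2 @ c0
        order = np.lexsort((tiebreak, score))
        best = order[: min(k, len(order))]
        votes = G[best]                                  # (k, n_sites)
        n0 = (votes == 0).sum(axis=0)
        n1 = (votes == 1).sum(axis=0)
        n2 = (votes == 2).sum(axis=0)
        counts = np.stack([n0, n1, n2])
        top = counts.max(axis=0)
        is_tie = (counts == top).sum(axis=0) > 1
        out[ind] = np.where(is_tie, 1, counts.argmax(axis=0)).astype(np.uint8)
    return out


_GT_CLASSES = np.array([GTClass.HOMREF, GTClass.HET, GTClass.HOMALT], dtype=object)


def genotypes_to_calls(genotypes: np.ndarray, panel: HaplotypePanel, sample_ids,
                       source: str = "imputed", marker_sites_only: bool = True,
                       extra: dict = None) -> "pd.DataFrame":
    """Genotype matrix -> long call table (sample, rsid, gt_class [+extras])."""
    import pandas as pd

    mask = (panel.rsid != "") if marker_sites_only else np.ones(panel.n_sites, bool)
    site_idx = np.flatnonzero(mask)
    records = {
        "sample": np.repeat(sample_ids, len(site_idx)),
        "rsid": np.tile(panel.rsid[site_idx], len(sample_ids)),
        "gt_class": _GT_CLASSES[genotypes[:, site_idx].reshape(-1)],
        "source": source,
    }
    df = pd.DataFrame(records)
    for key, value in (extra or {}).items():
        df[key] = value
    return df


# --- VCF emission -----------------------------------------------------------

def _vcf_header(panel: HaplotypePanel, sample_ids) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    seen = []
    for c in panel.chrom:
        if c not in seen:
            seen.append(c)
    for c in seen:
        length = int(panel.pos[panel.chrom == c].max()) + 1000
        header.contigs.add(c, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in sample_ids:
        header.add_sample(s)
    return header


def _write_vcf(panel: HaplotypePanel, genotype_pairs, sample_ids, path,
               phased: bool) -> None:
    header = _vcf_header(panel, sample_ids)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in range(panel.n_sites):
            rec = vcf.new_record(
                contig=str(panel.chrom[s]),
                start=int(panel.pos[s]) - 1,
                alleles=(str(panel.ref[s]), str(panel.alt[s])),
                id=str(panel.rsid[s]) or None,
            )
            for sid, pair in zip(sample_ids, genotype_pairs):
                rec.samples[sid]["GT"] = (int(pair[0][s]), int(pair[1][s]))
                rec.samples[sid].phased = phased
            vcf.write(rec)


def write_panel_vcf(panel: HaplotypePanel, path) -> None:
    """Phased VCF of the panel; haplotype pairs 2i/2i+1 form sample ``hapNNN``."""
    if panel.n_hap % 2:
        raise SimulationError("panel VCF needs an even haplotype count")
    ids = [f"hap{i:03d}" for i in range(panel.n_hap // 2)]
    pairs = [(panel.haplotypes[2 * i], panel.haplotypes[2 * i + 1])
             for i in range(panel.n_hap // 2)]
    _write_vcf(panel, pairs, ids, path, phased=True)


def write_truth_vcf(individuals: Individuals, path) -> None:
    """Unphased diploid VCF of the truth individuals."""
    pairs = [(individuals.haplotypes[i, 0], individuals.haplotypes[i, 1])
             for i in range(individuals.n)]
    _write_vcf(individuals.panel, pairs, individuals.sample_ids, path, phased=False)
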