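"""Simulated BAC library, fingerprints, contigs and phase-anchored markers.

Models the clone resources a BAC-by-BAC sequencing project works from: a
large-insert clone library sampled at a configured number of genome
equivalents per haplotype, paired end reads (BES) for every clone, an
in-silico restriction fingerprint per clone, fingerprint contigs built
by single-linkage on shared restriction bands, and haplotype-specific
genetic markers anchored to bins of a linkage map in which the whole
recombination-suppressed heterochromatin collapses into a single bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError
from .sequtil import encode
from .synthetic_genome import DiploidChromosome, RegionSpec, TruthTable

__all__ = [
    "BACClone",
    "Fingerprint",
    "FingerprintContig",
    "AFLPMarker",
    "GeneticBinMap",
    "coverage_probability",
    "sample_bac_library",
    "fingerprint_clone",
    "fingerprint_library",
    "band_overlap",
    "contig_build",
    "place_markers",
]


def coverage_probability(c: float) -> float:
    """Expected covered fraction of a genome at ``c`` clone equivalents.

    Random-library coverage: 1 - exp(-c).  At 4.8 genome equivalents per
    haplotype a physical map is expected to cover 99.2% of each haplotype.
    """
    if c < 0:
        raise ConfigurationError("genome equivalents must be >= 0")
    return -math.expm1(-c)  # 1 - e^{-c}, accurate for small c


@dataclass
class BACClone:
    """One library clone: an exact substring of its haplotype of origin."""

    id: str
    haplotype_of_origin: int
    start: int  # on the haplotype of origin
    end: int
    sequence: np.ndarray
    bes_left: np.ndarray
    bes_right: np.ndarray

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def true_interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def sample_bac_library(
    diploid: DiploidChromosome,
    mean_len: int = 122_651,
    len_sd: int = 25_000,
    equivalents_per_hap: float = 4.8,
    seed: int = 0,
    min_len: int = 14_260,
    max_len: int = 216_437,
    bes_len: int = 500,
) -> list[BACClone]:
    """Sample a clone library uniformly from both haplotypes.

    Clone count per haplotype is ``equivalents_per_hap * hap_len /
    mean_len`` (so expected depth equals the requested equivalents);
    lengths are truncated-normal within [min_len, max_len]; starts are
    uniform.  End sequences are exact prefixes/suffixes of the clone.
    """
    rng = np.random.default_rng(seed)
    clones = []
    for hap in (0, 1):
        hap_seq = diploid.haplotype(hap)
        n_hap = len(hap_seq)
        if mean_len >= n_hap:
            raise ConfigurationError("mean clone length must be below haplotype length")
        n_clones = int(round(equivalents_per_hap * n_hap / mean_len))
        if len_sd == 0:
            lengths = np.full(n_clones, mean_len)
        else:
            lengths = np.empty(n_clones, dtype=np.int64)
            todo = np.arange(n_clones)
            while len(todo):
                draw = rng.normal(mean_len, len_sd, len(todo)).round().astype(np.int64)
                ok = (draw >= min_len) & (draw <= max_len)
                lengths[todo[ok]] = draw[ok]
                todo = todo[~ok]
        starts = rng.integers(0, np.maximum(1, n_hap - lengths))
        for k in range(n_clones):
            s, e = int(starts[k]), int(starts[k] + lengths[k])
            seq = hap_seq[s:e]
            clones.append(
                BACClone(
                    id=f"CL{hap}_{k:04d}",
                    haplotype_of_origin=hap,
                    start=s,
                    end=e,
                    sequence=seq,
                    bes_left=seq[:bes_len],
                    bes_right=seq[-bes_len:],
                )
            )
    return clones


# ---------------------------------------------------------------------------
# fingerprints and contigs
# ---------------------------------------------------------------------------

@dataclass
class Fingerprint:
    """Restriction band profile of one clone (fragment sizes in bp)."""

    clone_id: str
    bands: np.ndarray  # sorted fragment lengths within the sizing window

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass
class FingerprintContig:
    id: str
    clone_ids: list[str]
    consensus_bands: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


DEFAULT_MOTIFS = ("GAATTC", "AAGCTT")


def _motif_positions(codes: np.ndarray, motif: np.ndarray) -> np.ndarray:
    m = len(motif)
    n = len(codes) - m + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    hit = np.ones(n, dtype=bool)
    for i, c in enumerate(motif):
        hit &= codes[i:i + n] == c
    return np.flatnonzero(hit)


def fingerprint_clone(
    clone: BACClone,
    motifs=DEFAULT_MOTIFS,
    min_frag: int = 50,
    max_frag: int = 1_500,
) -> Fingerprint:
    """In-silico digest of a clone at the given recognition motifs.

    Cut positions from all motifs are pooled; fragment lengths between
    consecutive cuts are kept if they fall inside the electrophoresis
    sizing window [min_frag, max_frag].
    """
    if not motifs:
        raise InputError("at least one digest motif is required")
    cuts = [np.array([0, clone.length], dtype=np.int64)]
    for motif in motifs:
        cuts.append(_motif_positions(clone.sequence, encode(motif)))
    pos = np.unique(np.concatenate(cuts))
    frags = np.diff(pos)
    bands = np.sort(frags[(frags >= min_frag) & (frags <= max_frag)])
    return Fingerprint(clone.id, bands.astype(np.int64))


def fingerprint_library(clones, **kwargs) -> dict[str, Fingerprint]:
    return {c.id: fingerprint_clone(c, **kwargs) for c in clones}


def band_overlap(a: np.ndarray, b: np.ndarray, tolerance: int = 3) -> int:
    """Number of bands shared between two sorted profiles within tolerance."""
    i = j = shared = 0
    while i < len(a) and j < len(b):
        d = int(a[i]) - int(b[j])
        if abs(d) <= tolerance:
            shared += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return shared


def contig_build(
    clones: list[BACClone],
    fingerprints: dict[str, Fingerprint],
    min_shared_frac: float = 0.6,
    tolerance: int = 3,
) -> list[FingerprintContig]:
    """Single-linkage fingerprint contigs.

    Two clones link when they share at least ``min_shared_frac`` of the
    smaller clone's band count (bands matched within ``tolerance`` bp).
    Contig membership partitions the library; in strongly diverged
    tracts the digests of opposite haplotypes share almost no bands, so
    contigs separate by haplotype, while in homozygous tracts identical
    underlying sequence forces co-assembly.
    """
    if not clones:
        raise InputError("empty clone library")
    n = len(clones)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    profiles = [fingerprints[c.id].bands for c in clones]
    for i in range(n):
        for j in range(i + 1, n):
            smaller = min(len(profiles[i]), len(profiles[j]))
            if smaller == 0:
                continue
            if band_overlap(profiles[i], profiles[j], tolerance) >= min_shared_frac * smaller:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    contigs = []
    for k, members in enumerate(sorted(groups.values(), key=lambda m: m[0])):
        ids = [clones[m].id for m in members]
        bands = np.sort(np.concatenate([profiles[m] for m in members]))
        contigs.append(FingerprintContig(f"ctg{k:04d}", ids, bands))
    return contigs


# ---------------------------------------------------------------------------
# genetic bin map and markers
# ---------------------------------------------------------------------------

@dataclass
class GeneticBinMap:
    """Monotone position-to-bin map with the heterochromatin in one bin.

    Recombination is suppressed across the pericentromeric
    heterochromatin (borders included), so the whole interval
    [het_start, het_end) collapses into the single ``het_bin``; the
    euchromatic arms are divided evenly into the remaining bins.
    """

    binT: int = 78
    het_bin: int = 46
    het_start: int = 0
    het_end: int = 0
    total_length: int = 0

    @classmethod
    def from_regions(cls, regions: list[RegionSpec], binT: int = 78, het_bin: int = 46):
        het = [r for r in regions if r.region_class in ("het_border", "central_het")]
        return cls(
            binT=binT,
            het_bin=het_bin,
            het_start=min(r.start for r in het),
            het_end=max(r.end for r in het),
            total_length=max(r.end for r in regions),
        )

    def bin_of(self, ref_pos: int) -> int:
        if not 0 <= ref_pos < self.total_length:
            raise InputError(f"position {ref_pos} outside the chromosome")
        if ref_pos < self.het_start:
            nb = self.het_bin - 1
            return 1 + min(nb - 1, int(ref_pos / self.het_start * nb))
        if ref_pos < self.het_end:
            return self.het_bin
        south_len = self.total_length - self.het_end
        nb = self.binT - self.het_bin
        return self.het_bin + 1 + min(nb - 1, int((ref_pos - self.het_end) / south_len * nb))


@dataclass
class AFLPMarker:
    """A haplotype-specific sequence tag with a genetic-bin assignment."""

    id: str
    phase: int
    bin: int
    position: int  # on its haplotype
    carrier_clone_ids: list[str] = field(default_factory=list)


def place_markers(
    diploid: DiploidChromosome,
    truth: TruthTable,
    density: float,
    bin_map: GeneticBinMap,
    seed: int = 0,
    clones: list[BACClone] | None = None,
) -> list[AFLPMarker]:
    """Place phase-specific markers at haplotype-specific sites.

    Each polymorphic site (a position present or variant in exactly one
    haplotype) becomes a marker independently with probability
    ``density``; inside fully haplotype-specific intervals (hemizygous
    inserts, cluster arrays, non-alignable heterochromatin) every bp
    counts as a site.  The marker bin comes from the genetic-bin map at
    the site's reference-frame location (its tract's span when the site
    itself has no reference equivalent, as in the heterochromatin).
    """
    if density <= 0:
        raise ConfigurationError("marker density must be > 0")
    rng = np.random.default_rng(seed)
    markers: list[AFLPMarker] = []
    by_hap_clones = {0: [], 1: []}
    if clones:
        for c in clones:
            by_hap_clones[c.haplotype_of_origin].append(c)

    for hap in (0, 1):
        sites = truth.polymorphic_sites[hap]
        chosen = sites[rng.random(len(sites)) < density] if len(sites) else np.empty(0, dtype=np.int64)
        interval_sites = []
        for lo, hi in truth.polymorphic_intervals[hap]:
            k = rng.binomial(hi - lo, density)
            if k:
                interval_sites.append(rng.integers(lo, hi, k))
        if interval_sites:
            chosen = np.unique(np.concatenate([chosen, *interval_sites]))
        for idx, pos in enumerate(np.sort(chosen)):
            pos = int(pos)
            ref_pos = truth.hap_to_ref(pos, hap)
            if ref_pos is None:
                tract = truth.hap_tract_of(pos, hap)
                if tract is None:
                    continue
                ref_pos = (tract.ref_span[0] + tract.ref_span[1]) // 2
            b = bin_map.bin_of(ref_pos)
            carriers = [
                c.id
                for c in by_hap_clones[hap]
                if c.start <= pos < c.end
            ]
            markers.append(AFLPMarker(f"M{hap}_{idx:04d}", hap, b, pos, carriers))
    if not markers:
        warnings.warn("no polymorphic sites: zero markers placed", stacklevel=2)
    return markers
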