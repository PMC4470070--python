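"""Simulator for a heterozygous diploid chromosome with region-structured divergence.

The simulated system is a single chromosome present in three copies: a
haploid reference assembly (``REF``) and the two homologous chromosome
copies (``HAP0``/``HAP1``) of a heterozygous diploid individual.  The
chromosome is divided into five consecutive regions -- north euchromatin,
north heterochromatin border, central heterochromatin, south
heterochromatin border and south euchromatin -- each with its own
divergence regime:

* euchromatic arms: an alternation of homozygous tracts (the two
  homologues are identical) and heterozygous-collinear tracts (the
  homologues differ by SNPs and short indels only), interrupted by
  occasional tandem gene-cluster breaks with unequal copy number;
* heterochromatin borders: heterozygous-collinear background carrying
  large one-sided (hemizygous) inserts present in only one homologue;
* central heterochromatin: the three copies are essentially independent
  sequences that share only a handful of scattered segments, which may or
  may not sit at allelic (same physical) positions.

Every stochastic event is recorded in a :class:`TruthTable` so that
downstream phasing, tiling and collinearity modules can be audited
against ground truth.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, GenerationError
from .sequtil import decode, random_sequence

#: sequence length of the full-size chromosome the desk-scale defaults mimic
FULL_SCALE_BP = 52_000_000

#: region proportions of the reference chromosome (north euchromatin,
#: north het border, central heterochromatin, south het border, south
#: euchromatin); derived from the reference region sizes so they sum to 1.
DEFAULT_REGION_FRACTIONS = tuple(
    x / 49_520_158 for x in (9_973_565, 12_734_159, 17_195_885, 1_791_234, 7_825_315)
)

REGION_NAMES = (
    "north_euchromatin",
    "north_het_border",
    "central_heterochromatin",
    "south_het_border",
    "south_euchromatin",
)
REGION_CLASSES = ("euchromatin", "het_border", "central_het", "het_border", "euchromatin")

TRACT_LABELS = (
    "homozygous",
    "heterozygous_collinear",
    "cluster_break",
    "hemizygous_insert",
    "non_alignable",
)


@dataclass(frozen=True)
class Tract:
    """One zygosity sub-tract of a region, on reference coordinates."""

    label: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSpec:
    """A named chromosome region with its zygosity plan."""

    name: str
    region_class: str  # euchromatin | het_border | central_het
    start: int
    end: int
    zygosity_plan: list[Tract] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DivergenceModel:
    """Rates and length laws for haplotype divergence.

    The two SNP rates are coupled: each homologue carries *shared*
    substitutions relative to the reference (present in both homologues)
    plus *private* substitutions, so that the homologue-vs-reference
    substitution density is ``snp_rate_vs_ref`` while the density of
    sites differing between the homologues is ``snp_rate_between_haps``.
    Defaults reproduce ~97.5% homologue-vs-reference and ~96.5%
    homologue-vs-homologue identity in heterozygous collinear tracts.

    Small indels follow a geometric length law truncated to 1-50 bp;
    large hemizygous inserts and central-heterochromatin shared segments
    are drawn uniformly from their configured ranges, which default to
    the full-scale ranges (200-450 kb and 50-250 kb) scaled down linearly
    to the simulated chromosome length.
    """

    snp_rate_vs_ref: float = 0.025
    snp_rate_between_haps: float = 0.035
    small_indel_rate: float = 2e-5  # events/bp between the two homologues
    small_indel_p: float = 0.35  # geometric length parameter, support 1..50
    large_insert_range: tuple[int, int] = (7_700, 17_300)
    cluster_unit_len: int = 3_000
    cluster_copies: tuple[int, int] = (2, 5)
    cluster_unit_divergence: float = 0.10
    shared_segment_count: int = 3
    shared_segment_range: tuple[int, int] = (1_900, 9_600)
    allelic_placement_prob: float = 0.5

    def validate(self) -> None:
        for name in ("snp_rate_vs_ref", "snp_rate_between_haps", "small_indel_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 < self.small_indel_p <= 1:
            raise ConfigurationError("small_indel_p must be in (0, 1]")
        if self.shared_segment_count < 0:
            raise ConfigurationError("shared_segment_count must be >= 0")
        if not 0 <= self.allelic_placement_prob <= 1:
            raise ConfigurationError("allelic_placement_prob must be a probability")

    @property
    def private_snp_rate(self) -> float:
        """Per-homologue private substitution rate."""
        return self.snp_rate_between_haps / 2.0

    @property
    def shared_snp_rate(self) -> float:
        """Substitution rate shared by both homologues relative to the reference."""
        return max(0.0, self.snp_rate_vs_ref - self.snp_rate_between_haps / 2.0)


def default_model(total_length: int = 2_000_000) -> DivergenceModel:
    """Divergence model with length laws scaled to the simulated chromosome."""
    s = total_length / FULL_SCALE_BP
    return DivergenceModel(
        large_insert_range=(max(2_000, int(200_000 * s)), max(4_000, int(450_000 * s))),
        shared_segment_range=(max(1_000, int(50_000 * s)), max(2_000, int(250_000 * s))),
    )


@dataclass
class VariantEvent:
    """One recorded divergence event.

    ``carrier`` is the haplotype carrying extra/changed sequence (0 or 1),
    or ``None`` when the event affects both (shared segments, clusters).
    ``dlen_hap0``/``dlen_hap1`` are the exact length deltas the event
    contributes to each haplotype relative to the reference.
    """

    kind: str
    carrier: int | None
    ref_pos: int
    hap0_span: tuple[int, int] | None
    hap1_span: tuple[int, int] | None
    length: int
    dlen_hap0: int = 0
    dlen_hap1: int = 0
    allelic: bool | None = None
    detail: str = ""


@dataclass
class TractRecord:
    label: str
    ref_span: tuple[int, int]
    hap0_span: tuple[int, int]
    hap1_span: tuple[int, int]
    region: str = ""


class TruthTable:
    """Machine-readable record of everything the simulator did.

    Holds region and tract bookkeeping, individual structural events,
    aggregate SNP counts, per-haplotype polymorphic site/interval lists
    (used to place haplotype-specific markers) and monotone piecewise
    coordinate liftover maps between the reference and each haplotype.
    """

    def __init__(self, regions: list[RegionSpec]):
        self.regions = regions
        self.tracts: list[TractRecord] = []
        self.events: list[VariantEvent] = []
        self.snp_counts = {"shared": 0, "hap0": 0, "hap1": 0}
        # haplotype-specific polymorphic sites (positions on the haplotype)
        self.polymorphic_sites = {0: [], 1: []}
        # intervals on the haplotype where the whole stretch is haplotype-specific
        self.polymorphic_intervals = {0: [], 1: []}
        # collinear liftover blocks per haplotype: rows (ref_start, ref_end, hap_start)
        self._blocks = {0: [], 1: []}
        self._block_arr: dict[int, np.ndarray] = {}

    # -- construction helpers -------------------------------------------------
    def add_blocks(self, hap: int, blocks) -> None:
        self._blocks[hap].extend(blocks)

    def finalize(self) -> None:
        for hap in (0, 1):
            arr = np.array(self._blocks[hap], dtype=np.int64).reshape(-1, 3)
            self._block_arr[hap] = arr[np.argsort(arr[:, 0])]
            self.polymorphic_sites[hap] = np.array(
                sorted(self.polymorphic_sites[hap]), dtype=np.int64
            )

    # -- queries ---------------------------------------------------------------
    def blocks(self, hap: int) -> np.ndarray:
        return self._block_arr[hap]

    def ref_to_hap(self, pos: int, hap: int) -> int | None:
        """Map a reference position into haplotype coordinates.

        Returns ``None`` outside collinear blocks (inserts, clusters,
        non-alignable tracts have no reference equivalent).
        """
        arr = self._block_arr[hap]
        i = np.searchsorted(arr[:, 0], pos, side="right") - 1
        if i < 0 or pos >= arr[i, 1]:
            return None
        return int(arr[i, 2] + (pos - arr[i, 0]))

    def hap_to_ref(self, pos: int, hap: int) -> int | None:
        arr = self._block_arr[hap]
        starts = arr[:, 2]
        order = np.argsort(starts)
        s = starts[order]
        i = np.searchsorted(s, pos, side="right") - 1
        if i < 0:
            return None
        row = arr[order[i]]
        if pos >= row[2] + (row[1] - row[0]):
            return None
        return int(row[0] + (pos - row[2]))

    def net_dlen(self, hap: int) -> int:
        return sum(e.dlen_hap0 if hap == 0 else e.dlen_hap1 for e in self.events)

    def shared_segments(self) -> list[VariantEvent]:
        return [e for e in self.events if e.kind == "shared_segment"]

    def region_of(self, ref_pos: int) -> RegionSpec:
        for r in self.regions:
            if r.start <= ref_pos < r.end:
                return r
        raise ValueError(f"position {ref_pos} outside the chromosome")

    def hap_tract_of(self, pos: int, hap: int) -> TractRecord | None:
        for t in self.tracts:
            lo, hi = t.hap0_span if hap == 0 else t.hap1_span
            if lo <= pos < hi:
                return t
        return None


@dataclass
class DiploidChromosome:
    """Reference plus the two derived homologues and their truth table."""

    reference: np.ndarray
    hap0: np.ndarray
    hap1: np.ndarray
    regions: list[RegionSpec]
    truth: TruthTable

    def haplotype(self, hap: int) -> np.ndarray:
        return self.hap0 if hap == 0 else self.hap1

    @classmethod
    def simulate(
        cls,
        total_length: int = 2_000_000,
        seed: int = 0,
        model: DivergenceModel | None = None,
        region_fractions=None,
        gc: float = 0.5,
    ) -> "DiploidChromosome":
        reference, regions = simulate_reference(total_length, region_fractions, gc, seed)
        model = model or default_model(total_length)
        hap0, hap1, truth = derive_haplotypes(reference, regions, model, seed + 1)
        return cls(reference, hap0, hap1, regions, truth)


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def _cut_plan(start: int, end: int, parts: list[tuple[str, float]]) -> list[Tract]:
    """Slice [start, end) into labelled tracts by the given fractions."""
    total = end - start
    bounds = [start]
    acc = 0.0
    for _, f in parts[:-1]:
        acc += f
        bounds.append(start + int(round(acc * total)))
    bounds.append(end)
    return [
        Tract(label, bounds[i], bounds[i + 1])
        for i, (label, _) in enumerate(parts)
        if bounds[i + 1] > bounds[i]
    ]


_DEFAULT_PLANS = {
    # euchromatic arms: heterozygous background with homozygous windows and
    # tandem gene-cluster breaks; borders: heterozygous with hemizygous
    # inserts; central heterochromatin: fully non-alignable.
    "north_euchromatin": [
        ("heterozygous_collinear", 0.30),
        ("cluster_break", 0.03),
        ("heterozygous_collinear", 0.30),
        ("homozygous", 0.30),
        ("heterozygous_collinear", 0.07),
    ],
    "north_het_border": [
        ("heterozygous_collinear", 0.28),
        ("hemizygous_insert", 0.16),
        ("heterozygous_collinear", 0.24),
        ("hemizygous_insert", 0.16),
        ("heterozygous_collinear", 0.16),
    ],
    "central_heterochromatin": [("non_alignable", 1.0)],
    "south_het_border": [
        ("heterozygous_collinear", 0.40),
        ("hemizygous_insert", 0.30),
        ("heterozygous_collinear", 0.30),
    ],
    "south_euchromatin": [
        ("homozygous", 0.45),
        ("heterozygous_collinear", 0.15),
        ("homozygous", 0.10),
        ("heterozygous_collinear", 0.12),
        ("cluster_break", 0.04),
        ("heterozygous_collinear", 0.14),
    ],
}


def simulate_reference(
    total_length: int,
    region_fractions=None,
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, list[RegionSpec]]:
    """Generate the reference haplotype and its five-region layout.

    Regions tile ``[0, total_length)`` contiguously in the fixed
    north-to-south order; each gets a default zygosity plan.  Identical
    seeds produce byte-identical sequence.
    """
    if total_length < 100_000:
        raise ConfigurationError("total_length must be >= 100 kb")
    fractions = tuple(region_fractions) if region_fractions is not None else DEFAULT_REGION_FRACTIONS
    if len(fractions) != 5:
        raise ConfigurationError("exactly five region fractions are required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"region fractions sum to {sum(fractions)}, expected 1")
    if not 0 < gc < 1:
        raise ConfigurationError("gc must be in (0, 1)")

    rng = np.random.default_rng(seed)
    reference = random_sequence(rng, total_length, gc)

    bounds = [0]
    acc = 0.0
    for f in fractions[:-1]:
        acc += f
        bounds.append(int(round(acc * total_length)))
    bounds.append(total_length)

    regions = []
    for i, (name, cls_) in enumerate(zip(REGION_NAMES, REGION_CLASSES)):
        start, end = bounds[i], bounds[i + 1]
        plan = _cut_plan(start, end, _DEFAULT_PLANS[name])
        regions.append(RegionSpec(name, cls_, start, end, plan))
    return reference, regions


# ---------------------------------------------------------------------------
# haplotype derivation
# ---------------------------------------------------------------------------

def _mutate_snps(seg: np.ndarray, rate: float, rng: np.random.Generator):
    """Substitute bases i.i.d. at the given per-bp rate; returns (copy, sites)."""
    if rate <= 0 or len(seg) == 0:
        return seg.copy(), np.empty(0, dtype=np.int64)
    mask = rng.random(len(seg)) < rate
    out = seg.copy()
    k = int(mask.sum())
    if k:
        out[mask] = (out[mask] + rng.integers(1, 4, k, dtype=np.uint8)) % 4
    return out, np.flatnonzero(mask)


def _geometric_lengths(rng, n, p, lo=1, hi=50):
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return np.clip(rng.geometric(p, n), lo, hi).astype(np.int64)


def _apply_indels(seg: np.ndarray, indels, rng):
    """Apply (pos, length, kind) indels to ``seg``.

    ``indels`` must be sorted by position with deletions not overlapping.
    Returns (new_array, blocks, realized) where blocks are collinear
    pieces as (ref_start, ref_end, hap_start) local to the tract and
    ``realized`` maps each event to its haplotype-local span.
    """
    pieces, blocks, realized = [], [], []
    ref_c, hap_c = 0, 0
    n = len(seg)
    for pos, ln, kind in indels:
        pos = int(min(pos, n))
        if pos > ref_c:
            pieces.append(seg[ref_c:pos])
            blocks.append((ref_c, pos, hap_c))
            hap_c += pos - ref_c
            ref_c = pos
        if kind == "ins":
            pieces.append(random_sequence(rng, int(ln)))
            realized.append((pos, int(ln), kind, hap_c, hap_c + int(ln)))
            hap_c += int(ln)
        else:
            cut = int(min(pos + ln, n))
            realized.append((pos, cut - pos, kind, hap_c, hap_c))
            ref_c = cut
    if ref_c < n:
        pieces.append(seg[ref_c:])
        blocks.append((ref_c, n, hap_c))
        hap_c += n - ref_c
    arr = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    return arr, blocks, realized


def _lift_local(sites: np.ndarray, blocks) -> np.ndarray:
    """Map tract-local reference sites through tract-local collinear blocks."""
    if len(sites) == 0 or not blocks:
        return np.empty(0, dtype=np.int64)
    b = np.array(blocks, dtype=np.int64)
    idx = np.searchsorted(b[:, 0], sites, side="right") - 1
    ok = (idx >= 0) & (sites < b[np.clip(idx, 0, None), 1])
    idx, s = idx[ok], sites[ok]
    return b[idx, 2] + (s - b[idx, 0])


def plant_cluster_break(
    tract: np.ndarray,
    unit_len: int,
    copies_hap0: int,
    copies_hap1: int,
    unit_divergence: float,
    rng: np.random.Generator,
):
    """Replace the head of a tract with a tandem gene-cluster array.

    The first ``unit_len`` bp of the tract act as the cluster unit; each
    haplotype receives its own tandem array (``copies_hap0`` vs
    ``copies_hap1`` copies), with the second haplotype's unit diverged at
    ``unit_divergence`` substitutions/bp.  The remainder of the tract is
    left untouched in both haplotypes.  With equal copy number and zero
    divergence the tract is unchanged; with >= 2-fold copy-number
    difference the pairwise collinearity over the tract collapses.
    """
    if copies_hap0 < 1 or copies_hap1 < 1:
        raise ConfigurationError("cluster copy numbers must be >= 1")
    n = len(tract)
    if unit_len * max(copies_hap0, copies_hap1) > n:
        raise GenerationError("cluster array exceeds tract length")
    unit0 = tract[:unit_len]
    unit1, _ = _mutate_snps(unit0, unit_divergence, rng)
    # each haplotype's array replaces the head of its own tract copy, so
    # the tract length is conserved and the copy-number difference shows
    # up as non-collinear sequence rather than as a length change
    arr0 = np.concatenate([np.tile(unit0, copies_hap0), tract[unit_len * copies_hap0:]])
    arr1 = np.concatenate([np.tile(unit1, copies_hap1), tract[unit_len * copies_hap1:]])
    record = {
        "kind": "cluster_break",
        "unit_len": unit_len,
        "copies": (copies_hap0, copies_hap1),
        "unit_divergence": unit_divergence,
        "dlen_hap0": 0,
        "dlen_hap1": 0,
        "cluster_span_hap0": (0, copies_hap0 * unit_len),
        "cluster_span_hap1": (0, copies_hap1 * unit_len),
        "suffix_ref_start_hap0": unit_len * copies_hap0,
        "suffix_ref_start_hap1": unit_len * copies_hap1,
        "polymorphic_until": unit_len * max(copies_hap0, copies_hap1),
    }
    return arr0, arr1, record


def _plant_shared_segments(arr0, arr1, model, rng, events, offset0, offset1, ref_start):
    """Overwrite slices of two non-alignable tracts with common sequence.

    With probability ``allelic_placement_prob`` a segment lands at the
    same tract-relative position on both haplotypes (allelic); otherwise
    the second copy is displaced to a random non-overlapping position.
    Returns the intervals occupied on each haplotype (tract-local).
    """
    n0, n1 = len(arr0), len(arr1)
    used0, used1 = [], []

    def free(used, n, ln, want=None, tries=60):
        for _ in range(tries):
            p = want if want is not None else int(rng.integers(0, max(1, n - ln)))
            if p + ln <= n and all(p + ln <= a or p >= b for a, b in used):
                return p
            want = None
        return None

    taken0, taken1 = [], []
    for _ in range(model.shared_segment_count):
        lo, hi = model.shared_segment_range
        ln = int(rng.integers(lo, hi + 1))
        if ln >= min(n0, n1):
            continue
        p0 = free(used0, n0, ln)
        if p0 is None:
            continue
        allelic = bool(rng.random() < model.allelic_placement_prob)
        p1 = free(used1, n1, ln, want=p0 if allelic else None)
        if p1 is None:
            continue
        allelic = allelic and p1 == p0
        seg = random_sequence(rng, ln)
        arr0[p0:p0 + ln] = seg
        arr1[p1:p1 + ln] = seg
        used0.append((p0, p0 + ln))
        used1.append((p1, p1 + ln))
        taken0.append((p0, p0 + ln))
        taken1.append((p1, p1 + ln))
        events.append(
            VariantEvent(
                kind="shared_segment",
                carrier=None,
                ref_pos=ref_start,
                hap0_span=(offset0 + p0, offset0 + p0 + ln),
                hap1_span=(offset1 + p1, offset1 + p1 + ln),
                length=ln,
                allelic=allelic,
            )
        )
    return taken0, taken1


def _subtract(interval, holes):
    """Subtract sorted holes from one interval, yielding leftover pieces."""
    lo, hi = interval
    out = []
    cur = lo
    for a, b in sorted(holes):
        if a > cur:
            out.append((cur, min(a, hi)))
        cur = max(cur, b)
    if cur < hi:
        out.append((cur, hi))
    return [(a, b) for a, b in out if b > a]


def derive_haplotypes(
    reference: np.ndarray,
    region_specs: list[RegionSpec],
    model: DivergenceModel,
    seed: int = 0,
):
    """Derive the two homologues from the reference, recording all events.

    Homozygous tracts yield identical homologues (both carrying the same
    shared substitutions relative to the reference); heterozygous
    collinear tracts add private SNPs and small indels per homologue;
    hemizygous-insert tracts additionally plant one large one-sided
    insert; cluster-break tracts get tandem arrays with unequal copy
    number; non-alignable tracts are independent random sequence except
    for planted shared segments.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    truth = TruthTable(region_specs)
    parts0, parts1 = [], []
    cur0 = cur1 = 0

    for region in region_specs:
        for tract in region.zygosity_plan:
            if tract.end > len(reference):
                raise GenerationError(
                    f"tract {tract} exceeds reference length {len(reference)}"
                )
            seg = reference[tract.start:tract.end]
            n = tract.length
            t0 = cur0
            t1 = cur1

            if tract.label == "homozygous":
                shared, sites = _mutate_snps(seg, model.snp_rate_vs_ref, rng)
                truth.snp_counts["shared"] += len(sites)
                parts0.append(shared)
                parts1.append(shared)
                truth.add_blocks(0, [(tract.start, tract.end, cur0)])
                truth.add_blocks(1, [(tract.start, tract.end, cur1)])
                cur0 += n
                cur1 += n

            elif tract.label in ("heterozygous_collinear", "hemizygous_insert"):
                shared, s_sites = _mutate_snps(seg, model.shared_snp_rate, rng)
                truth.snp_counts["shared"] += len(s_sites)
                ins_carrier = int(rng.integers(0, 2)) if tract.label == "hemizygous_insert" else None
                arrs = []
                for hap in (0, 1):
                    mutated, p_sites = _mutate_snps(shared, model.private_snp_rate, rng)
                    truth.snp_counts[f"hap{hap}"] += len(p_sites)
                    k = rng.binomial(n, model.small_indel_rate / 2.0)
                    pos = np.sort(rng.integers(0, n, k)) if k else np.empty(0, dtype=np.int64)
                    lens = _geometric_lengths(rng, k, model.small_indel_p)
                    kinds = rng.random(k) < 0.5
                    indels = [
                        (int(p), int(l), "ins" if ki else "del")
                        for p, l, ki in zip(pos, lens, kinds)
                    ]
                    if ins_carrier is not None and hap == ins_carrier:
                        ins_len = int(rng.integers(*model.large_insert_range))
                        ins_pos = int(rng.integers(n // 4, 3 * n // 4))
                        indels.append((ins_pos, ins_len, "ins"))
                        indels.sort(key=lambda e: e[0])
                        big = (ins_pos, ins_len)
                    else:
                        big = None
                    arr, blocks, realized = _apply_indels(mutated, indels, rng)
                    cur = cur0 if hap == 0 else cur1
                    truth.add_blocks(
                        hap, [(tract.start + a, tract.start + b, cur + h) for a, b, h in blocks]
                    )
                    hap_sites = _lift_local(p_sites, blocks) + cur
                    truth.polymorphic_sites[hap].extend(int(x) for x in hap_sites)
                    for rpos, rlen, kind, hlo, hhi in realized:
                        is_big = big is not None and kind == "ins" and (rpos, rlen) == big
                        span = (cur + hlo, cur + hhi)
                        ev = VariantEvent(
                            kind="hemizygous_insert" if is_big else f"small_{'insertion' if kind == 'ins' else 'deletion'}",
                            carrier=hap,
                            ref_pos=tract.start + rpos,
                            hap0_span=span if hap == 0 else None,
                            hap1_span=span if hap == 1 else None,
                            length=rlen,
                            dlen_hap0=(rlen if kind == "ins" else -rlen) if hap == 0 else 0,
                            dlen_hap1=(rlen if kind == "ins" else -rlen) if hap == 1 else 0,
                        )
                        truth.events.append(ev)
                        if is_big:
                            truth.polymorphic_intervals[hap].append(span)
                        elif kind == "ins":
                            truth.polymorphic_sites[hap].extend(range(span[0], span[1]))
                    arrs.append(arr)
                parts0.append(arrs[0])
                parts1.append(arrs[1])
                cur0 += len(arrs[0])
                cur1 += len(arrs[1])

            elif tract.label == "cluster_break":
                c_lo, c_hi = model.cluster_copies
                unit_len = min(model.cluster_unit_len, max(1, n // (2 * c_hi)))
                if unit_len * c_hi > n:
                    # tract too small to host a tandem array at this scale
                    unit_len = max(1, n // c_hi)
                arr0, arr1, rec = plant_cluster_break(
                    seg, unit_len, c_lo, c_hi, model.cluster_unit_divergence, rng
                )
                parts0.append(arr0)
                parts1.append(arr1)
                for hap, cur in ((0, cur0), (1, cur1)):
                    suffix = rec[f"suffix_ref_start_hap{hap}"]
                    truth.add_blocks(
                        hap, [(tract.start + suffix, tract.end, cur + suffix)]
                    )
                poly_hi = rec["polymorphic_until"]
                truth.events.append(
                    VariantEvent(
                        kind="cluster_break",
                        carrier=None,
                        ref_pos=tract.start,
                        hap0_span=(cur0, cur0 + poly_hi),
                        hap1_span=(cur1, cur1 + poly_hi),
                        length=unit_len,
                        dlen_hap0=rec["dlen_hap0"],
                        dlen_hap1=rec["dlen_hap1"],
                        detail=f"copies={rec['copies']}",
                    )
                )
                truth.polymorphic_intervals[0].append((cur0, cur0 + poly_hi))
                truth.polymorphic_intervals[1].append((cur1, cur1 + poly_hi))
                cur0 += len(arr0)
                cur1 += len(arr1)

            elif tract.label == "non_alignable":
                arr0 = random_sequence(rng, n)
                arr1 = random_sequence(rng, n)
                if region.region_class == "central_het" and model.shared_segment_count:
                    holes0, holes1 = _plant_shared_segments(
                        arr0, arr1, model, rng, truth.events, cur0, cur1, tract.start
                    )
                else:
                    holes0, holes1 = [], []
                parts0.append(arr0)
                parts1.append(arr1)
                for hap, holes, cur in ((0, holes0, cur0), (1, holes1, cur1)):
                    for a, b in _subtract((0, n), holes):
                        truth.polymorphic_intervals[hap].append((cur + a, cur + b))
                cur0 += n
                cur1 += n
            else:
                raise ConfigurationError(f"unknown tract label {tract.label!r}")

            truth.tracts.append(
                TractRecord(tract.label, (tract.start, tract.end), (t0, cur0), (t1, cur1), region.name)
            )

    hap0 = np.concatenate(parts0)
    hap1 = np.concatenate(parts1)
    truth.finalize()
    return hap0, hap1, truth
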