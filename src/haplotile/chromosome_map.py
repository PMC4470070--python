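"""Integration of genetic bins, cytogenetic FISH positions and reference
alignment into an ordered chromosome map.

The three coordinate systems of a chromosome project disagree in
characteristic ways: the genetic map collapses the recombination-free
heterochromatin into a single bin, the cytogenetic (pachytene) map
compresses the condensed heterochromatin to a fraction of its sequence
length, and only the reference alignment offers base-pair resolution --
where collinearity holds.  A FISH signal position is summarised as a
*fraction length*: FL = (S / T) * binT, where S is the distance from the
chromosome's north end to the signal, T the total chromosome length
(both in um on the same spread) and binT the total bin count, so FL is
directly comparable to genetic bin numbers.

Ordering policy: in the euchromatic arms, marker bins order the paths,
FISH breaks ties and the reference alignment refines within a bin; in
the heterochromatin borders the reference alignment may be used; in the
central heterochromatin only a direct FISH anchor (or an alignment
chained to one) places a path -- everything else keeps an arbitrary
position and is flagged as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bac_resources import AFLPMarker, GeneticBinMap
from .errors import InputError
from .synthetic_genome import RegionSpec
from .tiling import TilingPath

__all__ = [
    "FISHMeasurement",
    "fraction_length",
    "CondensationModel",
    "simulate_fish",
    "allelism_test",
    "AllelismVerdict",
    "RefAlign",
    "Placement",
    "ChromosomeMap",
    "order_paths",
    "region_table",
    "region_table_from_cells",
]

REGION_COLUMNS = [
    "north_euchromatin",
    "north_het_border",
    "central_heterochromatin",
    "south_het_border",
    "south_euchromatin",
]


@dataclass
class FISHMeasurement:
    """Per-cell FISH signal distances for one clone or path probe."""

    clone_id: str
    S: np.ndarray  # um from the north end to the signal, one per cell
    T: np.ndarray  # total chromosome length in um, one per cell
    binT: int = 78

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.S.size < 1 or self.S.shape != self.T.shape:
            raise InputError("need >= 1 cell with paired S and T")
        if (self.T <= 0).any():
            raise InputError("total chromosome length T must be positive")
        if ((self.S < 0) | (self.S > self.T)).any():
            raise InputError("S must satisfy 0 <= S <= T in every cell")

    @property
    def n_cells(self) -> int:
        return self.S.size


def fraction_length(m: FISHMeasurement) -> tuple[float, float]:
    """Mean and sample sd of FL = (S / T) * binT over cells (bin units)."""
    fl = m.S / m.T * m.binT
    mean = float(np.mean(fl))
    sd = float(np.std(fl, ddof=1)) if m.n_cells > 1 else 0.0
    return round(mean, 2), round(sd, 2)


@dataclass
class CondensationModel:
    """Piecewise-linear map from sequence fraction to cytogenetic fraction.

    The heterochromatin occupies ``het_seq_lo..het_seq_hi`` of the
    sequence but only ``het_cyto_fraction`` of the pachytene chromosome
    length; the euchromatic arms share the remaining cytogenetic length
    proportionally to their sequence lengths.
    """

    het_seq_lo: float
    het_seq_hi: float
    het_cyto_fraction: float = 0.40

    @classmethod
    def from_regions(cls, regions: list[RegionSpec], het_cyto_fraction: float = 0.40):
        het = [r for r in regions if r.region_class in ("het_border", "central_het")]
        total = max(r.end for r in regions)
        return cls(
            het_seq_lo=min(r.start for r in het) / total,
            het_seq_hi=max(r.end for r in het) / total,
            het_cyto_fraction=het_cyto_fraction,
        )

    def cyto_fraction(self, seq_fraction: float) -> float:
        if not 0 <= seq_fraction <= 1:
            raise InputError("sequence fraction outside [0, 1]")
        lo, hi = self.het_seq_lo, self.het_seq_hi
        north = lo
        south = 1.0 - hi
        eu_cyto = 1.0 - self.het_cyto_fraction
        c_north = eu_cyto * north / (north + south) if north + south > 0 else 0.0
        c_south = eu_cyto - c_north
        if seq_fraction < lo:
            return seq_fraction / lo * c_north if lo else 0.0
        if seq_fraction < hi:
            return c_north + (seq_fraction - lo) / (hi - lo) * self.het_cyto_fraction
        if hi == 1.0:
            return 1.0
        return c_north + self.het_cyto_fraction + (seq_fraction - hi) / (1.0 - hi) * c_south

    def seq_fraction(self, cyto_fraction: float) -> float:
        """Inverse map: cytogenetic fraction back to sequence fraction.

        Inside the heterochromatin plateau the inverse is the linear
        interpolant across the compressed interval.
        """
        if not 0 <= cyto_fraction <= 1:
            raise InputError("cytogenetic fraction outside [0, 1]")
        lo, hi = self.het_seq_lo, self.het_seq_hi
        north = lo
        south = 1.0 - hi
        eu_cyto = 1.0 - self.het_cyto_fraction
        c_north = eu_cyto * north / (north + south) if north + south > 0 else 0.0
        c_south = eu_cyto - c_north
        if cyto_fraction < c_north:
            return cyto_fraction / c_north * lo if c_north else 0.0
        if cyto_fraction < c_north + self.het_cyto_fraction:
            return lo + (cyto_fraction - c_north) / self.het_cyto_fraction * (hi - lo)
        if c_south == 0:
            return 1.0
        return hi + (cyto_fraction - c_north - self.het_cyto_fraction) / c_south * (1.0 - hi)


def simulate_fish(
    true_position: int,
    condensation: CondensationModel,
    total_length: int,
    n_cells: int = 20,
    noise_sd: float = 2.0,
    seed: int = 0,
    binT: int = 78,
    clone_id: str = "probe",
    chromosome_um: float = 50.0,
) -> FISHMeasurement:
    """Emulate a pachytene FISH experiment for a probe at a known position.

    The sequence coordinate is mapped through the condensation model to
    a cytogenetic fraction, converted to a distance on a chromosome of
    ``chromosome_um`` um, and per-cell Gaussian noise of ``noise_sd``
    (bin units) is added to the signal position.
    """
    if n_cells < 1:
        raise InputError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    frac = condensation.cyto_fraction(true_position / total_length)
    fl_true = frac * binT
    T = np.full(n_cells, chromosome_um)
    fl_obs = fl_true + (rng.normal(0.0, noise_sd, n_cells) if noise_sd > 0 else 0.0)
    fl_obs = np.clip(fl_obs, 0.0, binT)
    S = fl_obs / binT * T
    return FISHMeasurement(clone_id, S, T, binT)


@dataclass
class AllelismVerdict:
    verdict: str  # consistent | different | ambiguous
    delta: float


def allelism_test(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    k: float = 2.0,
) -> AllelismVerdict:
    """Do two FISH fraction-length estimates mark the same position?

    Two probes are *different* when their mean +/- k standard errors
    intervals are disjoint -- the signature of co-aligning sequence
    blocks that are in fact not allelic; *consistent* when the
    separation is within k pooled-scale standard errors; ambiguous
    otherwise.
    """
    if n_a < 2 or n_b < 2:
        raise InputError("allelism test needs >= 2 cells per probe")
    delta = abs(mean_a - mean_b)
    half_a = k * sd_a / math.sqrt(n_a)
    half_b = k * sd_b / math.sqrt(n_b)
    disjoint = (mean_a + half_a < mean_b - half_b) or (mean_b + half_b < mean_a - half_a)
    if disjoint:
        verdict = "different"
    elif delta <= k * max(sd_a, sd_b) / math.sqrt(min(n_a, n_b)):
        verdict = "consistent"
    else:
        verdict = "ambiguous"
    return AllelismVerdict(verdict, round(delta, 2))


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

@dataclass
class RefAlign:
    """Summary of a path's alignment to the reference pseudomolecule."""

    position: int  # representative reference coordinate
    span: tuple[int, int]
    C: float
    unique: bool = True


@dataclass
class Placement:
    path_id: str
    rank: int
    region: str
    status: str  # ordered | arbitrary
    evidence: set = field(default_factory=set)
    coordinate: int | None = None
    median_bin: float | None = None
    fl: float | None = None
    conflict: bool = False


@dataclass
class ChromosomeMap:
    placements: list[Placement]

    def ordered(self) -> list[Placement]:
        return [p for p in self.placements if p.status == "ordered"]

    def arbitrary(self) -> list[Placement]:
        return [p for p in self.placements if p.status == "arbitrary"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path_id": [p.path_id for p in self.placements],
                "rank": [p.rank for p in self.placements],
                "region": [p.region for p in self.placements],
                "status": [p.status for p in self.placements],
                "evidence": ["+".join(sorted(p.evidence)) or "none" for p in self.placements],
                "median_bin": [p.median_bin for p in self.placements],
                "FL": [p.fl for p in self.placements],
                "ref_coordinate": [p.coordinate for p in self.placements],
                "conflict": [p.conflict for p in self.placements],
            }
        )


def _region_at(regions: list[RegionSpec], pos: int) -> str:
    for r in regions:
        if r.start <= pos < r.end:
            return r.name
    return regions[-1].name


def order_paths(
    paths: list[TilingPath],
    markers: list[AFLPMarker],
    fish: dict[str, tuple[float, float]],
    ref_alignments: dict[str, RefAlign],
    region_specs: list[RegionSpec],
    bin_map: GeneticBinMap,
    green_threshold: float = 0.75,
    condensation: CondensationModel | None = None,
) -> ChromosomeMap:
    """Place tiling paths on the chromosome with explicit evidence tracking.

    Region assignment prefers a good unique reference alignment, then
    the marker bin (the heterochromatin bin cannot separate borders
    from the centre, so bin-only heterochromatin paths fall into the
    central pool).  Ordering uses bin > FISH > reference-position
    precedence; central-heterochromatin paths without a FISH anchor or
    an alignment chained to one stay at arbitrary positions.
    """
    marker_by_id = {m.id: m for m in markers}
    het_names = {r.name for r in region_specs if r.region_class in ("het_border", "central_het")}
    placements = []
    for p in paths:
        bins = [marker_by_id[mid].bin for mid in p.marker_ids if mid in marker_by_id]
        median_bin = float(np.median(bins)) if bins else None
        fl = fish.get(p.id, (None, None))[0]
        ra = ref_alignments.get(p.id)
        good_ra = ra is not None and ra.C >= green_threshold and ra.unique
        evidence = set()
        if bins:
            evidence.add("bin")
        if fl is not None:
            evidence.add("fish")
        if good_ra:
            evidence.add("ref_align")

        if good_ra:
            region = _region_at(region_specs, ra.position)
        elif median_bin is not None:
            if median_bin == bin_map.het_bin:
                region = "central_heterochromatin"
            elif median_bin < bin_map.het_bin:
                region = "north_euchromatin"
            else:
                region = "south_euchromatin"
        elif fl is not None:
            region = "central_heterochromatin"
        else:
            region = "central_heterochromatin"

        if region == "central_heterochromatin":
            # only a FISH anchor (or an alignment chained to one) orders here
            status = "ordered" if fl is not None else "arbitrary"
        else:
            status = "ordered" if (bins or fl is not None or good_ra) else "arbitrary"
        placements.append(
            Placement(
                path_id=p.id,
                rank=-1,
                region=region,
                status=status,
                evidence=evidence,
                coordinate=ra.position if good_ra else None,
                median_bin=median_bin,
                fl=fl,
                conflict=False,
            )
        )

    # chained placement: an arbitrary central-het path whose good alignment
    # overlaps the reference span of a FISH-anchored path inherits an order
    fish_spans = [
        ref_alignments[p.path_id].span
        for p in placements
        if p.region == "central_heterochromatin" and p.status == "ordered"
        and p.path_id in ref_alignments
    ]
    for p in placements:
        if p.region != "central_heterochromatin" or p.status == "ordered":
            continue
        ra = ref_alignments.get(p.path_id)
        if ra is None or ra.C < green_threshold or not ra.unique:
            continue
        for lo, hi in fish_spans:
            if ra.span[0] < hi and lo < ra.span[1]:
                p.status = "ordered"
                p.evidence.add("ref_align")
                p.coordinate = ra.position
                break

    # Evidence is quantized to its real resolution before sorting: bins
    # are integers, a FISH fraction length is good to about one bin
    # (and is read against the genetic map through the inverse of the
    # condensation model, so both live on the bin axis), and the
    # reference coordinate refines the order within a bin.
    big = 10 ** 12

    def fl_as_bin(fl: float) -> int:
        if condensation is not None and bin_map.total_length:
            seq_pos = condensation.seq_fraction(min(1.0, fl / bin_map.binT))
            pos = min(bin_map.total_length - 1, int(seq_pos * bin_map.total_length))
            return bin_map.bin_of(pos)
        return round(fl)

    def base_key(pl: Placement):
        if pl.median_bin is not None:
            b = round(pl.median_bin)
        elif pl.fl is not None:
            b = fl_as_bin(pl.fl)
        else:
            b = big
        c = pl.coordinate if pl.coordinate is not None else big
        f = round(pl.fl) if pl.fl is not None else big
        return (b, c, f)

    keys = {pl.path_id: base_key(pl) for pl in placements}

    # Allelic partners -- paths of opposite phase covering the same
    # reference span -- sit at the same bin; their mutual order comes
    # from the reference coordinate, the only evidence fine enough.
    phase_of = {p.id: p.phase for p in paths}
    ordered_pl = [p for p in placements if p.status == "ordered"]
    def good(align: RefAlign | None) -> bool:
        return align is not None and align.C >= green_threshold and align.unique

    partner = {pl.path_id: pl.path_id for pl in placements}

    def find(x):
        while partner[x] != x:
            partner[x] = partner[partner[x]]
            x = partner[x]
        return x

    for i, a in enumerate(ordered_pl):
        ra = ref_alignments.get(a.path_id)
        if not good(ra):
            continue
        for b in ordered_pl[i + 1:]:
            rb = ref_alignments.get(b.path_id)
            if not good(rb):
                continue
            if {phase_of.get(a.path_id), phase_of.get(b.path_id)} != {0, 1}:
                continue
            ov = min(ra.span[1], rb.span[1]) - max(ra.span[0], rb.span[0])
            shorter = min(ra.span[1] - ra.span[0], rb.span[1] - rb.span[0])
            if shorter > 0 and ov / shorter >= 0.5:
                ba = min(keys[a.path_id][0], keys[b.path_id][0])
                keys[a.path_id] = (ba,) + keys[a.path_id][1:]
                keys[b.path_id] = (ba,) + keys[b.path_id][1:]
                partner[find(a.path_id)] = find(b.path_id)

    # partners are the same chromosome position on opposite homologues:
    # they keep their list order (reference coordinate) but share a rank
    ordered = sorted(ordered_pl, key=lambda p: (keys[p.path_id], p.path_id))
    arbitrary = sorted([p for p in placements if p.status == "arbitrary"], key=lambda p: p.path_id)
    group_rank: dict[str, int] = {}
    for idx, p in enumerate(ordered + arbitrary):
        g = find(p.path_id)
        p.rank = group_rank.setdefault(g, idx)

    # flag bin-vs-reference order conflicts instead of resolving them
    with_both = [p for p in ordered if p.median_bin is not None and p.coordinate is not None]
    for a, b in zip(with_both, with_both[1:]):
        if a.median_bin != b.median_bin and (
            (a.median_bin < b.median_bin) != (a.coordinate < b.coordinate)
        ):
            a.conflict = b.conflict = True
    return ChromosomeMap(ordered + arbitrary)


# ---------------------------------------------------------------------------
# region distribution table
# ---------------------------------------------------------------------------

def _phase_class(phase) -> str:
    if phase == 0:
        return "haplotype_0"
    if phase == 1:
        return "haplotype_1"
    if phase == "monomorphic":
        return "homozygous"
    return "unknown"


def region_table(
    cmap: ChromosomeMap,
    paths: list[TilingPath],
    region_specs: list[RegionSpec],
    ref_alignments: dict[str, RefAlign] | None = None,
) -> pd.DataFrame:
    """Non-redundant consensus bp per haplotype class and chromosome region.

    A path whose reference span crosses a region boundary is split
    pro-rata by overlap length (integer remainders assigned to the last
    overlapped region, keeping row sums exact); paths without a usable
    reference span are counted entirely in their assigned region.
    Row and column totals are always computed, never supplied.
    """
    ref_alignments = ref_alignments or {}
    by_id = {p.id: p for p in paths}
    rows = ["homozygous", "unknown", "haplotype_0", "haplotype_1"]
    table = {r: {c: 0 for c in REGION_COLUMNS} for r in rows}
    for pl in cmap.placements:
        path = by_id[pl.path_id]
        cls = _phase_class(path.phase)
        ra = ref_alignments.get(pl.path_id)
        length = path.consensus_length
        if ra is not None and ra.span is not None:
            lo, hi = ra.span
            overlaps = []
            for r in region_specs:
                ov = min(hi, r.end) - max(lo, r.start)
                if ov > 0:
                    overlaps.append((r.name, ov))
            if overlaps:
                total_ov = sum(ov for _, ov in overlaps)
                assigned = 0
                for i, (name, ov) in enumerate(overlaps):
                    if i == len(overlaps) - 1:
                        part = length - assigned
                    else:
                        part = int(length * ov / total_ov)
                    table[cls][name] += part
                    assigned += part
                continue
        table[cls][pl.region] += length
    df = pd.DataFrame(table).T[REGION_COLUMNS]
    df.loc["totals"] = df.sum(axis=0)
    df["totals"] = df.sum(axis=1)
    return df.astype(np.int64)


def region_table_from_cells(cells: dict[str, list[int]]) -> pd.DataFrame:
    """Build a region table from given per-cell values, computing totals.

    ``cells`` maps a haplotype-class label to its five per-region bp
    values (zeros where a class has no sequence in a region).
    """
    for k, v in cells.items():
        if len(v) != len(REGION_COLUMNS):
            raise InputError(f"row {k!r} must have {len(REGION_COLUMNS)} cells")
    df = pd.DataFrame(cells, index=REGION_COLUMNS).T
    df.loc["totals"] = df.sum(axis=0)
    df["totals"] = df.sum(axis=1)
    return df.astype(np.int64)
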