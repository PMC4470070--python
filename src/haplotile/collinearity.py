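"""Anchor-based pairwise collinearity analysis.

Two sequences are compared through their maximal exact matches (MEMs) of
length >= ``w`` on both strands, in the spirit of a word-based dot plot.
Anchors are chained into collinear segments by grouping them into
diagonal bands, segments are trimmed to be non-overlapping on both
coordinates, and the fraction of collinear sequence is summarised by

    C = 2 * O / (L1 + L2)

where ``O`` is the total length of the collinear sequence segments
(defined here as the mean of the merged segment projections on the two
sequences, which keeps C symmetric) and L1, L2 are the compared lengths.
C = 1 means full collinear overlap.  Hemizygous presence/absence
variants appear as gaps covered on one sequence but absent from the
other, and are called as inserts above a configurable minimum size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .sequtil import encode, revcomp

__all__ = [
    "Anchor",
    "CollinearSegment",
    "CollinearityResult",
    "InsertCall",
    "OverlapMatrix",
    "find_anchors",
    "chain_anchors",
    "trim_segments",
    "collinearity_C",
    "recovery_percent",
    "classify_band",
    "detect_inserts",
    "compare",
    "overlap_matrix",
]

BAND_THRESHOLDS = {"green": 0.75, "yellow": 0.50, "orange": 0.25}


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match: A[x:x+length] == B[y:y+length] (strand +).

    For strand '-', A[x:x+length] equals the reverse complement of
    B[y:y+length]; ``y`` is always on the forward strand of B.
    """

    x: int
    y: int
    length: int
    strand: str = "+"

    @property
    def x_end(self) -> int:
        return self.x + self.length

    @property
    def y_end(self) -> int:
        return self.y + self.length


@dataclass
class CollinearSegment:
    """A chained run of co-monotone anchors forming one dot-plot diagonal."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    n_anchors: int
    anchor_bp: int  # summed anchor length (chain score)

    @property
    def len_a(self) -> int:
        return self.a_end - self.a_start

    @property
    def len_b(self) -> int:
        return self.b_end - self.b_start


@dataclass
class InsertCall:
    """A presence/absence variant: sequence on one side with no counterpart."""

    carrier: str  # 'A' or 'B'
    start: int
    end: int
    length: int
    flank_left: int  # indices into the segment list
    flank_right: int


@dataclass
class CollinearityResult:
    O: float
    L1: int
    L2: int
    C: float
    band: str
    segments: list[CollinearSegment] = field(default_factory=list)
    inserts: list[InsertCall] = field(default_factory=list)


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return encode(seq)


def _kmer_keys(codes: np.ndarray, w: int) -> np.ndarray:
    """2-bit pack every w-mer into a uint64 (requires w <= 32)."""
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    k = codes.astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for i in range(w):
        out |= k[i:i + n] << np.uint64(2 * (w - 1 - i))
    return out


def _seed_pairs(ka: np.ndarray, kb: np.ndarray, max_freq: int):
    """All (i, j) with ka[i] == kb[j], excluding words above max_freq."""
    if len(ka) == 0 or len(kb) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ua, ca = np.unique(ka, return_counts=True)
    ub, cb = np.unique(kb, return_counts=True)
    bad = np.union1d(ua[ca > max_freq], ub[cb > max_freq])
    order = np.argsort(ka, kind="stable")
    sa = ka[order]
    left = np.searchsorted(sa, kb, side="left")
    right = np.searchsorted(sa, kb, side="right")
    counts = right - left
    if len(bad):
        counts[np.isin(kb, bad)] = 0
    nz = np.flatnonzero(counts)
    if len(nz) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    reps = counts[nz]
    total = int(reps.sum())
    base = np.repeat(left[nz], reps)
    step = np.arange(total) - np.repeat(np.cumsum(reps) - reps, reps)
    i = order[base + step]
    j = np.repeat(nz, reps)
    return i.astype(np.int64), j.astype(np.int64)


def _maximal_runs(i: np.ndarray, j: np.ndarray, w: int, ca: np.ndarray, cb: np.ndarray):
    """Merge seed hits on each diagonal into maximal exact matches."""
    if len(i) == 0:
        return []
    diag = i - j
    order = np.lexsort((i, diag))
    i, j, diag = i[order], j[order], diag[order]
    breaks = np.flatnonzero((np.diff(diag) != 0) | (np.diff(i) != 1))
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(i) - 1]])
    na, nb = len(ca), len(cb)
    out = set()
    for s, e in zip(starts, ends):
        x, y = int(i[s]), int(j[s])
        ln = int(i[e]) - x + w
        # extend across word-frequency-filtered gaps to restore maximality
        while x > 0 and y > 0 and ca[x - 1] == cb[y - 1]:
            x -= 1
            y -= 1
            ln += 1
        while x + ln < na and y + ln < nb and ca[x + ln] == cb[y + ln]:
            ln += 1
        out.add((x, y, ln))
    return sorted(out)


def find_anchors(seq_a, seq_b, w: int = 20, max_freq: int = 50, strands: str = "+-",
                 b_keys_fwd: np.ndarray | None = None) -> list[Anchor]:
    """All maximal exact matches of length >= w between two sequences.

    Both strands are scanned by default (``strands`` restricts the
    search); words occurring more than ``max_freq`` times on either
    sequence are dropped before seeding, which keeps high-copy tandem
    repeats from flooding the anchor set (merged runs are re-extended,
    so anchors remain maximal).
    """
    if w < 8:
        raise InputError("word length w must be >= 8")
    if w > 32:
        raise InputError("word length w must be <= 32 (2-bit packing)")
    ca, cb = _as_codes(seq_a), _as_codes(seq_b)
    if len(ca) < w or len(cb) < w:
        return []
    ka = _kmer_keys(ca, w)
    anchors = []
    passes = [("+", cb)] if strands == "+" else (
        [("-", revcomp(cb))] if strands == "-" else [("+", cb), ("-", revcomp(cb))]
    )
    for strand, codes_b in passes:
        if strand == "+" and b_keys_fwd is not None:
            kb = b_keys_fwd  # caller-cached packed words of seq_b
        else:
            kb = _kmer_keys(codes_b, w)
        i, j = _seed_pairs(ka, kb, max_freq)
        for x, y, ln in _maximal_runs(i, j, w, ca, codes_b):
            if strand == "-":
                y = len(cb) - y - ln
            anchors.append(Anchor(x, y, ln, strand))
    return anchors


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def chain_anchors(
    anchors: list[Anchor],
    max_gap: int = 10_000,
    max_diag_drift: int = 5_000,
    len_b: int | None = None,
) -> list[CollinearSegment]:
    """Group anchors into co-monotone collinear segments.

    Anchors are clustered into diagonal bands by single linkage on the
    diagonal offset (tolerance ``max_diag_drift``), then split wherever
    the positional gap between consecutive anchors exceeds ``max_gap``.
    Reverse-strand anchors are chained on the anti-diagonal frame, for
    which ``len_b`` (length of sequence B) is required if any '-' anchor
    is present.
    """
    segments: list[CollinearSegment] = []
    for strand in ("+", "-"):
        sub = [a for a in anchors if a.strand == strand]
        if not sub:
            continue
        if strand == "-":
            if len_b is None:
                raise InputError("len_b is required to chain reverse-strand anchors")
            ys = np.array([len_b - a.y - a.length for a in sub])
        else:
            ys = np.array([a.y for a in sub])
        xs = np.array([a.x for a in sub])
        ls = np.array([a.length for a in sub])
        diag = xs - ys
        order = np.argsort(diag, kind="stable")
        band_break = np.flatnonzero(np.diff(diag[order]) > max_diag_drift)
        band_starts = np.concatenate([[0], band_break + 1])
        band_ends = np.concatenate([band_break + 1, [len(sub)]])
        for bs, be in zip(band_starts, band_ends):
            idx = order[bs:be]
            idx = idx[np.argsort(xs[idx], kind="stable")]
            cur = [idx[0]]
            for k in idx[1:]:
                prev = cur[-1]
                gx = xs[k] - (xs[prev] + ls[prev])
                gy = ys[k] - (ys[prev] + ls[prev])
                if gx > max_gap or gy > max_gap or ys[k] + ls[k] < ys[prev] + ls[prev]:
                    segments.append(_make_segment(cur, xs, ys, ls, strand, len_b))
                    cur = [k]
                else:
                    cur.append(k)
            segments.append(_make_segment(cur, xs, ys, ls, strand, len_b))
    return segments


def _make_segment(members, xs, ys, ls, strand, len_b):
    a0 = int(min(xs[m] for m in members))
    a1 = int(max(xs[m] + ls[m] for m in members))
    b0 = int(min(ys[m] for m in members))
    b1 = int(max(ys[m] + ls[m] for m in members))
    if strand == "-":
        b0, b1 = len_b - b1, len_b - b0
    return CollinearSegment(
        a_start=a0,
        a_end=a1,
        b_start=b0,
        b_end=b1,
        strand=strand,
        n_anchors=len(members),
        anchor_bp=int(sum(ls[m] for m in members)),
    )


def _clip(lo, hi, claimed):
    """Clip [lo, hi) against claimed intervals (edge clipping)."""
    for a, b in claimed:
        if a <= lo < b:
            lo = b
        if a < hi <= b:
            hi = a
        if lo < a and hi > b:
            # claimed interval strictly inside: keep the larger side
            if a - lo >= hi - b:
                hi = a
            else:
                lo = b
    return lo, hi


def trim_segments(segments: list[CollinearSegment]) -> list[CollinearSegment]:
    """Make segments non-overlapping on both coordinates.

    Segments are admitted greedily by descending anchor support; later
    segments are clipped against the intervals already claimed on each
    sequence and dropped when nothing remains.  This prevents tandem
    duplication blocks (one region matching many) from being counted
    more than once in the overlap length O.
    """
    out = []
    claimed_a: list[tuple[int, int]] = []
    claimed_b: list[tuple[int, int]] = []
    for seg in sorted(segments, key=lambda s: -s.anchor_bp):
        a0, a1 = _clip(seg.a_start, seg.a_end, claimed_a)
        b0, b1 = _clip(seg.b_start, seg.b_end, claimed_b)
        if a1 - a0 <= 0 or b1 - b0 <= 0:
            continue
        shrink = min((a1 - a0) / seg.len_a, (b1 - b0) / seg.len_b)
        out.append(
            CollinearSegment(a0, a1, b0, b1, seg.strand, seg.n_anchors,
                             int(seg.anchor_bp * shrink))
        )
        claimed_a.append((a0, a1))
        claimed_b.append((b0, b1))
    out.sort(key=lambda s: s.a_start)
    return out


# ---------------------------------------------------------------------------
# the C statistic
# ---------------------------------------------------------------------------

def _merged_total(intervals) -> int:
    total = 0
    for lo, hi in _merge(intervals):
        total += hi - lo
    return total


def _merge(intervals):
    out = []
    for lo, hi in sorted(intervals):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def classify_band(C: float) -> str:
    """Colour-code a collinearity value: green >= 0.75 is a good alignment."""
    if not -1e-9 <= C <= 1 + 1e-9:
        raise InputError(f"C = {C} outside [0, 1]")
    for band, thr in BAND_THRESHOLDS.items():
        if C >= thr:
            return band
    return "red"


def collinearity_C(segments: list[CollinearSegment], L1: int, L2: int) -> CollinearityResult:
    """Summarise chained segments into the collinearity statistic C.

    O is the mean of the merged segment projections on the two
    sequences, so C(A, B) == C(B, A) exactly.
    """
    if L1 <= 0 or L2 <= 0:
        raise InputError("compared lengths must be positive")
    proj_a = _merged_total([(s.a_start, s.a_end) for s in segments])
    proj_b = _merged_total([(s.b_start, s.b_end) for s in segments])
    O = min((proj_a + proj_b) / 2.0, float(L1), float(L2))
    C = min(1.0, 2.0 * O / (L1 + L2))
    return CollinearityResult(O=O, L1=L1, L2=L2, C=C, band=classify_band(C), segments=segments)


def recovery_percent(O: float, L: float) -> float:
    """Percent of a sequence set recovered in another: 100 * O / L."""
    if L <= 0:
        raise InputError("sequence length must be positive")
    if not 0 <= O <= L:
        raise InputError("overlap must satisfy 0 <= O <= L")
    return 100.0 * O / L


def detect_inserts(
    result: CollinearityResult,
    min_insert: int = 20_000,
    max_counterpart_gap: int = 5_000,
) -> list[InsertCall]:
    """Call hemizygous inserts from gaps between collinear flanks.

    A gap of at least ``min_insert`` bp on one sequence, faced by at
    most ``max_counterpart_gap`` bp on the other, between two collinear
    segments is called as a one-sided (presence/absence) insert on the
    gapped sequence.  Only plus-strand segment pairs are considered.
    """
    segs = [s for s in result.segments if s.strand == "+"]
    segs.sort(key=lambda s: s.a_start)
    calls = []
    for k in range(len(segs) - 1):
        left, right = segs[k], segs[k + 1]
        gap_a = right.a_start - left.a_end
        gap_b = right.b_start - left.b_end
        if gap_a >= min_insert and gap_b <= max_counterpart_gap:
            calls.append(
                InsertCall("A", left.a_end, right.a_start, gap_a - max(gap_b, 0), k, k + 1)
            )
        elif gap_b >= min_insert and gap_a <= max_counterpart_gap:
            calls.append(
                InsertCall("B", left.b_end, right.b_start, gap_b - max(gap_a, 0), k, k + 1)
            )
    result.inserts = calls
    return calls


def compare(
    seq_a,
    seq_b,
    w: int = 20,
    max_gap: int = 10_000,
    max_diag_drift: int = 5_000,
    max_freq: int = 50,
    min_insert: int = 20_000,
    strands: str = "+-",
) -> CollinearityResult:
    """End-to-end pairwise comparison: anchors, chains, C, inserts."""
    ca, cb = _as_codes(seq_a), _as_codes(seq_b)
    anchors = find_anchors(ca, cb, w=w, max_freq=max_freq, strands=strands)
    segments = trim_segments(chain_anchors(anchors, max_gap, max_diag_drift, len_b=len(cb)))
    result = collinearity_C(segments, len(ca), len(cb))
    detect_inserts(result, min_insert=min_insert)
    return result


# ---------------------------------------------------------------------------
# set-versus-set overlap (central heterochromatin quantification)
# ---------------------------------------------------------------------------

@dataclass
class OverlapMatrix:
    """Pairwise overlap between named haplotype sequence collections.

    ``O_kb[i][j]`` is the overlap length between set i and set j in kb
    (upper triangle of the printed table); ``recovery[i][j]`` is the
    percentage of set i's sequence recovered in set j (lower triangle).
    Recovery is intentionally asymmetric: it is normalised by the
    length of the recovered (row) set.
    """

    names: list[str]
    n_sequences: list[int]
    total_kb: list[float]
    O_kb: np.ndarray
    recovery: np.ndarray

    def to_frame(self):
        import pandas as pd

        n = len(self.names)
        cells = np.full((n, n), "", dtype=object)
        for i in range(n):
            for j in range(n):
                if i < j:
                    cells[i, j] = f"{self.O_kb[i, j]:.0f}"
                elif i > j:
                    cells[i, j] = f"{self.recovery[i, j]:.1f}"
                else:
                    cells[i, j] = "--"
        df = pd.DataFrame(cells, index=self.names, columns=self.names)
        df.insert(0, "total_kb", [f"{x:.0f}" for x in self.total_kb])
        df.insert(0, "n_sequences", self.n_sequences)
        return df


def overlap_matrix(seq_sets: dict[str, list], w: int = 20, **kwargs) -> OverlapMatrix:
    """All-versus-all overlap quantification between sequence collections.

    For every pair of sets, every cross pair of sequences is compared;
    covered intervals are merged per sequence so repeated matches are
    not double counted.  O is the mean of the two per-set coverages.
    """
    names = list(seq_sets)
    if len(names) < 2:
        raise InputError("at least two sequence sets are required")
    sets = {k: [_as_codes(s) for s in v] for k, v in seq_sets.items()}
    for k, v in sets.items():
        if not v:
            raise InputError(f"sequence set {k!r} is empty")
    lens = {k: [len(s) for s in v] for k, v in sets.items()}
    n = len(names)
    O_kb = np.zeros((n, n))
    recovery = np.zeros((n, n))
    for i in range(n):
        recovery[i, i] = 100.0
        for j in range(i + 1, n):
            cov_i = [[] for _ in sets[names[i]]]
            cov_j = [[] for _ in sets[names[j]]]
            for a, sa in enumerate(sets[names[i]]):
                for b, sb in enumerate(sets[names[j]]):
                    segs = trim_segments(
                        chain_anchors(
                            find_anchors(sa, sb, w=w, **kwargs),
                            len_b=len(sb),
                        )
                    )
                    cov_i[a].extend((s.a_start, s.a_end) for s in segs)
                    cov_j[b].extend((s.b_start, s.b_end) for s in segs)
            tot_i = sum(_merged_total(c) for c in cov_i)
            tot_j = sum(_merged_total(c) for c in cov_j)
            O = (tot_i + tot_j) / 2.0
            O_kb[i, j] = O_kb[j, i] = O / 1000.0
            recovery[i, j] = recovery_percent(min(tot_i, sum(lens[names[i]])), sum(lens[names[i]]))
            recovery[j, i] = recovery_percent(min(tot_j, sum(lens[names[j]])), sum(lens[names[j]]))
    return OverlapMatrix(
        names=names,
        n_sequences=[len(sets[k]) for k in names],
        total_kb=[sum(lens[k]) / 1000.0 for k in names],
        O_kb=O_kb,
        recovery=recovery,
    )
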