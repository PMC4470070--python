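"""Phase-aware minimal tiling path construction from BAC evidence.

Sequencing of a heterozygous genome clone-by-clone only stays on one
homologue if every extension clone is verified against the growing
consensus: an end sequence (BES) of a candidate clone must match the
tiling-path consensus perfectly to be accepted as the same haplotype.
In collinear euchromatin the alternative haplotype typically aligns at
97-98% identity (an *allelic* match, useful for finding the opposite
homologue's contigs) while unrelated clones stay at or below 96%
(*non-specific*).  Paths are seeded in clones anchored by
haplotype-specific markers and extended greedily in both directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

from .bac_resources import AFLPMarker, BACClone, Fingerprint, FingerprintContig, band_overlap
from .errors import InputError
from .sequtil import decode

__all__ = [
    "BESMatch",
    "TilingPath",
    "select_seeds",
    "classify_bes",
    "extend_path",
    "build_tiling_paths",
    "assembly_stats",
    "marker_stats",
]


@dataclass
class BESMatch:
    """Verdict of aligning one BAC end sequence against a path consensus."""

    bes_id: str
    target_path_id: str
    identity: float  # percent over the aligned span
    span: int
    verdict: str  # same_haplotype | allelic | non_specific
    location: tuple[int, int] | None = None  # on the consensus


@dataclass
class TilingPath:
    """An ordered, phase-labelled clone chain with a non-redundant consensus."""

    id: str
    phase: object  # 0 | 1 | "unphased" | "monomorphic"
    clone_ids: list[str]
    offsets: dict[str, int]  # clone id -> start offset in the consensus
    consensus: np.ndarray
    marker_ids: list[str] = field(default_factory=list)

    @property
    def consensus_length(self) -> int:
        return len(self.consensus)

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)


def select_seeds(markers: list[AFLPMarker], clones: list[BACClone]):
    """Seed clones: every marker-carrying clone, labelled with the marker phase.

    Clones carrying markers of both phases are contradictory and are
    excluded with a warning.
    """
    phases: dict[str, set[int]] = {}
    for m in markers:
        for cid in m.carrier_clone_ids:
            phases.setdefault(cid, set()).add(m.phase)
    by_id = {c.id: c for c in clones}
    seeds = []
    for cid, ph in sorted(phases.items()):
        if cid not in by_id:
            continue
        if len(ph) > 1:
            warnings.warn(f"clone {cid} carries markers of both phases; excluded", stacklevel=2)
            continue
        seeds.append((by_id[cid], ph.pop()))
    return seeds


def classify_bes(
    bes: np.ndarray,
    path_consensus: np.ndarray,
    path_id: str = "",
    bes_id: str = "",
    min_span: int = 300,
    same_hap_min_identity: float = 100.0,
    non_specific_max_identity: float = 96.0,
) -> BESMatch:
    """Classify a BES against a consensus by best infix alignment identity.

    The same-haplotype rule is strict 100% identity by default (a knob
    allows e.g. 99.9% for error-containing reads); identities in
    (96, 100) indicate the allelic (opposite) haplotype, and <= 96% is
    non-specific.
    """
    if len(path_consensus) == 0:
        raise InputError("empty path consensus")
    if len(bes) < min_span:
        raise InputError(f"BES shorter than min_span={min_span}")
    res = edlib.align(decode(bes), decode(path_consensus), mode="HW", task="locations")
    dist = res["editDistance"]
    identity = 100.0 * (1.0 - dist / len(bes))
    loc = tuple(res["locations"][0]) if res["locations"] else None
    if identity >= same_hap_min_identity:
        verdict = "same_haplotype"
    elif identity > non_specific_max_identity:
        verdict = "allelic"
    else:
        verdict = "non_specific"
        if identity < 50.0:
            identity = 0.0
            loc = None
    return BESMatch(bes_id, path_id, identity, len(bes), verdict, loc)


def _contig_neighbours(contigs: list[FingerprintContig], tolerance: int = 3,
                       adjacency_frac: float = 0.25) -> dict[str, set[str]]:
    """Contigs whose consensus band profiles overlap (extension reservoir)."""
    adj: dict[str, set[str]] = {c.id: {c.id} for c in contigs}
    for i in range(len(contigs)):
        for j in range(i + 1, len(contigs)):
            a, b = contigs[i], contigs[j]
            smaller = min(len(a.consensus_bands), len(b.consensus_bands))
            if smaller == 0:
                continue
            if band_overlap(a.consensus_bands, b.consensus_bands, tolerance) >= adjacency_frac * smaller:
                adj[a.id].add(b.id)
                adj[b.id].add(a.id)
    return adj


@dataclass
class _Extension:
    clone: BACClone
    place_start: int  # clone start in current consensus coordinates
    gain: int
    identity: float


def _locate_bes(bes: np.ndarray, consensus: np.ndarray, cons_bytes: bytes,
                same_hap_min_identity: float):
    """Same-haplotype location of a BES on the consensus, or None.

    With the default exact-match rule this is a raw substring search;
    when a lower identity threshold is configured (noisy-read mode) it
    falls back to an infix edit-distance alignment.
    """
    if same_hap_min_identity >= 100.0:
        pos = cons_bytes.find(bes.tobytes())
        if pos < 0:
            return None
        return (pos, pos + len(bes) - 1), 100.0
    m = classify_bes(bes, consensus, same_hap_min_identity=same_hap_min_identity)
    if m.verdict != "same_haplotype" or m.location is None:
        return None
    return m.location, m.identity


def _bes_consistent(clone: BACClone, start: int, consensus: np.ndarray) -> bool:
    """Check that every BES lying inside the consensus matches it exactly.

    A candidate placed by one end must not contradict the consensus at
    its other end: if that end also falls within the assembled span it
    has to be a perfect match too, otherwise the clone comes from the
    other homologue (typical for clones straddling the boundary of a
    homozygous tract, where a single end cannot tell the phases apart).
    """
    n = len(consensus)
    for bes, off in ((clone.bes_left, 0), (clone.bes_right, clone.length - len(clone.bes_right))):
        lo = start + off
        hi = lo + len(bes)
        if 0 <= lo and hi <= n and not np.array_equal(consensus[lo:hi], bes):
            return False
    return True


def _propose(clone: BACClone, consensus: np.ndarray, cons_bytes: bytes,
             min_overlap: int, same_hap_min_identity: float) -> _Extension | None:
    """Try to place a candidate clone against the consensus by its BES."""
    n = len(consensus)
    best = None
    for which, bes in (("L", clone.bes_left), ("R", clone.bes_right)):
        hit = _locate_bes(bes, consensus, cons_bytes, same_hap_min_identity)
        if hit is None:
            continue
        (loc0, loc1), identity = hit
        start = loc0 if which == "L" else (loc1 + 1) - clone.length
        overlap = min(n, start + clone.length) - max(0, start)
        if overlap < min_overlap:
            continue
        gain = max(0, start + clone.length - n) + max(0, -start)
        if gain <= 0:
            continue
        if same_hap_min_identity >= 100.0 and not _bes_consistent(clone, start, consensus):
            continue
        if best is None or (gain, identity) > (best.gain, best.identity):
            best = _Extension(clone, start, gain, identity)
    return best


def extend_path(
    seed: BACClone,
    phase,
    clones: list[BACClone],
    contigs: list[FingerprintContig],
    neighbours: dict[str, set[str]],
    used: set[str],
    path_id: str,
    fingerprints: dict[str, Fingerprint] | None = None,
    prefilter_frac: float = 0.15,
    min_overlap: int = 2_000,
    max_span: int | None = 300_000,
    same_hap_min_identity: float = 100.0,
    clone_phases: dict[str, set[int]] | None = None,
) -> TilingPath:
    """Greedy bidirectional extension from a seed clone.

    The candidate reservoir is restricted to clones from the seed
    members' fingerprint contigs and their band-overlapping neighbours;
    candidates are accepted only on a perfect-identity BES match to the
    consensus, and among acceptable candidates the one extending the
    path the furthest wins (ties: higher identity, then clone id).
    Marker phases veto candidates: a phased path never recruits a clone
    anchored to the opposite phase, and an unphased path recruits only
    marker-free clones -- this keeps a path from silently switching
    homologue where it crosses a homozygous tract in which the two
    homologues are indistinguishable at the sequence level.  ``max_span``
    bounds the consensus length of a single path, emulating the finite
    reach of a physical-map contig before a gap or an anchoring change
    forces a new tiling path.
    """
    clone_phases = clone_phases or {}
    contig_of = {cid: ctg.id for ctg in contigs for cid in ctg.clone_ids}
    by_contig: dict[str, list[BACClone]] = {}
    for c in clones:
        by_contig.setdefault(contig_of[c.id], []).append(c)

    consensus = seed.sequence.copy()
    cons_bytes = consensus.tobytes()
    offsets = {seed.id: 0}
    order = [seed.id]
    used.add(seed.id)

    while True:
        pool_contigs = set()
        for cid in order:
            pool_contigs |= neighbours.get(contig_of[cid], {contig_of[cid]})
        if phase in (0, 1):
            def admissible(c):
                return clone_phases.get(c.id, {phase}) <= {phase}
        else:
            def admissible(c):
                return not clone_phases.get(c.id)
        candidates = [
            c
            for ctg in sorted(pool_contigs)
            for c in by_contig.get(ctg, [])
            if c.id not in used and admissible(c)
        ]
        if fingerprints is not None:
            # cheap screen: a clone can only overlap the path near one of its
            # ends, so it must share restriction bands with an end clone
            end_fps = [fingerprints[order[0]].bands, fingerprints[order[-1]].bands]
            screened = []
            for c in candidates:
                bands = fingerprints[c.id].bands
                for ref_bands in end_fps:
                    smaller = min(len(bands), len(ref_bands))
                    if smaller and band_overlap(bands, ref_bands) >= prefilter_frac * smaller:
                        screened.append(c)
                        break
            candidates = screened
        best = None
        for cand in sorted(candidates, key=lambda c: c.id):
            prop = _propose(cand, consensus, cons_bytes, min_overlap, same_hap_min_identity)
            if prop is None:
                continue
            if max_span is not None and len(consensus) + prop.gain > max_span:
                continue
            if best is None or (prop.gain, prop.identity) > (best.gain, best.identity):
                best = prop
        if best is None:
            break
        start = best.place_start
        clone = best.clone
        if start < 0:
            consensus = np.concatenate([clone.sequence[: -start], consensus])
            offsets = {k: v - start for k, v in offsets.items()}
            offsets[clone.id] = 0
            order.insert(0, clone.id)
        else:
            tail = start + clone.length - len(consensus)
            if tail > 0:
                consensus = np.concatenate([consensus, clone.sequence[-tail:]])
            offsets[clone.id] = start
            order.append(clone.id)
        used.add(clone.id)
        cons_bytes = consensus.tobytes()

    return TilingPath(path_id, phase, order, offsets, consensus)


def _trim_markerless_ends(path: TilingPath, clone_phases, by_id, used: set[str]) -> None:
    """Shrink a phased path to its marker-anchored territory.

    The phase of a path is vouched for by its anchor markers; a terminal
    clone without any marker may come from either homologue wherever the
    path has run into a homozygous tract, so such clones are released
    back to the pool (they typically re-assemble as unphased or
    monomorphic paths).
    """
    while len(path.clone_ids) > 1:
        first = min(path.clone_ids, key=lambda cid: path.offsets[cid])
        last = max(path.clone_ids, key=lambda cid: path.offsets[cid] + by_id[cid].length)
        drop = [cid for cid in {first, last} if not clone_phases.get(cid)]
        if not drop:
            break
        for cid in drop:
            path.clone_ids.remove(cid)
            del path.offsets[cid]
            used.discard(cid)
    lo = min(path.offsets.values())
    hi = max(path.offsets[cid] + by_id[cid].length for cid in path.clone_ids)
    path.consensus = path.consensus[lo:hi]
    if lo:
        path.offsets = {cid: off - lo for cid, off in path.offsets.items()}


def build_tiling_paths(
    clones: list[BACClone],
    contigs: list[FingerprintContig],
    markers: list[AFLPMarker],
    fingerprints: dict[str, Fingerprint] | None = None,
    min_overlap: int = 2_000,
    max_span: int | None = 300_000,
    same_hap_min_identity: float = 100.0,
    equivalents_per_hap: float = 4.8,
    monomorphic_depth_factor: float = 1.5,
) -> list[TilingPath]:
    """Build the full tiling-path set: marker-seeded first, then the rest.

    Marker-anchored seeds carry their marker phase.  Remaining clones
    seed unphased paths; an unphased path whose observed clone depth
    exceeds ``monomorphic_depth_factor`` times the per-haplotype library
    depth is relabelled *monomorphic* (clones of both homologues
    co-assemble on identical sequence, doubling the apparent depth).
    A prospective seed whose two end sequences both locate perfectly
    inside an already-built consensus is redundant -- its region is
    sequenced -- and is retired instead of starting a duplicate path,
    which keeps the path set a minimal tiling of the haplotypes.
    """
    neighbours = _contig_neighbours(contigs)
    seeds = select_seeds(markers, clones)
    clone_phases: dict[str, set[int]] = {}
    for m in markers:
        for cid in m.carrier_clone_ids:
            clone_phases.setdefault(cid, set()).add(m.phase)
    by_id = {c.id: c for c in clones}
    used: set[str] = set()
    paths: list[TilingPath] = []
    built_bytes: list[bytes] = []

    def covered(clone: BACClone) -> bool:
        # a clone with an end inside an already-built consensus would only
        # duplicate sequenced territory; it is retired, not re-seeded
        lb, rb = clone.bes_left.tobytes(), clone.bes_right.tobytes()
        return any(cb.find(lb) >= 0 or cb.find(rb) >= 0 for cb in built_bytes)

    k = 0
    for seed, phase in seeds:
        if seed.id in used:
            continue
        if covered(seed):
            used.add(seed.id)
            continue
        path = extend_path(
            seed, phase, clones, contigs, neighbours, used, f"MTP{k:03d}",
            fingerprints=fingerprints,
            min_overlap=min_overlap, max_span=max_span,
            same_hap_min_identity=same_hap_min_identity,
            clone_phases=clone_phases,
        )
        _trim_markerless_ends(path, clone_phases, by_id, used)
        paths.append(path)
        built_bytes.append(path.consensus.tobytes())
        k += 1
    # marker back-annotation
    marker_clones = {m.id: set(m.carrier_clone_ids) for m in markers}
    for p in paths:
        members = set(p.clone_ids)
        p.marker_ids = sorted(mid for mid, cc in marker_clones.items() if cc & members)
    # unseeded remainder: longest-first unphased seeds
    rest = sorted((c for c in clones if c.id not in used), key=lambda c: (-c.length, c.id))
    for c in rest:
        if c.id in used:
            continue
        if covered(c):
            used.add(c.id)
            continue
        path = extend_path(
            c, "unphased", clones, contigs, neighbours, used, f"MTP{k:03d}",
            fingerprints=fingerprints,
            min_overlap=min_overlap, max_span=max_span,
            same_hap_min_identity=same_hap_min_identity,
            clone_phases=clone_phases,
        )
        depth = sum(by_id[cid].length for cid in path.clone_ids) / max(1, path.consensus_length)
        if depth >= monomorphic_depth_factor * equivalents_per_hap:
            path.phase = "monomorphic"
        paths.append(path)
        built_bytes.append(path.consensus.tobytes())
        k += 1
    return paths


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def n50(lengths) -> int:
    """Largest L such that pieces of length >= L hold half the total."""
    ls = sorted(lengths, reverse=True)
    half = sum(ls) / 2.0
    acc = 0
    for x in ls:
        acc += x
        if acc >= half:
            return x
    raise InputError("empty length list")


def assembly_stats(lengths) -> dict:
    """Basic length statistics (mean reported to the nearest bp)."""
    lengths = list(lengths)
    if not lengths or any(x <= 0 for x in lengths):
        raise InputError("assembly_stats requires a nonempty list of positive lengths")
    total = sum(lengths)
    return {
        "n": len(lengths),
        "total": total,
        "min": min(lengths),
        "max": max(lengths),
        "mean": int(round(total / len(lengths))),
        "N50": n50(lengths),
    }


def marker_stats(paths: list[TilingPath]) -> dict:
    """Marker statistics over marker-bearing paths (mean to 2 decimals)."""
    counts = [len(p.marker_ids) for p in paths if p.marker_ids]
    if not counts:
        return {
            "paths_with_markers": 0,
            "total_markers": 0,
            "mean_per_path": 0.0,
            "min": 0,
            "max": 0,
            "N50_markers": 0,
            "defined": False,
        }
    return {
        "paths_with_markers": len(counts),
        "total_markers": sum(counts),
        "mean_per_path": round(sum(counts) / len(counts), 2),
        "min": min(counts),
        "max": max(counts),
        "N50_markers": n50(counts),
        "defined": True,
    }
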