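"""End-to-end orchestration: simulate, assemble, compare, map.

Each stage is an importable function so tests and the command line can
run any slice of the pipeline; :func:`run_pipeline` chains them all.
One integer seed governs every stochastic stage (children are fixed
offsets of it), so a run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import collinearity as col
from .bac_resources import (
    BACClone,
    GeneticBinMap,
    contig_build,
    fingerprint_library,
    place_markers,
    sample_bac_library,
)
from .chromosome_map import (
    ChromosomeMap,
    CondensationModel,
    FISHMeasurement,
    RefAlign,
    fraction_length,
    order_paths,
    region_table,
    simulate_fish,
)
from .synthetic_genome import DiploidChromosome, DivergenceModel, default_model
from .tiling import TilingPath, assembly_stats, build_tiling_paths, marker_stats

log = logging.getLogger("haplotile")


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    The defaults describe a desk-scale (2 Mb) analogue of a 52 Mb
    chromosome: region proportions follow the reference chromosome,
    divergence rates reproduce 97.5% / 96.5% collinear-tract identity,
    the clone library matches the observed clone-length distribution at
    4.8 genome equivalents per haplotype, and structural-variant length
    laws are scaled down linearly with chromosome length.
    """

    seed: int = 0
    total_length: int = 2_000_000
    region_fractions: tuple | None = None
    gc: float = 0.5
    # divergence model overrides (None = scaled defaults)
    snp_rate_vs_ref: float = 0.025
    snp_rate_between_haps: float = 0.035
    small_indel_rate: float = 2e-5
    # library
    mean_clone_len: int = 122_651
    clone_len_sd: int = 25_000
    min_clone_len: int = 14_260
    max_clone_len: int = 216_437
    equivalents_per_hap: float = 4.8
    bes_len: int = 500
    # markers / map
    marker_density: float = 1e-3
    binT: int = 78
    het_bin: int = 46
    # alignment
    w: int = 20
    max_gap: int = 10_000
    max_diag_drift: int = 5_000
    max_freq: int = 50
    min_insert: int = 20_000
    min_overlap: int = 2_000
    max_path_span: int = 300_000
    # FISH
    fish_cells: int = 20
    fish_noise_sd: float = 2.0
    het_cyto_fraction: float = 0.40
    central_fish_probes: int = 2

    def model(self) -> DivergenceModel:
        m = default_model(self.total_length)
        return dataclasses.replace(
            m,
            snp_rate_vs_ref=self.snp_rate_vs_ref,
            snp_rate_between_haps=self.snp_rate_between_haps,
            small_indel_rate=self.small_indel_rate,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimBundle:
    """Everything the simulation stage produces."""

    diploid: DiploidChromosome
    clones: list[BACClone]
    fingerprints: dict
    contigs: list
    markers: list
    bin_map: GeneticBinMap
    condensation: CondensationModel


def simulate_resources(cfg: RunConfig) -> SimBundle:
    """Genome, clone library, fingerprints, contigs and markers."""
    diploid = DiploidChromosome.simulate(
        total_length=cfg.total_length,
        seed=cfg.seed,
        model=cfg.model(),
        region_fractions=cfg.region_fractions,
        gc=cfg.gc,
    )
    log.info("simulated chromosome: %d bp, haplotypes %d / %d bp",
             len(diploid.reference), len(diploid.hap0), len(diploid.hap1))
    clones = sample_bac_library(
        diploid,
        mean_len=cfg.mean_clone_len,
        len_sd=cfg.clone_len_sd,
        equivalents_per_hap=cfg.equivalents_per_hap,
        seed=cfg.seed + 1000,
        min_len=cfg.min_clone_len,
        max_len=cfg.max_clone_len,
        bes_len=cfg.bes_len,
    )
    log.info("sampled %d clones", len(clones))
    fingerprints = fingerprint_library(clones)
    contigs = contig_build(clones, fingerprints)
    log.info("built %d fingerprint contigs", len(contigs))
    bin_map = GeneticBinMap.from_regions(diploid.regions, binT=cfg.binT, het_bin=cfg.het_bin)
    markers = place_markers(
        diploid, diploid.truth, cfg.marker_density, bin_map, seed=cfg.seed + 2000, clones=clones
    )
    log.info("placed %d phase-specific markers", len(markers))
    condensation = CondensationModel.from_regions(
        diploid.regions, het_cyto_fraction=cfg.het_cyto_fraction
    )
    return SimBundle(diploid, clones, fingerprints, contigs, markers, bin_map, condensation)


def build_paths(sim: SimBundle, cfg: RunConfig) -> list[TilingPath]:
    paths = build_tiling_paths(
        sim.clones,
        sim.contigs,
        sim.markers,
        fingerprints=sim.fingerprints,
        min_overlap=cfg.min_overlap,
        max_span=cfg.max_path_span,
        equivalents_per_hap=cfg.equivalents_per_hap,
    )
    log.info("assembled %d tiling paths", len(paths))
    return paths


def align_to_reference(paths: list[TilingPath], sim: SimBundle, cfg: RunConfig) -> dict[str, RefAlign]:
    """Summarise each path's placement on the reference pseudomolecule.

    The simulated system has no inversions between the homologues and
    the reference, so only the forward strand is scanned here.
    """
    ref = sim.diploid.reference
    ref_keys = col._kmer_keys(ref, cfg.w)
    out: dict[str, RefAlign] = {}
    for p in paths:
        anchors = col.find_anchors(
            p.consensus, ref, w=cfg.w, max_freq=cfg.max_freq, strands="+", b_keys_fwd=ref_keys
        )
        segs = col.trim_segments(
            col.chain_anchors(anchors, cfg.max_gap, cfg.max_diag_drift, len_b=len(ref))
        )
        if not segs:
            continue
        proj_a = sum(s.len_a for s in segs)
        b_lo = min(s.b_start for s in segs)
        b_hi = max(s.b_end for s in segs)
        res = col.collinearity_C(segs, p.consensus_length, b_hi - b_lo)
        out[p.id] = RefAlign(
            position=(b_lo + b_hi) // 2,
            span=(b_lo, b_hi),
            C=res.C,
            unique=proj_a / p.consensus_length >= 0.5,
        )
    return out


def _ref_frame(pos: int, hap: int, truth) -> int | None:
    """Map a haplotype position to the reference frame, interpolating
    through non-liftable tracts (inserts, clusters, heterochromatin)."""
    ref = truth.hap_to_ref(pos, hap)
    if ref is not None:
        return ref
    tract = truth.hap_tract_of(pos, hap)
    if tract is None:
        return None
    lo, hi = tract.hap0_span if hap == 0 else tract.hap1_span
    frac = (pos - lo) / max(1, hi - lo)
    return int(tract.ref_span[0] + frac * (tract.ref_span[1] - tract.ref_span[0]))


def true_path_span(path: TilingPath, sim: SimBundle, clones_by_id) -> tuple[int, int]:
    """Ground-truth reference-frame span of a path (union of its clones)."""
    truth = sim.diploid.truth
    los, his = [], []
    for cid in path.clone_ids:
        c = clones_by_id[cid]
        lo = _ref_frame(c.start, c.haplotype_of_origin, truth)
        hi = _ref_frame(c.end - 1, c.haplotype_of_origin, truth)
        if lo is not None:
            los.append(lo)
        if hi is not None:
            his.append(hi + 1)
    if not los or not his:
        return (0, 0)
    return (min(los), max(his))


def true_path_position(path: TilingPath, sim: SimBundle, clones_by_id) -> int:
    """Ground-truth reference-frame midpoint of a path (for FISH truth)."""
    lo, hi = true_path_span(path, sim, clones_by_id)
    return (lo + hi) // 2


def make_fish(
    paths: list[TilingPath], sim: SimBundle, cfg: RunConfig
) -> tuple[dict[str, tuple[float, float]], dict[str, FISHMeasurement]]:
    """Simulated FISH fraction lengths for euchromatic/border paths and a
    limited number of central-heterochromatin probes."""
    clones_by_id = {c.id: c for c in sim.clones}
    regions = sim.diploid.regions
    central = next(r for r in regions if r.region_class == "central_het")
    fls: dict[str, tuple[float, float]] = {}
    measurements: dict[str, FISHMeasurement] = {}
    central_used = 0
    for i, p in enumerate(paths):
        pos = true_path_position(p, sim, clones_by_id)
        in_central = central.start <= pos < central.end
        if in_central:
            if central_used >= cfg.central_fish_probes:
                continue
            central_used += 1
        m = simulate_fish(
            pos,
            sim.condensation,
            cfg.total_length,
            n_cells=cfg.fish_cells,
            noise_sd=cfg.fish_noise_sd,
            seed=cfg.seed + 3000 + i,
            binT=cfg.binT,
            clone_id=p.id,
        )
        measurements[p.id] = m
        fls[p.id] = fraction_length(m)
    return fls, measurements


def make_map(paths, sim: SimBundle, cfg: RunConfig, ref_aligns, fish_fls):
    cmap = order_paths(
        paths, sim.markers, fish_fls, ref_aligns, sim.diploid.regions, sim.bin_map,
        condensation=sim.condensation,
    )
    rtable = region_table(cmap, paths, sim.diploid.regions, ref_aligns)
    return cmap, rtable


def pair_collinearity(paths, ref_aligns, cfg: RunConfig, min_span_overlap: int = 20_000) -> pd.DataFrame:
    """Haplotype-0 vs haplotype-1 comparison of co-located path pairs."""
    rows = []
    phased = {0: [], 1: []}
    for p in paths:
        if p.phase in (0, 1) and p.id in ref_aligns:
            phased[p.phase].append(p)
    for a in phased[0]:
        ra = ref_aligns[a.id]
        for b in phased[1]:
            rb = ref_aligns[b.id]
            ov = min(ra.span[1], rb.span[1]) - max(ra.span[0], rb.span[0])
            if ov < min_span_overlap:
                continue
            res = col.compare(
                a.consensus, b.consensus,
                w=cfg.w, max_gap=cfg.max_gap, max_diag_drift=cfg.max_diag_drift,
                max_freq=cfg.max_freq, min_insert=cfg.min_insert,
            )
            rows.append(
                {
                    "path_a": a.id,
                    "path_b": b.id,
                    "C": round(res.C, 4),
                    "band": res.band,
                    "O_bp": int(res.O),
                    "n_inserts": len(res.inserts),
                }
            )
    return pd.DataFrame(rows, columns=["path_a", "path_b", "C", "band", "O_bp", "n_inserts"])


def central_overlap(paths, sim: SimBundle, cfg: RunConfig, cmap: ChromosomeMap):
    """Three-way overlap quantification in the central heterochromatin."""
    central_ids = {
        pl.path_id for pl in cmap.placements if pl.region == "central_heterochromatin"
    }
    sets = {"hap0_paths": [], "hap1_paths": []}
    for p in paths:
        if p.id in central_ids and p.phase in (0, 1):
            sets[f"hap{p.phase}_paths"].append(p.consensus)
    region = next(r for r in sim.diploid.regions if r.region_class == "central_het")
    sets["reference"] = [sim.diploid.reference[region.start:region.end]]
    if not sets["hap0_paths"] or not sets["hap1_paths"]:
        return None
    return col.overlap_matrix(sets, w=cfg.w, max_freq=cfg.max_freq)


@dataclass
class PipelineResult:
    config: RunConfig
    sim: SimBundle
    paths: list[TilingPath]
    ref_aligns: dict[str, RefAlign]
    fish_fls: dict[str, tuple[float, float]]
    fish_measurements: dict[str, FISHMeasurement]
    cmap: ChromosomeMap
    rtable: pd.DataFrame
    clone_stats: dict = field(default_factory=dict)
    path_stats: dict = field(default_factory=dict)
    mstats: dict = field(default_factory=dict)
    pair_table: pd.DataFrame | None = None
    overlap: object = None


def run_pipeline(cfg: RunConfig, with_pairs: bool = True, with_overlap: bool = True) -> PipelineResult:
    sim = simulate_resources(cfg)
    paths = build_paths(sim, cfg)
    ref_aligns = align_to_reference(paths, sim, cfg)
    fish_fls, fish_ms = make_fish(paths, sim, cfg)
    cmap, rtable = make_map(paths, sim, cfg, ref_aligns, fish_fls)
    result = PipelineResult(
        config=cfg,
        sim=sim,
        paths=paths,
        ref_aligns=ref_aligns,
        fish_fls=fish_fls,
        fish_measurements=fish_ms,
        cmap=cmap,
        rtable=rtable,
        clone_stats=assembly_stats([c.length for c in sim.clones]),
        path_stats=assembly_stats([p.consensus_length for p in paths]),
        mstats=marker_stats(paths),
    )
    if with_pairs:
        result.pair_table = pair_collinearity(paths, ref_aligns, cfg)
    if with_overlap:
        result.overlap = central_overlap(paths, sim, cfg, cmap)
    return result


# ---------------------------------------------------------------------------
# truth audits (used by the test-suite and the verification report)
# ---------------------------------------------------------------------------

def phase_purity(paths, clones, truth) -> tuple[int, int]:
    """Clone-level phase accuracy of phased paths in heterozygous tracts.

    Returns (correct, total) over clones whose midpoint lies in a tract
    where the homologues actually differ; clones in homozygous tracts
    carry no phase information and are excluded.
    """
    by_id = {c.id: c for c in clones}
    correct = total = 0
    for p in paths:
        if p.phase not in (0, 1):
            continue
        for cid in p.clone_ids:
            c = by_id[cid]
            mid = (c.start + c.end) // 2
            tract = truth.hap_tract_of(mid, c.haplotype_of_origin)
            if tract is None or tract.label == "homozygous":
                continue
            total += 1
            if c.haplotype_of_origin == p.phase:
                correct += 1
    return correct, total


def euchromatic_order_agreement(result: PipelineResult) -> float:
    """Kendall tau between inferred and true order of ordered euchromatic paths.

    Two paths whose true reference spans overlap reciprocally by at
    least half (allelic partners covering the same territory on the two
    homologues) have no meaningful mutual order and share one true
    rank, which Kendall's tau-b treats as a tie.
    """
    from scipy.stats import kendalltau

    clones_by_id = {c.id: c for c in result.sim.clones}
    by_id = {p.id: p for p in result.paths}
    eu = [
        pl
        for pl in result.cmap.placements
        if pl.status == "ordered" and pl.region in ("north_euchromatin", "south_euchromatin")
    ]
    if len(eu) < 3:
        return float("nan")
    spans = [true_path_span(by_id[pl.path_id], result.sim, clones_by_id) for pl in eu]
    n = len(eu)
    group = list(range(n))

    def find(x):
        while group[x] != x:
            group[x] = group[group[x]]
            x = group[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            (a0, a1), (b0, b1) = spans[i], spans[j]
            ov = min(a1, b1) - max(a0, b0)
            shorter = min(a1 - a0, b1 - b0)
            if shorter > 0 and ov / shorter >= 0.5:
                group[find(i)] = find(j)
    mid = {g: np.mean([(s[0] + s[1]) / 2 for k, s in enumerate(spans) if find(k) == g])
           for g in {find(i) for i in range(n)}}
    inferred = [pl.rank for pl in eu]
    true = [mid[find(i)] for i in range(n)]
    tau, _ = kendalltau(inferred, true)
    return float(tau)
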