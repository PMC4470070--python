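"""Writers for the standard interchange formats the pipeline emits.

FASTA for sequences, BED for truth annotations (0-based half-open),
AGP v2.1 for tiling paths and the chromosome map (1-based inclusive, as
the format requires), TSV for tabular reports and a JSON run manifest
with parameter and checksum provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .sequtil import decode


def write_fasta(records: dict[str, np.ndarray | str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [
        SeqRecord(Seq(decode(s) if isinstance(s, np.ndarray) else s), id=name, description="")
        for name, s in records.items()
    ]
    seqio_write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_truth_bed(truth, path) -> None:
    """Regions, tracts and structural events as one BED file.

    The name field encodes the record type and event kind; SNPs are
    summarised in the companion manifest rather than emitted per site.
    """
    lines = []
    for r in truth.regions:
        lines.append(f"REF\t{r.start}\t{r.end}\tregion:{r.name}:{r.region_class}")
    for t in truth.tracts:
        lines.append(f"REF\t{t.ref_span[0]}\t{t.ref_span[1]}\ttract:{t.label}:{t.region}")
    for e in truth.events:
        if e.kind.startswith("small_"):
            continue
        for hap, span in ((0, e.hap0_span), (1, e.hap1_span)):
            if span is None:
                continue
            flag = "" if e.allelic is None else (":allelic" if e.allelic else ":non_allelic")
            lines.append(f"HAP{hap}\t{span[0]}\t{span[1]}\tevent:{e.kind}{flag}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_liftover_tsv(truth, path) -> None:
    rows = ["hap\tref_start\tref_end\thap_start"]
    for hap in (0, 1):
        for ref_s, ref_e, hap_s in truth.blocks(hap):
            rows.append(f"{hap}\t{ref_s}\t{ref_e}\t{hap_s}")
    Path(path).write_text("\n".join(rows) + "\n")


def write_markers_tsv(markers, path) -> None:
    rows = ["id\tphase\tbin\tposition\tcarriers"]
    for m in markers:
        rows.append(f"{m.id}\t{m.phase}\t{m.bin}\t{m.position}\t{','.join(m.carrier_clone_ids)}")
    Path(path).write_text("\n".join(rows) + "\n")


def write_fingerprints_tsv(fingerprints, path) -> None:
    rows = ["clone_id\tn_bands\tbands"]
    for fp in fingerprints.values():
        rows.append(f"{fp.clone_id}\t{fp.n_bands}\t{','.join(map(str, fp.bands))}")
    Path(path).write_text("\n".join(rows) + "\n")


def write_contigs_tsv(contigs, path) -> None:
    rows = ["contig_id\tn_clones\tclones"]
    for c in contigs:
        rows.append(f"{c.id}\t{len(c.clone_ids)}\t{','.join(c.clone_ids)}")
    Path(path).write_text("\n".join(rows) + "\n")


def write_paths_agp(paths, clone_lengths: dict[str, int], path) -> None:
    """Tiling paths as AGP v2.1 component lines (coordinates 1-based)."""
    lines = ["##agp-version\t2.1"]
    for p in paths:
        part = 1
        for cid in p.clone_ids:
            off = p.offsets[cid]
            ln = clone_lengths[cid]
            end = min(off + ln, p.consensus_length)
            lines.append(
                f"{p.id}\t{off + 1}\t{end}\t{part}\tF\t{cid}\t1\t{end - off}\t+"
            )
            part += 1
    Path(path).write_text("\n".join(lines) + "\n")


def write_map_agp(cmap, paths_by_id, path, gap_size: int = 100) -> None:
    """Ordered chromosome map as AGP v2.1 with U gaps between placements."""
    lines = ["##agp-version\t2.1"]
    part = 1
    pos = 0
    for pl in cmap.placements:
        if pl.status != "ordered":
            continue
        p = paths_by_id[pl.path_id]
        if part > 1:
            lines.append(
                f"chromosome\t{pos + 1}\t{pos + gap_size}\t{part}\tU\t{gap_size}\tcontig\tno\tna"
            )
            pos += gap_size
            part += 1
        lines.append(
            f"chromosome\t{pos + 1}\t{pos + p.consensus_length}\t{part}\tW\t{pl.path_id}\t1\t{p.consensus_length}\t+"
        )
        pos += p.consensus_length
        part += 1
    Path(path).write_text("\n".join(lines) + "\n")


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(config_dict: dict, outputs: list, path) -> None:
    manifest = {
        "tool": "haplotile",
        "config": config_dict,
        "outputs": {str(Path(o).name): sha256_of(o) for o in outputs if Path(o).exists()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
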