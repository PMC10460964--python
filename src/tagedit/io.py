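"""Readers and writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Biopython; tables are pandas TSV; everything else is
JSON.  All TSV schemas are documented in the writer docstrings.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import AlleleCall, PopulationSummary, ReadCall
from .capture import DiscordantCluster, DropoutCall, PairAlignment
from .model import GeneLocus, GuideDesign, Junction, TandemArrayModel
from .pcr import BandingReport, PredictedProduct
from .simulate import LineRecord, ReadPair
from .targets import TargetSet

__all__ = [
    "write_array_model", "read_array_model",
    "write_fastq_pairs", "read_fastq_pairs",
    "write_truth", "write_targets",
    "write_read_calls", "write_allele_matrix", "write_summary",
    "write_products", "write_banding",
    "write_alignments", "write_coverage", "write_clusters",
    "write_junctions", "write_report", "write_manifest",
]


# ---------------------------------------------------------------------------
# Array model: FASTA contigs + JSON sidecar
# ---------------------------------------------------------------------------

def write_array_model(array: TandemArrayModel, fasta_path, sidecar_path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in array.contigs.items()]
    SeqIO.write(records, str(fasta_path), "fasta")
    sidecar = {
        "genes": [{
            "id": g.id, "interval": list(g.interval), "strand": g.strand,
            "cds_blocks": [list(b) for b in g.cds_blocks],
            "cut_point": g.cut_point, "is_pseudogene": g.is_pseudogene,
            "contig": g.contig,
        } for g in array.genes],
        "guide": {"spacer": array.guide.spacer, "pam": array.guide.pam,
                  "cut_offset": array.guide.cut_offset},
        "diagnostic_variants": {
            gid: [[p, b] for p, b in vs]
            for gid, vs in array.diagnostic_variants.items()},
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_array_model(fasta_path, sidecar_path) -> TandemArrayModel:
    contigs = {rec.id: str(rec.seq)
               for rec in SeqIO.parse(str(fasta_path), "fasta")}
    meta = json.loads(Path(sidecar_path).read_text())
    genes = [GeneLocus(
        id=g["id"], interval=tuple(g["interval"]), strand=g["strand"],
        cds_blocks=tuple(tuple(b) for b in g["cds_blocks"]),
        cut_point=g["cut_point"], is_pseudogene=g["is_pseudogene"],
        contig=g["contig"]) for g in meta["genes"]]
    guide = GuideDesign(**meta["guide"])
    diag = {gid: [(int(p), b) for p, b in vs]
            for gid, vs in meta["diagnostic_variants"].items()}
    return TandemArrayModel(contigs, genes, guide, diag)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def _open(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq_pairs(reads: Iterable[ReadPair], r1_path, r2_path) -> int:
    """Write paired reads; constant quality (the simulator models no
    base-quality noise)."""
    n = 0
    with _open(r1_path, "w") as f1, _open(r2_path, "w") as f2:
        for p in reads:
            f1.write(f"@{p.read_id}/1\n{p.r1}\n+\n{'I' * len(p.r1)}\n")
            f2.write(f"@{p.read_id}/2\n{p.r2}\n+\n{'I' * len(p.r2)}\n")
            n += 1
    return n


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    with _open(r1_path, "r") as f1:
        r1s = list(SeqIO.parse(f1, "fastq"))
    with _open(r2_path, "r") as f2:
        r2s = list(SeqIO.parse(f2, "fastq"))
    if len(r1s) != len(r2s):
        raise ValueError("R1/R2 record counts differ")
    out = []
    for a, b in zip(r1s, r2s):
        rid = a.id.rsplit("/", 1)[0]
        if b.id.rsplit("/", 1)[0] != rid:
            raise ValueError(f"unpaired records {a.id} vs {b.id}")
        out.append(ReadPair(rid, str(a.seq), str(b.seq)))
    return out


# ---------------------------------------------------------------------------
# Truth, targets
# ---------------------------------------------------------------------------

def write_truth(lines: list[LineRecord], tsv_path, json_path=None) -> None:
    """Truth table TSV: one row per (line, gene) with the structural state,
    indel, partner, and the amplicon-projected expectation."""
    rows = []
    for ln in lines:
        for gid, call in ln.truth.calls.items():
            exp = ln.truth.expected_amplicon[gid]
            rows.append({
                "line": ln.line_id, "gene": gid, "state": call.state,
                "indel": call.indel, "partner": call.partner or "",
                "junction_t": call.junction_t
                if call.junction_t is not None else "",
                "expected_amplicon": "|".join(str(x) for x in exp),
            })
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = [{
            "line": ln.line_id,
            "events": [{
                "kind": e.kind, "breakpoints": list(e.breakpoints),
                "contig": e.contig, "indel_size": e.indel_size,
                "inserted_seq": e.inserted_seq,
                "insert_source": list(e.insert_source) if e.insert_source else None,
                "partner": list(e.partner) if e.partner else None,
            } for e in ln.truth.events],
            "junctions": [_junction_dict(j) for j in ln.truth.junctions],
        } for ln in lines]
        Path(json_path).write_text(json.dumps(payload, indent=1))


def write_targets(targets: TargetSet, fasta_path, tsv_path=None) -> None:
    records = []
    for t in targets.targets:
        desc = f"class={','.join(t.ids)} cut={t.cut}"
        records.append(SeqRecord(Seq(t.sequence), id=t.id, description=desc))
    SeqIO.write(records, str(fasta_path), "fasta")
    if tsv_path is not None:
        rows = [{"target": t.id, "ids": ",".join(t.ids), "cut": t.cut,
                 "length": len(t.sequence),
                 "distinguishing": ",".join(map(str, t.distinguishing))}
                for t in targets.targets]
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Amplicon outputs
# ---------------------------------------------------------------------------

def write_read_calls(calls: Iterable[ReadCall], path) -> None:
    """Per-read TSV: read id, status, matched target ids, indel descriptor."""
    rows = [{
        "read": c.read_id, "status": c.status,
        "targets": ",".join(c.target_ids),
        "indel_size": c.indel.size if c.indel else 0,
        "indel_offset_from_cut": c.indel.offset_from_cut if c.indel else "",
        "inserted": c.indel.inserted if c.indel else "",
    } for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_allele_matrix(calls: list[AlleleCall], path) -> None:
    """Allele matrix TSV: lines as rows, genes as columns, cells like
    ``native``, ``-1``, ``g7-g2(-2)``, ``NA``."""
    def cell(c: AlleleCall) -> str:
        if c.category == "native":
            return "native"
        if c.category == "indel":
            return f"{c.indel:+d}"
        if c.category == "fusion":
            return f"{c.fusion_id}({c.indel:+d})"
        return "NA" if c.category == "na" else "no_call"

    frame: dict[str, dict[str, str]] = {}
    for c in calls:
        frame.setdefault(c.line_id, {})[c.gene_id] = cell(c)
    df = pd.DataFrame.from_dict(frame, orient="index").sort_index()
    df.index.name = "line"
    df.to_csv(path, sep="\t")


def write_summary(summary: PopulationSummary, path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# PCR outputs
# ---------------------------------------------------------------------------

def write_products(products: Iterable[PredictedProduct], path) -> None:
    """Products TSV: molecule, start, end, length, primers, mismatches,
    specificity."""
    rows = [{
        "molecule": p.molecule, "start": p.start, "end": p.end,
        "length": p.length,
        "left_primer": p.left_site.primer, "right_primer": p.right_site.primer,
        "left_mm": p.left_site.mismatches, "right_mm": p.right_site.mismatches,
        "specificity": p.specificity,
    } for p in products]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_banding(report: BandingReport, path) -> None:
    payload = {
        "line": report.line_id,
        "bands": {pid: [[l, m] for l, m in bands]
                  for pid, bands in report.bands.items()},
        "na_genes": report.na_genes,
        "control_ok": report.control_ok,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Capture outputs
# ---------------------------------------------------------------------------

def write_alignments(alignments: Iterable[PairAlignment], path) -> None:
    """Alignment TSV: pair id, per-end contig/start/end/strand/exact,
    orientation class."""
    rows = []
    for a in alignments:
        row = {"pair": a.pair_id, "orientation": a.orientation}
        for i, e in ((1, a.end1), (2, a.end2)):
            row[f"contig{i}"] = e.contig if e else ""
            row[f"start{i}"] = e.start if e else ""
            row[f"end{i}"] = e.end if e else ""
            row[f"strand{i}"] = e.strand if e else ""
            row[f"exact{i}"] = e.exact if e else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_coverage(profile: dict, window: int, path) -> None:
    rows = []
    for contig, wins in profile.items():
        for i, d in enumerate(wins):
            rows.append({"contig": contig, "start": i * window,
                         "end": (i + 1) * window, "depth": round(float(d), 3)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_clusters(clusters: Iterable[DiscordantCluster], path) -> None:
    rows = [{
        "orientation": c.orientation, "support": c.support,
        "left_contig": c.left_contig, "left_start": c.left_span[0],
        "left_end": c.left_span[1], "right_contig": c.right_contig,
        "right_start": c.right_span[0], "right_end": c.right_span[1],
        "loci": ",".join(c.loci),
    } for c in clusters]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _junction_dict(j: Junction) -> dict:
    return {
        "side5": list(j.side5), "side3": list(j.side3),
        "orientation": j.orientation, "inserted": j.inserted,
        "insert_source": list(j.insert_source) if j.insert_source else None,
        "net_indel": j.net_indel, "provenance": j.provenance,
    }


def write_junctions(junctions: Iterable[Junction], path) -> None:
    """Junction TSV: 5'/3' locus and transcription offset, orientation,
    net indel, inserted bases, provenance."""
    rows = [{
        "locus5": j.side5[0], "t5": j.side5[1],
        "locus3": j.side3[0], "t3": j.side3[1],
        "orientation": j.orientation, "net_indel": j.net_indel,
        "inserted": j.inserted,
        "insert_source": j.insert_source[0] if j.insert_source else "",
        "provenance": j.provenance,
    } for j in junctions]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reports and manifests
# ---------------------------------------------------------------------------

def write_report(line_id: str, result, reports, path) -> None:
    """Per-line reconstruction report JSON: best scenario(s), final calls,
    conflicts."""
    payload = {
        "line": line_id,
        "observed_junctions": sorted(map(list, result.observed)),
        "exhaustive": result.exhaustive,
        "scenarios": [{
            "events": [{
                "kind": e.kind, "breakpoints": list(e.breakpoints),
                "partner": list(e.partner) if e.partner else None,
            } for e in s.events],
            "mismatch": s.mismatch, "score": s.score,
        } for s in result.scenarios[:10]],
        "unexplained": sorted(map(list, result.unexplained)),
        "genes": [{
            "gene": r.gene_id, "state": r.final.state, "indel": r.final.indel,
            "partner": r.final.partner, "amplicon": r.amplicon_category,
            "consistent": r.consistent, "conflicts": list(r.conflicts),
        } for r in reports],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_manifest(params: dict, inputs: Iterable, path) -> None:
    """Record run parameters and sha256 of input files for reproducibility."""
    hashes = {}
    for p in inputs:
        p = Path(p)
        if p.exists():
            hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    Path(path).write_text(json.dumps(
        {"params": params, "input_sha256": hashes}, indent=1))
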