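"""Readers and writers for the plain-text formats the pipeline consumes:
FASTA genomes, BED peak files, bedGraph signal tracks, motif-profile files
(the '>' header + one probability row per position dialect used by common
motif scanners), BED12/GFF3 gene models and TSV screen count tables.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Coverage, GeneModel, GenomicInterval, PeakSet, Transcript
from .motifs import ConsensusMotif, MotifHit, MotifProfile

__all__ = [
    "read_fasta", "write_fasta",
    "read_bed", "write_bed", "write_hits_bed",
    "read_bedgraph", "write_bedgraph",
    "read_motif_file", "write_motif_file",
    "read_bed12_genes", "read_gff3_genes",
    "read_screen_table", "write_tsv",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path, label: str | None = None) -> PeakSet:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            strand = fields[5] if len(fields) > 5 else None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals, label or Path(str(path)).stem)


def write_bed(peaks: PeakSet, path) -> None:
    stem = peaks.label or "peak"
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks):
            name = iv.name or f"{stem}_{i}"
            score = 0 if iv.score is None else iv.score
            fh.write(f"{iv.sequence_id}\t{iv.start}\t{iv.end}\t{name}"
                     f"\t{score:g}\t{iv.strand or '.'}\n")


def write_hits_bed(hits: list[MotifHit], path) -> None:
    """Hits as BED6 with the log-odds score."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.profile_name}"
                     f"\t{h.score:.4f}\t{h.strand}\n")


def read_bedgraph(path) -> Coverage:
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    return Coverage(frame)


def write_bedgraph(frame: pd.DataFrame, path) -> None:
    frame[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%g"
    )


def write_motif_file(profiles: list[MotifProfile], path) -> None:
    """'>consensus name threshold' header then one A C G T row per position."""
    with open(path, "w") as fh:
        for p in profiles:
            fh.write(f">{p.source.iupac}\t{p.name}\t{p.threshold:.6f}\n")
            for row in p.matrix:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def read_motif_file(path) -> list[MotifProfile]:
    profiles = []
    header, rows = None, []

    def _flush():
        if header is None:
            return
        consensus, name, threshold = header
        matrix = np.array(rows, dtype=float)
        log_odds = np.log2(matrix / 0.25)
        profiles.append(MotifProfile(
            name=name, matrix=matrix, log_odds=log_odds,
            threshold=threshold, mismatch_tolerance=0,
            source=ConsensusMotif(name, consensus),
        ))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                parts = line[1:].split()
                if len(parts) < 3:
                    raise ValueError(f"motif header needs consensus, name, threshold: {line!r}")
                header, rows = (parts[0], parts[1], float(parts[2])), []
            else:
                vals = [float(v) for v in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"expected 4 probabilities per row, got {line!r}")
                rows.append(vals)
    _flush()
    return profiles


def read_bed12_genes(path) -> GeneModel:
    transcripts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            transcripts.append(Transcript(name, chrom, start, end, strand, exons))
    return GeneModel(transcripts)


def read_gff3_genes(path) -> GeneModel:
    """Minimal GFF3 subset: transcript/mRNA features with exon children."""
    spans: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype in ("transcript", "mRNA"):
                tid = attr.get("ID", f"{chrom}:{start}-{end}")
                spans[tid] = dict(chrom=chrom, start=int(start) - 1,
                                  end=int(end), strand=strand)
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent:
                    exons.setdefault(parent, []).append((int(start) - 1, int(end)))
    transcripts = [
        Transcript(tid, s["chrom"], s["start"], s["end"], s["strand"],
                   tuple(sorted(exons.get(tid, [(s["start"], s["end"])]))))
        for tid, s in spans.items()
    ]
    return GeneModel(transcripts)


def read_screen_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"guide_id", "gene", "count_low", "count_high"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"screen table missing columns: {sorted(missing)}")
    return frame


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)
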