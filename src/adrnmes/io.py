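"""Plain-text readers and writers for the pipeline's artifacts.

Expression data travels as three companion TSVs (values, detection calls,
sample metadata); coverage as fixed-step bedGraph with the library size in
a header comment; intervals as BED6.  All writers are deterministic: the
same in-memory object always produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import CoverageTrack, ExpressionMatrix
from .errors import InputError

__all__ = [
    "write_expression",
    "read_expression",
    "write_bedgraph",
    "read_bedgraph",
    "write_bed",
    "read_bed",
    "write_fasta",
    "read_fasta",
    "write_signature_tsv",
    "read_signature_tsv",
    "sha256_file",
]

_FLOAT_FMT = "%.10g"


def write_expression(em: ExpressionMatrix, out_dir: str | Path, prefix: str) -> dict[str, Path]:
    """Write values/detection/samples TSVs; returns the paths by role."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": out_dir / f"{prefix}_values.tsv",
        "detection": out_dir / f"{prefix}_detection.tsv",
        "samples": out_dir / f"{prefix}_samples.tsv",
    }
    em.values.to_csv(paths["values"], sep="\t", float_format=_FLOAT_FMT)
    em.detection.to_csv(paths["detection"], sep="\t")
    em.samples.to_csv(paths["samples"], sep="\t", float_format=_FLOAT_FMT)
    return paths


def read_expression(
    values_path: str | Path,
    detection_path: str | Path,
    samples_path: str | Path,
) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    detection = pd.read_csv(detection_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    samples.index = samples.index.astype(str)
    values.columns = values.columns.astype(str)
    detection.columns = detection.columns.astype(str)
    return ExpressionMatrix(values, detection, samples)


def write_bedgraph(track: CoverageTrack, path: str | Path, name: str = "coverage") -> Path:
    """Fixed-step bedGraph; the library size is kept in a header comment."""
    path = Path(path)
    with open(path, "w") as out:
        out.write(f"# total_mapped_reads={track.total_mapped_reads:.10g}\n")
        out.write(f'track type=bedGraph name="{name}"\n')
        w = track.bin_width
        for i, v in enumerate(track.counts):
            s = track.start_offset + i * w
            out.write(f"{track.chrom}\t{s}\t{s + w}\t{v:.10g}\n")
    return path


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a fixed-step bedGraph, validating the bin grid."""
    path = Path(path)
    total = None
    chrom = None
    starts: list[int] = []
    ends: list[int] = []
    vals: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("track"):
                continue
            if line.startswith("#"):
                if "total_mapped_reads=" in line:
                    total = float(line.split("total_mapped_reads=")[1])
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise InputError(f"{path}:{lineno}: expected 4 bedGraph fields")
            c, s, e, v = fields
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise InputError(f"{path}:{lineno}: multiple chromosomes not supported")
            starts.append(int(s))
            ends.append(int(e))
            vals.append(float(v))
    if not vals:
        raise InputError(f"{path}: empty bedGraph")
    widths = {e - s for s, e in zip(starts, ends)}
    if len(widths) != 1:
        raise InputError(f"{path}: bins are not fixed-width")
    bin_width = widths.pop()
    if any(b - a != bin_width for a, b in zip(starts, starts[1:])):
        raise InputError(f"{path}: bins are not contiguous on a fixed grid")
    counts = np.array(vals)
    if total is None:
        total = float(counts.sum())
    return CoverageTrack(chrom, bin_width, starts[0], counts, total)


def write_bed(
    rows: Iterable[tuple],
    path: str | Path,
    chrom: str,
) -> Path:
    """Write BED6 rows given as (start, end, name, score, strand) tuples."""
    path = Path(path)
    with open(path, "w") as out:
        for start, end, name, score, strand in rows:
            out.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:.10g}\t{strand}\n")
    return path


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, float, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            out.append((chrom, start, end, name, score, strand))
    return out


def write_fasta(name: str, sequence: str, path: str | Path) -> Path:
    path = Path(path)
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_signature_tsv(sig, path: str | Path) -> Path:
    """Two-column gene_id / class TSV for a signature gene set."""
    path = Path(path)
    with open(path, "w") as out:
        out.write("gene_id\tclass\n")
        for g in sorted(sig.mes_genes):
            out.write(f"{g}\tMES\n")
        for g in sorted(sig.adrn_genes):
            out.write(f"{g}\tADRN\n")
    return path


def read_signature_tsv(path: str | Path):
    from .signature import SignatureGeneSet

    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "class"} <= set(df.columns):
        raise InputError(f"{path}: expected gene_id and class columns")
    mes = frozenset(df.loc[df["class"] == "MES", "gene_id"])
    adrn = frozenset(df.loc[df["class"] == "ADRN", "gene_id"])
    return SignatureGeneSet(mes, adrn)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
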