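"""Readers and writers for every on-disk format the pipeline touches.

All formats are plain text: Matrix Market triplets (matrix.mtx +
barcodes.tsv + features.tsv) for counts, TSV for tables, BED6+4 for peaks
(columns 7-10: atac_flag, foxp3_flag, H3K27ac, H3K27me3; a 9-column file is
accepted with H3K27me3 defaulting to 0), FASTA for peak sequences, a simple
block format for position weight matrices, and JSON sidecars for ground
truth and manifests.

Readers validate and reject malformed input rather than coercing it; every
writer/reader pair round-trips valid data exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import CountMatrix, FormatError

logger = logging.getLogger(__name__)

PEAK_COLUMNS = [
    "chrom", "start", "end", "peak_id", "score", "strand",
    "atac_flag", "foxp3_flag", "h3k27ac", "h3k27me3",
]


# ---------------------------------------------------------------------------
# count matrices (10x-style MTX triplet, cells x genes)
# ---------------------------------------------------------------------------

def _read_id_file(path) -> List[str]:
    ids = [line.rstrip("\n") for line in Path(path).read_text().splitlines()]
    return [x for x in ids if x != ""]


def read_count_matrix(mtx_path, barcodes_path, features_path) -> CountMatrix:
    """Read a counts matrix stored as MTX plus barcode/feature id files.

    The MTX is stored genes x cells (the convention of 10x triplets) and is
    transposed on load so cells are rows.
    """
    mat = scipy.io.mmread(str(mtx_path))
    barcodes = _read_id_file(barcodes_path)
    features = _read_id_file(features_path)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"MTX header {mat.shape[0]}x{mat.shape[1]} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    return CountMatrix(sp.csr_matrix(mat.T), barcodes, features)


def write_count_matrix(cm: CountMatrix, mtx_path, barcodes_path, features_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(cm.values.T), field="integer")
    Path(barcodes_path).write_text("".join(f"{c}\n" for c in cm.cell_ids))
    Path(features_path).write_text("".join(f"{g}\n" for g in cm.gene_ids))


# ---------------------------------------------------------------------------
# peaks (BED6+4)
# ---------------------------------------------------------------------------

def validate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Validate a peak table and return it sorted by (chrom, start)."""
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise FormatError(f"peak table missing columns: {missing}")
    if (peaks["start"] >= peaks["end"]).any():
        bad = peaks.loc[peaks["start"] >= peaks["end"], "peak_id"].iloc[0]
        raise FormatError(f"peak {bad!r} has end <= start")
    if peaks["peak_id"].duplicated().any():
        bad = peaks.loc[peaks["peak_id"].duplicated(), "peak_id"].iloc[0]
        raise FormatError(f"duplicate peak id {bad!r}")
    if (peaks["foxp3_flag"] & ~peaks["atac_flag"]).any():
        bad = peaks.loc[peaks["foxp3_flag"] & ~peaks["atac_flag"], "peak_id"].iloc[0]
        raise FormatError(f"peak {bad!r} is TF-bound but not an open-chromatin peak")
    if (peaks[["h3k27ac", "h3k27me3"]] < 0).any().any():
        raise FormatError("histone signal values must be non-negative")
    return peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def read_peaks(bed_path) -> pd.DataFrame:
    """Read peaks from BED6+4 (or BED6+3 with a single signal column)."""
    rows = []
    for lineno, line in enumerate(Path(bed_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) not in (9, 10):
            raise FormatError(
                f"{bed_path}:{lineno}: expected 9 or 10 columns, got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
            atac, foxp3 = bool(int(fields[6])), bool(int(fields[7]))
            ac = float(fields[8])
            me3 = float(fields[9]) if len(fields) == 10 else 0.0
        except ValueError as exc:
            raise FormatError(f"{bed_path}:{lineno}: {exc}") from None
        rows.append((fields[0], start, end, fields[3], fields[4], fields[5],
                     atac, foxp3, ac, me3))
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    peaks["start"] = peaks["start"].astype(np.int64)
    peaks["end"] = peaks["end"].astype(np.int64)
    return validate_peaks(peaks)


def write_peaks(peaks: pd.DataFrame, bed_path) -> None:
    peaks = validate_peaks(peaks)
    with open(bed_path, "w") as fh:
        for row in peaks.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.peak_id}\t{row.score}\t"
                f"{row.strand}\t{int(row.atac_flag)}\t{int(row.foxp3_flag)}\t"
                f"{row.h3k27ac:g}\t{row.h3k27me3:g}\n"
            )


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def validate_gene_annotation(genes: pd.DataFrame) -> pd.DataFrame:
    required = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in genes.columns]
    if missing:
        raise FormatError(f"gene annotation missing columns: {missing}")
    if genes["gene_id"].duplicated().any():
        bad = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene id {bad!r}")
    if not genes["strand"].isin(["+", "-"]).all():
        bad = genes.loc[~genes["strand"].isin(["+", "-"]), "strand"].iloc[0]
        raise FormatError(f"unknown strand {bad!r}")
    if (genes["start"] >= genes["end"]).any():
        bad = genes.loc[genes["start"] >= genes["end"], "gene_id"].iloc[0]
        raise FormatError(f"gene {bad!r} has end <= start")
    genes = genes.copy()
    # TSS in 0-based coordinates: first base of the gene on its strand
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    return genes.reset_index(drop=True)


def read_gene_annotation(tsv_path) -> pd.DataFrame:
    genes = pd.read_csv(tsv_path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return validate_gene_annotation(genes)


def write_gene_annotation(genes: pd.DataFrame, tsv_path) -> None:
    cols = ["gene_id", "chrom", "start", "end", "strand"]
    validate_gene_annotation(genes)[cols].to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signatures, DE tables, generic TSV
# ---------------------------------------------------------------------------

def read_signature(txt_path) -> List[str]:
    """One gene id per line; blank lines skipped, order preserved."""
    genes = []
    for line in Path(txt_path).read_text().splitlines():
        g = line.strip()
        if g:
            genes.append(g)
    if len(set(genes)) != len(genes):
        raise FormatError(f"signature file {txt_path} contains duplicate genes")
    return genes


def write_signature(genes: Sequence[str], txt_path) -> None:
    Path(txt_path).write_text("".join(f"{g}\n" for g in genes))


def write_de_table(de: pd.DataFrame, tsv_path) -> None:
    de.to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")


def read_de_table(tsv_path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t", dtype={"gene_id": str})


def read_table(tsv_path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, tsv_path, index: bool = False) -> None:
    df.to_csv(tsv_path, sep="\t", index=index, float_format="%.10g")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(sequences: Dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# position weight matrices
# ---------------------------------------------------------------------------

def read_pwms(path) -> list:
    """Parse PWMs from the block format written by :func:`write_pwms`.

    Each block starts with ``>motif_id`` followed by four lines ``A/C/G/T``
    of per-position probabilities and an optional ``BG`` line of background
    base frequencies. Probability columns must sum to 1 within 1e-6.
    """
    from .motifs import PWM  # local import to avoid a cycle

    blocks: List[List[str]] = []
    current: List[str] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith(">"):
            if current:
                blocks.append(current)
            current = [line]
        else:
            if not current:
                raise FormatError(f"{path}: PWM data before any '>' header")
            current.append(line)
    if current:
        blocks.append(current)

    pwms = []
    for block in blocks:
        motif_id = block[0][1:].strip()
        rows: Dict[str, List[float]] = {}
        background = np.full(4, 0.25)
        for line in block[1:]:
            fields = line.split()
            key = fields[0].rstrip(":").upper()
            vals = [float(x) for x in fields[1:]]
            if key == "BG":
                if len(vals) != 4:
                    raise FormatError(f"{path}: BG line must have 4 frequencies")
                background = np.asarray(vals)
            elif key in "ACGT":
                rows[key] = vals
            else:
                raise FormatError(f"{path}: unexpected PWM row {key!r}")
        if sorted(rows) != ["A", "C", "G", "T"]:
            raise FormatError(f"{path}: motif {motif_id!r} missing base rows")
        matrix = np.asarray([rows[b] for b in "ACGT"])
        pwms.append(PWM(motif_id=motif_id, matrix=matrix, background=background))
    return pwms


def write_pwms(pwms: Sequence, path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for base, row in zip("ACGT", pwm.matrix):
                fh.write(base + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("BG " + "  ".join(f"{x:.6f}" for x in pwm.background) + "\n")


# ---------------------------------------------------------------------------
# JSON sidecars
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
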