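"""Readers and writers for the on-disk formats the annotation pipeline touches.

Accessibility matrices travel as Matrix Market sparse files with BED and
cell-barcode sidecars (the layout most peak-calling pipelines emit); peak
sequences as FASTA; reference labels and predictions as TSV. Coordinates use
BED semantics throughout: 0-based, half-open, forward strand (scATAC peaks
are unstranded).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from pyfaidx import Fasta


class FormatError(ValueError):
    """Raised when an input file violates the documented format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomicPeak:
    """A chromatin-accessible region, optionally carrying its DNA sequence.

    ``start``/``end`` follow BED conventions (0-based half-open), so the
    sequence length equals ``end - start`` before any cleaning.
    """

    chrom: str
    start: int
    end: int
    peak_id: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"peak {self.peak_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.sequence is not None and len(self.sequence) != self.end - self.start:
            raise FormatError(
                f"peak {self.peak_id!r}: sequence length {len(self.sequence)} != "
                f"interval length {self.end - self.start}"
            )


@dataclass
class AccessibilityMatrix:
    """Binary peaks x cells accessibility observations for one domain.

    ``values`` is a CSR matrix with entries in {0, 1}; rows align with
    ``peak_ids`` and columns with ``cell_barcodes``.
    """

    values: sp.csr_matrix
    peak_ids: list[str]
    cell_barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.uint8)
        n_peaks, n_cells = self.values.shape
        if n_peaks != len(self.peak_ids):
            raise FormatError(
                f"matrix has {n_peaks} rows but {len(self.peak_ids)} peak ids"
            )
        if n_cells != len(self.cell_barcodes):
            raise FormatError(
                f"matrix has {n_cells} columns but {len(self.cell_barcodes)} barcodes"
            )
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise FormatError("duplicate cell barcodes")
        if len(set(self.peak_ids)) != len(self.peak_ids):
            raise FormatError("duplicate peak ids")
        if self.values.nnz and not np.all(np.isin(self.values.data, (0, 1))):
            raise FormatError("accessibility entries must be binary")

    @property
    def n_peaks(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=np.float64)


@dataclass
class LabelTable:
    """Cell-type assignments for one domain plus the class-name <-> index map.

    ``class_index`` is a bijection covering exactly the classes present in the
    source domain; it fixes the column order of every posterior matrix the
    pipeline emits.
    """

    assignments: "pd.Series"  # barcode -> class name
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = sorted(self.assignments.unique())
        if len(self.classes) < 2:
            raise FormatError("a label table needs at least 2 classes")
        unknown = set(self.assignments.unique()) - set(self.classes)
        if unknown:
            raise FormatError(f"labels outside the class set: {sorted(unknown)}")
        if self.assignments.index.duplicated().any():
            raise FormatError("a barcode appears in more than one label row")

    @property
    def class_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.classes)}

    def encoded(self, barcodes: list[str]) -> np.ndarray:
        """Integer class indices aligned to ``barcodes``."""
        idx = self.class_index
        try:
            return np.array([idx[self.assignments[b]] for b in barcodes], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise FormatError(f"barcode without a label: {exc}") from exc


# ---------------------------------------------------------------------------
# Accessibility matrix I/O
# ---------------------------------------------------------------------------


def read_peaks_bed(peaks_path: str | os.PathLike) -> list[GenomicPeak]:
    """Read a BED file (>= 3 columns) into peaks; column 4, when present, is the peak id."""
    df = pd.read_csv(peaks_path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{peaks_path}: BED needs at least 3 columns")
    peaks = []
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        peak_id = str(row[3]) if df.shape[1] >= 4 else f"{chrom}:{start}-{end}"
        peaks.append(GenomicPeak(chrom, start, end, peak_id))
    return peaks


def write_peaks_bed(peaks: list[GenomicPeak], peaks_path: str | os.PathLike) -> None:
    with open(peaks_path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")


def read_barcodes(barcodes_path: str | os.PathLike) -> list[str]:
    with open(barcodes_path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_barcodes(barcodes: list[str], barcodes_path: str | os.PathLike) -> None:
    with open(barcodes_path, "w") as fh:
        for b in barcodes:
            fh.write(b + "\n")


def read_accessibility(
    matrix_path: str | os.PathLike,
    peaks_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
) -> AccessibilityMatrix:
    """Read a Matrix Market count matrix with BED/barcode sidecars, binarized.

    Any nonzero count becomes 1: downstream reconstruction treats
    accessibility as a Bernoulli observation, so raw fragment counts are
    thresholded at presence.
    """
    mat = scipy.io.mmread(os.fspath(matrix_path)).tocsr()
    peaks = read_peaks_bed(peaks_path)
    barcodes = read_barcodes(barcodes_path)
    n_peaks, n_cells = mat.shape
    if n_peaks != len(peaks):
        raise FormatError(
            f"matrix has {n_peaks} rows but {peaks_path} lists {len(peaks)} peaks"
        )
    if n_cells != len(barcodes):
        raise FormatError(
            f"matrix has {n_cells} columns but {barcodes_path} lists {len(barcodes)} barcodes"
        )
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("matrix contains non-integer entries")
    mat.data = (mat.data != 0).astype(np.uint8)
    mat.eliminate_zeros()
    return AccessibilityMatrix(mat, [p.peak_id for p in peaks], barcodes)


def write_accessibility(
    matrix: AccessibilityMatrix,
    peaks: list[GenomicPeak],
    matrix_path: str | os.PathLike,
    peaks_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
) -> None:
    if [p.peak_id for p in peaks] != list(matrix.peak_ids):
        raise FormatError("peak list does not align with matrix rows")
    scipy.io.mmwrite(os.fspath(matrix_path), matrix.values.tocoo())
    write_peaks_bed(peaks, peaks_path)
    write_barcodes(matrix.cell_barcodes, barcodes_path)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


def extract_peak_sequences(
    peaks: list[GenomicPeak], genome_fasta_path: str | os.PathLike
) -> list[GenomicPeak]:
    """Attach the forward-strand genome slice ``[start, end)`` to each peak.

    Sequences are uppercased; soft-masked (lowercase) genome input therefore
    yields the same result as an unmasked genome.
    """
    genome = Fasta(os.fspath(genome_fasta_path))
    out = []
    for p in peaks:
        if p.chrom not in genome:
            raise FormatError(f"peak {p.peak_id!r}: contig {p.chrom!r} not in genome FASTA")
        contig = genome[p.chrom]
        if p.start < 0 or p.end > len(contig):
            raise FormatError(
                f"peak {p.peak_id!r}: interval [{p.start},{p.end}) outside contig "
                f"{p.chrom!r} of length {len(contig)}"
            )
        seq = contig[p.start : p.end].seq.upper()
        out.append(GenomicPeak(p.chrom, p.start, p.end, p.peak_id, seq))
    return out


def read_peak_fasta(fasta_path: str | os.PathLike, peaks: list[GenomicPeak]) -> list[GenomicPeak]:
    """Attach sequences from a per-peak FASTA keyed by peak id."""
    seqs = _parse_fasta(fasta_path)
    out = []
    for p in peaks:
        if p.peak_id not in seqs:
            raise FormatError(f"peak {p.peak_id!r} missing from {fasta_path}")
        out.append(GenomicPeak(p.chrom, p.start, p.end, p.peak_id, seqs[p.peak_id].upper()))
    return out


def _parse_fasta(path: str | os.PathLike) -> dict[str, str]:
    records: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                records[name] = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence data before any header")
                records[name].append(line)
    return {k: "".join(v) for k, v in records.items()}


def write_peak_fasta(peaks: list[GenomicPeak], fasta_path: str | os.PathLike, width: int = 80) -> None:
    with open(fasta_path, "w") as fh:
        for p in peaks:
            if p.sequence is None:
                raise FormatError(f"peak {p.peak_id!r} has no sequence to write")
            fh.write(f">{p.peak_id} {p.chrom}:{p.start}-{p.end}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Labels and predictions
# ---------------------------------------------------------------------------


def read_labels(labels_path: str | os.PathLike, classes: list[str] | None = None) -> LabelTable:
    """Read a two-column (barcode, class) TSV without header."""
    df = pd.read_csv(labels_path, sep="\t", header=None, names=["barcode", "label"], dtype=str)
    series = pd.Series(df["label"].values, index=df["barcode"].values)
    return LabelTable(series, classes=list(classes) if classes else [])


def write_labels(labels: "pd.Series", labels_path: str | os.PathLike) -> None:
    labels.to_csv(labels_path, sep="\t", header=False)


def write_predictions(
    barcodes: list[str],
    predicted_classes: list[str],
    posterior_rows: np.ndarray,
    classes: list[str],
    out_path: str | os.PathLike,
) -> None:
    """Write target-cell predictions as TSV with per-class posterior columns.

    Column order follows the source-domain class index; ties in the posterior
    are broken toward the lowest class index before this function is called.
    """
    posterior_rows = np.atleast_2d(np.asarray(posterior_rows, dtype=float))
    if len(barcodes) != len(predicted_classes):
        raise FormatError("barcodes and predictions differ in length")
    if len(barcodes) and posterior_rows.shape != (len(barcodes), len(classes)):
        raise FormatError("posterior matrix shape does not match barcodes x classes")
    if len(barcodes) and np.any(np.abs(posterior_rows.sum(axis=1) - 1.0) > 1e-6):
        raise FormatError("posterior rows must sum to 1 within 1e-6")
    with open(out_path, "w") as fh:
        fh.write("barcode\tpredicted_label\t" + "\t".join(f"p_{c}" for c in classes) + "\n")
        for i, (bc, cls) in enumerate(zip(barcodes, predicted_classes)):
            probs = "\t".join(f"{v:.6g}" for v in posterior_rows[i])
            fh.write(f"{bc}\t{cls}\t{probs}\n")
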