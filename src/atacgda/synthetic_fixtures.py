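"""Paired source/target scATAC-like fixtures with planted ground truth.

The generator emulates the study setting end to end: each cell type owns a
disjoint block of marker peaks whose DNA sequences carry a class-specific
motif on an i.i.d. background, accessibility is Bernoulli (``p_on`` at a
cell's own markers, ``p_off`` elsewhere), and the target domain receives a
platform-style batch effect that mixes a fraction ``batch_effect`` of the
per-peak rates toward a peak-specific random perturbation. Both domains share
the peak set (and therefore the feature space); target labels exist only as a
held-out truth table that the annotation pipeline never reads.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import (
    AccessibilityMatrix,
    GenomicPeak,
    write_accessibility,
    write_labels,
    write_peak_fasta,
)

# Canonical TF-like motifs handed to classes in order (AP-1, E-box, SP1,
# E2F, POU/Oct, NF-Y); configs with more classes draw extra motifs at random.
_DEFAULT_MOTIFS = ("TGACTCAG", "CACGTGGT", "GGGCGGGG", "TTTCGCGC", "ATGCAAAT", "CCAATCAG")

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one simulated source/target pair.

    Defaults match the synthetic benchmark used throughout the test harness:
    3 balanced cell types, 600 peaks x 300 cells per domain, 5% of peaks as
    markers per class, strong marker contrast (p_on=0.9 vs p_off=0.05) and a
    moderate batch effect (0.5). The sparse marker fraction keeps the
    benchmark in the regime the method targets: within-domain separation is
    near-perfect while the batch effect displaces target clusters enough that
    alignment-free label transfer makes real errors.
    """

    n_peaks: int = 600
    n_cells_source: int = 300
    n_cells_target: int = 300
    n_classes: int = 3
    peak_length: int = 200
    marker_fraction: float = 0.05  # fraction of all peaks owned by EACH class
    motif_copies: int = 3  # homotypic binding-site cluster per marker peak
    p_on: float = 0.9
    p_off: float = 0.05
    batch_effect: float = 0.5
    class_proportions: tuple[float, ...] | None = None
    motifs: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_off < self.p_on <= 1):
            raise ValueError("need 0 <= p_off < p_on <= 1")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not (0 <= self.batch_effect <= 1):
            raise ValueError("batch_effect must lie in [0, 1]")
        if self.class_proportions is None:
            self.class_proportions = tuple([1.0 / self.n_classes] * self.n_classes)
        if len(self.class_proportions) != self.n_classes:
            raise ValueError("class_proportions length must equal n_classes")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.n_classes * self.marker_fraction > 1.0 + 1e-12:
            raise ValueError("marker blocks exceed the peak set")
        if int(self.marker_fraction * self.n_peaks) < 1:
            raise ValueError("infeasible config: zero marker peaks per class")
        if self.motif_copies < 1:
            raise ValueError("need at least one motif copy per marker peak")

    @property
    def class_names(self) -> list[str]:
        return [f"type{chr(ord('A') + c)}" for c in range(self.n_classes)]


@dataclass
class DomainData:
    """One simulated domain: matrix + sequences + labels + generating rates.

    ``rates`` (peaks x classes Bernoulli parameters) and target-domain
    ``labels`` are ground truth for evaluation only; the annotation pipeline
    consumes just the matrix, peaks and (for the source) labels.
    """

    domain: str
    matrix: AccessibilityMatrix
    peaks: list[GenomicPeak]
    labels: "pd.Series"
    rates: np.ndarray
    classes: list[str] = field(default_factory=list)


def _motifs_for(config: SimConfig, rng: np.random.Generator) -> list[str]:
    if config.motifs is not None:
        motifs = list(config.motifs)
        if len(motifs) < config.n_classes:
            raise ValueError("fewer motifs than classes")
    else:
        motifs = list(_DEFAULT_MOTIFS[: config.n_classes])
        while len(motifs) < config.n_classes:
            motifs.append("".join(rng.choice(_BASES, size=8)))
    if max(len(m) for m in motifs) > config.peak_length:
        raise ValueError("peak_length shorter than the longest motif")
    return motifs


def _simulate_peaks(config: SimConfig, marker_class: np.ndarray, rng: np.random.Generator) -> list[GenomicPeak]:
    motifs = _motifs_for(config, rng)
    peaks = []
    gap = 50
    for i in range(config.n_peaks):
        seq = "".join(rng.choice(_BASES, size=config.peak_length))
        c = marker_class[i]
        if c >= 0:
            # homotypic cluster: several copies of the class motif at random
            # non-overlapping offsets, as in real enhancer architecture
            motif = motifs[c]
            slots = config.peak_length // len(motif)
            picks = rng.choice(slots, size=min(config.motif_copies, slots), replace=False)
            for s in picks:
                off = int(s) * len(motif)
                seq = seq[:off] + motif + seq[off + len(motif):]
        start = i * (config.peak_length + gap)
        peaks.append(GenomicPeak("chrS", start, start + config.peak_length, f"peak{i:05d}", seq))
    return peaks


def _sample_domain(
    domain: str,
    n_cells: int,
    rates: np.ndarray,
    config: SimConfig,
    peaks: list[GenomicPeak],
    rng: np.random.Generator,
) -> DomainData:
    classes = config.class_names
    label_idx = rng.choice(config.n_classes, size=n_cells, p=config.class_proportions)
    y = (rng.random((config.n_peaks, n_cells)) < rates[:, label_idx]).astype(np.uint8)
    barcodes = [f"{domain}_cell{j:05d}" for j in range(n_cells)]
    matrix = AccessibilityMatrix(sp.csr_matrix(y), [p.peak_id for p in peaks], barcodes)
    labels = pd.Series([classes[c] for c in label_idx], index=barcodes)
    return DomainData(domain, matrix, peaks, labels, rates.copy(), classes)


def simulate_domain_pair(config: SimConfig) -> tuple[DomainData, DomainData]:
    """Generate a (source, target) pair under one explicit seed.

    Randomness is split into independent substreams (sequences, class/marker
    layout, per-domain accessibility, batch perturbation) so that, e.g.,
    changing the batch-effect strength never reshuffles the peak sequences.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_seq, rng_src, rng_tgt, rng_batch = (np.random.default_rng(s) for s in ss.spawn(4))

    markers_per_class = int(config.marker_fraction * config.n_peaks)
    marker_class = np.full(config.n_peaks, -1, dtype=int)
    for c in range(config.n_classes):  # disjoint leading blocks, one per class
        marker_class[c * markers_per_class : (c + 1) * markers_per_class] = c

    peaks = _simulate_peaks(config, marker_class, rng_seq)

    rates = np.full((config.n_peaks, config.n_classes), config.p_off)
    for c in range(config.n_classes):
        rates[marker_class == c, c] = config.p_on

    source = _sample_domain("source", config.n_cells_source, rates, config, peaks, rng_src)

    beta = config.batch_effect
    rates_t = rates.copy()
    if beta > 0:
        n_pert = int(round(beta * config.n_peaks))
        pert = rng_batch.choice(config.n_peaks, size=n_pert, replace=False)
        u = rng_batch.random(n_pert)
        rates_t[pert, :] = (1 - beta) * rates[pert, :] + beta * u[:, None]
    target = _sample_domain("target", config.n_cells_target, rates_t, config, peaks, rng_tgt)
    return source, target


def write_domain(data: DomainData, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write one domain as MTX/BED/TSV/FASTA; target labels go to a truth file."""
    os.makedirs(out_dir, exist_ok=True)
    d = os.fspath(out_dir)
    tag = data.domain
    paths = {
        "matrix": os.path.join(d, f"{tag}_matrix.mtx"),
        "peaks": os.path.join(d, f"{tag}_peaks.bed"),
        "barcodes": os.path.join(d, f"{tag}_barcodes.tsv"),
        "fasta": os.path.join(d, f"{tag}_peaks.fa"),
        "labels": os.path.join(
            d, f"{tag}_labels.tsv" if tag == "source" else f"{tag}_truth.tsv"
        ),
    }
    write_accessibility(data.matrix, data.peaks, paths["matrix"], paths["peaks"], paths["barcodes"])
    write_peak_fasta(data.peaks, paths["fasta"])
    write_labels(data.labels, paths["labels"])
    return paths


def checksum_fixture(paths: list[str | os.PathLike]) -> str:
    """Stable content digest of a fixture: SHA-256 over (basename, bytes) pairs.

    Files are digested in sorted basename order; an empty path list yields the
    digest of the empty byte string as a defined sentinel.
    """
    h = hashlib.sha256()
    for p in sorted(paths, key=lambda q: os.path.basename(os.fspath(q))):
        p = os.fspath(p)
        if not os.path.exists(p):
            raise FileNotFoundError(p)
        h.update(os.path.basename(p).encode())
        with open(p, "rb") as fh:
            h.update(fh.read())
    return h.hexdigest()
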