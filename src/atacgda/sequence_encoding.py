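"""Peak-sequence cleaning, tokenization and embedding.

Every peak's DNA sequence is mapped to one fixed-width real vector. The
built-in encoder is an L1-normalized k-mer composition profile (default k=4,
256 dimensions): deterministic, CPU-cheap, and sufficient for motif-level
signal. An adapter contract is provided for external pretrained DNA language
models (BPE/SentencePiece tokenization, mean-pooled final hidden states); it
requires the optional ``transformers`` dependency plus local model weights
and never falls back silently.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from itertools import product
from typing import Protocol, Sequence

import numpy as np

from .io_formats import GenomicPeak

logger = logging.getLogger(__name__)

_CANONICAL = "ACGT"
_CODE = {b: i for i, b in enumerate(_CANONICAL)}


class DegenerateSequenceError(ValueError):
    """Raised when a sequence is empty after removing non-canonical symbols."""


class AdapterUnavailableError(RuntimeError):
    """Raised when the external DNA language model adapter cannot be used."""


def clean_sequence(raw: str) -> str:
    """Uppercase and strip non-canonical symbols (N and friends are removed).

    Removal (rather than substitution) keeps the result deterministic; a
    sequence with no canonical bases left is an error, not an empty vector.
    """
    cleaned = "".join(ch for ch in raw.upper() if ch in _CANONICAL)
    if not cleaned:
        raise DegenerateSequenceError(
            f"sequence {raw[:20]!r}... contains no canonical A/C/G/T bases"
        )
    return cleaned


def kmer_vocabulary(k: int) -> list[str]:
    """The 4^k canonical k-mers in lexicographic order (the fixed row/column convention)."""
    return ["".join(t) for t in product(_CANONICAL, repeat=k)]


def kmer_encode(seq: str, k: int) -> np.ndarray:
    """L1-normalized k-mer counts of a clean sequence over the lexicographic vocabulary."""
    if not (1 <= k <= 6):
        raise ValueError("k must lie in 1..6")
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    codes = np.fromiter((_CODE[b] for b in seq), dtype=np.int64, count=len(seq))
    # rolling base-4 index of each window
    idx = np.zeros(len(seq) - k + 1, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + codes[j : j + len(idx)]
    counts = np.bincount(idx, minlength=4**k).astype(np.float64)
    return counts / counts.sum()


@dataclass
class PeakEmbeddingMatrix:
    """One embedding row per peak, row order matching the accessibility matrix."""

    values: np.ndarray  # N_p x d'
    peak_ids: list[str]
    encoder_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.peak_ids):
            raise ValueError("embedding rows must align with peak ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite peak embeddings")

    @property
    def dim(self) -> int:
        return self.values.shape[1]


class SequenceEncoder(Protocol):
    """Contract: a pure, deterministic map from clean sequence to a d'-vector."""

    name: str
    dim: int

    def encode(self, seq: str) -> np.ndarray: ...


class KmerEncoder:
    """The built-in deterministic encoder: L1-normalized k-mer composition."""

    def __init__(self, k: int = 4):
        if not (1 <= k <= 6):
            raise ValueError("k must lie in 1..6")
        self.k = k
        self.dim = 4**k
        self.name = f"kmer{k}"

    def encode(self, seq: str) -> np.ndarray:
        return kmer_encode(seq, self.k)


def encode_peaks(
    peaks: Sequence[GenomicPeak],
    encoder: SequenceEncoder,
    batch_size: int = 512,
) -> PeakEmbeddingMatrix:
    """Clean and encode every peak sequence into one embedding matrix."""
    rows = np.empty((len(peaks), encoder.dim), dtype=np.float64)
    t0 = time.monotonic()
    for i, p in enumerate(peaks):
        if p.sequence is None:
            raise ValueError(f"peak {p.peak_id!r} carries no sequence")
        try:
            rows[i] = encoder.encode(clean_sequence(p.sequence))
        except DegenerateSequenceError as exc:
            raise DegenerateSequenceError(f"peak {p.peak_id!r}: {exc}") from exc
        if (i + 1) % batch_size == 0:
            rate = (i + 1) / max(time.monotonic() - t0, 1e-9)
            logger.info("encoded %d/%d peaks (%.0f peaks/s)", i + 1, len(peaks), rate)
    return PeakEmbeddingMatrix(rows, [p.peak_id for p in peaks], encoder.name)


class DnaLLMEncoder:
    """Adapter around an external pretrained DNA language model.

    Tokenizes with the model's own BPE/SentencePiece vocabulary (~4096
    subwords, special start/separator tokens appended by the tokenizer) and
    mean-pools the final hidden states over tokens into one vector per peak.
    Requires ``transformers`` and a local model directory; absence raises
    :class:`AdapterUnavailableError` rather than degrading silently.
    """

    def __init__(self, model_dir: str, max_length: int | None = None):
        try:
            from transformers import AutoModel, AutoTokenizer  # noqa: PLC0415
        except ImportError as exc:
            raise AdapterUnavailableError(
                "the external DNA language model adapter needs the 'transformers' "
                "package; install it (pip install transformers) and supply a local "
                "model directory, or use the built-in k-mer encoder "
                "(encoder type 'kmer')"
            ) from exc
        self._tokenizer = AutoTokenizer.from_pretrained(model_dir, trust_remote_code=True)
        self._model = AutoModel.from_pretrained(model_dir, trust_remote_code=True)
        self._model.eval()
        self.max_length = max_length
        self.dim = int(self._model.config.hidden_size)
        self.name = f"dnallm:{model_dir}"

    def tokenize(self, seq: str) -> list[int]:
        """Subword token ids with the transformer's special tokens appended."""
        ids = self._tokenizer(
            seq,
            truncation=self.max_length is not None,
            max_length=self.max_length,
            add_special_tokens=True,
        )["input_ids"]
        if len(ids) <= 2:  # nothing but special tokens survived truncation
            raise DegenerateSequenceError("empty token body after truncation")
        return list(ids)

    def encode(self, seq: str) -> np.ndarray:
        import torch  # noqa: PLC0415 - only reachable with the adapter installed

        ids = torch.tensor([self.tokenize(seq)])
        with torch.no_grad():
            hidden = self._model(ids)[0]
        return hidden.mean(dim=1).squeeze(0).numpy().astype(np.float64)


def llm_adapter_tokenize(seq: str, model_dir: str, max_length: int | None = None) -> list[int]:
    """Tokenize one clean sequence with the external model's vocabulary."""
    return DnaLLMEncoder(model_dir, max_length=max_length).tokenize(seq)


def make_encoder(kind: str = "kmer", *, k: int = 4, model_dir: str | None = None) -> SequenceEncoder:
    """Encoder factory behind the ``encoder:`` config key."""
    if kind == "kmer":
        return KmerEncoder(k=k)
    if kind == "external":
        if model_dir is None:
            raise AdapterUnavailableError("encoder type 'external' requires model_dir")
        return DnaLLMEncoder(model_dir)
    raise ValueError(f"unknown encoder type {kind!r}")
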