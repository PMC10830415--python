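"""Sequence containers, random/background sequence generation and genome windowing.

All coordinates in this package are 0-based half-open, both internally and in
BED output.  DNA is restricted to the uppercase alphabet ``ACGT``; the numeric
encoding maps A,C,G,T to 0..3, so the complement of base ``i`` is ``3 - i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "Sequence",
    "PositionFrequencyProfile",
    "GenomicWindow",
    "encode",
    "decode",
    "one_hot",
    "reverse_complement",
    "default_profile",
    "generate_random_sequences",
    "estimate_position_profile",
    "markov_background_sample",
    "make_windows",
    "read_fasta",
    "write_fasta",
    "write_bed",
]

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class Sequence:
    """An identified DNA sequence with optional genomic provenance.

    ``source`` is a ``(chrom, start, end, strand)`` tuple when the sequence was
    cut out of a genome; coordinates are 0-based half-open.
    """

    id: str
    residues: str
    source: tuple[str, int, int, str] | None = None

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise ValidationError(f"sequence {self.id!r} is empty")
        if any(c not in _BASE_INDEX for c in self.residues):
            bad = sorted({c for c in self.residues if c not in _BASE_INDEX})
            raise ValidationError(
                f"sequence {self.id!r} contains non-ACGT symbols {bad}; "
                "normalize or mask before constructing a Sequence"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def header(self) -> str:
        if self.source is None:
            return self.id
        chrom, start, end, strand = self.source
        return f"{self.id} {chrom}:{start}-{end}({strand})"


def encode(residues: str) -> np.ndarray:
    """Encode a DNA string as an int8 vector over 0..3 (A,C,G,T)."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        raise ValidationError("non-ACGT symbol in sequence")
    return out


def decode(indices: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in np.asarray(indices, dtype=int))


def one_hot(batch: np.ndarray) -> np.ndarray:
    """(n, L) int codes -> (n, L, 4) float64 one-hot."""
    batch = np.asarray(batch)
    return np.eye(4, dtype=np.float64)[batch]


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


class PositionFrequencyProfile:
    """Per-position base probabilities for generating fixed-length sequences.

    The matrix has shape (L, 4) with columns ordered A,C,G,T; every row must
    sum to 1.
    """

    def __init__(self, matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[1] != 4 or matrix.shape[0] == 0:
            raise ValidationError("profile must be a non-empty (L, 4) matrix")
        if (matrix < 0).any() or (matrix > 1).any():
            raise ValidationError("profile entries must lie in [0, 1]")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("every profile row must sum to 1")
        self.matrix = matrix

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PositionFrequencyProfile) and np.array_equal(
            self.matrix, other.matrix
        )


def default_profile(
    length: int = 500, gc_edge: float = 0.40, gc_centre: float = 0.55
) -> PositionFrequencyProfile:
    """GC-graded generation profile emulating accessible-region base composition.

    GC fraction rises linearly from ``gc_edge`` at both ends to ``gc_centre``
    at the centre, mirroring the higher central GC content of regulatory
    regions; A/T and C/G split their halves evenly.
    """
    pos = np.arange(length, dtype=np.float64)
    centre = (length - 1) / 2.0
    rel = 1.0 - np.abs(pos - centre) / centre if length > 1 else np.ones(1)
    gc = gc_edge + (gc_centre - gc_edge) * rel
    at = 1.0 - gc
    matrix = np.column_stack([at / 2, gc / 2, gc / 2, at / 2])
    return PositionFrequencyProfile(matrix)


def generate_random_sequences(
    profile: PositionFrequencyProfile, n: int, seed: int
) -> list[Sequence]:
    """Draw ``n`` sequences, each position independently from the profile row."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = profile.length
    # vectorized per-position inverse-CDF draw
    cdf = np.cumsum(profile.matrix, axis=1)
    u = rng.random((n, L))
    codes = (u[:, :, None] > cdf[None, :, :]).sum(axis=2).astype(np.int8)
    return [Sequence(id=f"random_{i}", residues=decode(codes[i])) for i in range(n)]


def estimate_position_profile(
    sequences: TypingSequence[Sequence],
) -> PositionFrequencyProfile:
    """Empirical per-position base frequencies of an equal-length sequence set."""
    if len(sequences) == 0:
        raise ValidationError("need at least one sequence")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValidationError("sequences must all have the same length")
    codes = np.stack([encode(s.residues) for s in sequences])
    counts = np.zeros((L, 4), dtype=np.float64)
    for b in range(4):
        counts[:, b] = (codes == b).sum(axis=0)
    return PositionFrequencyProfile(counts / len(sequences))


def markov_background_sample(
    training: TypingSequence[Sequence],
    order: int,
    n: int,
    length: int,
    seed: int,
    smoothing: bool = True,
) -> list[Sequence]:
    """Sample sequences from a k-th order Markov chain fit to ``training``.

    Transition frequencies use add-one (Laplace) smoothing by default;
    ``smoothing=False`` gives the exact empirical chain (useful for tests,
    errors on unseen contexts).  The initial k-mer is drawn from the training
    start-k-mer frequencies.
    """
    if not training:
        raise ValidationError("empty training set")
    if order < 0:
        raise ValidationError("order must be >= 0")
    if order > length:
        raise ValidationError("order must be <= requested length")
    if any(len(s) <= order for s in training):
        raise ValidationError("training sequences must be longer than the order")

    rng = np.random.default_rng(seed)
    k = order
    # transition counts: context index (base-4) -> next-base counts
    n_contexts = 4**k
    counts = np.zeros((n_contexts, 4), dtype=np.float64)
    start_counts = np.zeros(n_contexts, dtype=np.float64)
    powers = 4 ** np.arange(k - 1, -1, -1) if k else np.array([], dtype=int)
    for s in training:
        codes = encode(s.residues)
        if k:
            start_counts[int(codes[:k] @ powers)] += 1
            ctx = codes[:k] @ powers
            for i in range(k, len(codes)):
                counts[int(ctx), codes[i]] += 1
                ctx = (ctx * 4 + codes[i]) % n_contexts
        else:
            start_counts[0] += 1
            for b in codes:
                counts[0, b] += 1
    if smoothing:
        counts = counts + 1.0
    row_sums = counts.sum(axis=1)
    out: list[Sequence] = []
    start_p = start_counts / start_counts.sum()
    for i in range(n):
        codes = np.empty(length, dtype=np.int8)
        if k:
            ctx = rng.choice(n_contexts, p=start_p)
            kmer = []
            c = int(ctx)
            for p in powers:
                kmer.append(c // int(p))
                c %= int(p)
            codes[:k] = kmer
            ctx = int(ctx)
        else:
            ctx = 0
        for pos in range(k, length):
            if row_sums[ctx] == 0:
                raise ValidationError(
                    "unseen context reached with smoothing disabled"
                )
            p = counts[ctx] / row_sums[ctx]
            b = rng.choice(4, p=p)
            codes[pos] = b
            ctx = (ctx * 4 + b) % n_contexts if k else 0
        out.append(Sequence(id=f"markov{k}_{i}", residues=decode(codes)))
    return out


@dataclass(frozen=True, order=True)
class GenomicWindow:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad window {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start


def make_windows(
    chromsizes: Mapping[str, int], width: int, stride: int
) -> list[GenomicWindow]:
    """Tile each chromosome with [j*stride, j*stride+width) windows.

    Windows extending past the chromosome end (i.e. not exactly ``width`` wide)
    are dropped.  Output is sorted by (chrom, start).
    """
    if width < 1 or stride < 1:
        raise ValidationError("width and stride must be >= 1")
    windows: list[GenomicWindow] = []
    for chrom in sorted(chromsizes):
        size = chromsizes[chrom]
        start = 0
        while start + width <= size:
            windows.append(GenomicWindow(chrom, start, start + width))
            start += stride
    return windows


def read_fasta(path: str | Path, on_invalid: str = "error", seed: int = 0) -> list[Sequence]:
    """Read a FASTA file into Sequence records.

    Lowercase residues are uppercased (logged).  Non-ACGT symbols raise by
    default; ``on_invalid="mask"`` replaces them with uniform random bases
    (seeded) since the scoring oracles are defined over ACGT only.
    """
    if on_invalid not in ("error", "mask"):
        raise ValidationError("on_invalid must be 'error' or 'mask'")
    rng = np.random.default_rng(seed)
    out: list[Sequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq)
        if residues != residues.upper():
            log.info("sequence %s: lowercase residues normalized to uppercase", rec.id)
            residues = residues.upper()
        bad = [i for i, c in enumerate(residues) if c not in _BASE_INDEX]
        if bad:
            if on_invalid == "error":
                raise ValidationError(
                    f"record {rec.id!r}: non-ACGT symbol at position {bad[0]}"
                )
            chars = list(residues)
            for i in bad:
                chars[i] = ALPHABET[rng.integers(4)]
            residues = "".join(chars)
            log.info("sequence %s: masked %d non-ACGT symbols", rec.id, len(bad))
        out.append(Sequence(id=rec.id, residues=residues))
    return out


def write_fasta(sequences: Iterable[Sequence], path: str | Path) -> None:
    records = []
    for s in sequences:
        desc = ""
        if s.source is not None:
            chrom, start, end, strand = s.source
            desc = f"{chrom}:{start}-{end}({strand})"
        records.append(SeqRecord(Seq(s.residues), id=s.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def write_bed(intervals: Iterable, path: str | Path) -> None:
    """Write windows or scored/stranded intervals as BED (0-based half-open).

    Accepts GenomicWindow-like objects; optional ``name``/``score``/``strand``
    attributes populate BED columns 4-6.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [str(iv.chrom), str(iv.start), str(iv.end)]
            name = getattr(iv, "name", None)
            score = getattr(iv, "score", None)
            strand = getattr(iv, "strand", None)
            if name is not None or score is not None or strand is not None:
                cols.append(str(name if name is not None else "."))
                cols.append(f"{score:.6g}" if score is not None else ".")
                if strand is not None:
                    cols.append(str(strand))
            fh.write("\t".join(cols) + "\n")
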