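"""Sliding-window genome scoring and near-enhancer filtering.

A *near-enhancer* is a genomic window that the oracle already scores high
for a class but that shows little measured accessibility in that cell type
— a candidate that few mutations could convert into a functional enhancer.
The scan tiles every contig with fixed-width windows (default 500 bp, 50 bp
stride, partial windows dropped), scores each window's sequence, attaches
the length-weighted mean of a per-base signal track, and filters on both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence as TypingSequence

import numpy as np
from Bio import SeqIO

from .oracle import OracleModel, score_sequences
from .seqcore import GenomicWindow, Sequence, ValidationError, encode, make_windows

__all__ = [
    "ScoredWindow",
    "scan_genome",
    "read_bedgraph",
    "mean_signal_per_window",
    "near_enhancer_filter",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoredWindow:
    chrom: str
    start: int
    end: int
    score: float
    mean_signal: float | None = None

    @property
    def width(self) -> int:
        return self.end - self.start


def _load_contigs(genome: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(genome, (str, Path)):
        return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(genome), "fasta")}
    return {k: v.upper() for k, v in genome.items()}


def scan_genome(
    genome: str | Path | Mapping[str, str],
    oracle: OracleModel,
    class_name: str,
    width: int = 500,
    stride: int = 50,
    chromsizes: Mapping[str, int] | None = None,
    batch: int = 256,
) -> tuple[list[ScoredWindow], int]:
    """Score every full-width window of a genome FASTA (or contig mapping).

    Contig lengths come from the sequences themselves; a provided chromsize
    mapping that disagrees is an error.  Windows containing non-ACGT symbols
    are skipped and counted (second return value).
    """
    if oracle.input_length not in ("any", width):
        raise ValidationError(
            f"window width {width} does not match oracle input length "
            f"{oracle.input_length}"
        )
    contigs = _load_contigs(genome)
    sizes = {name: len(s) for name, s in contigs.items()}
    if chromsizes is not None:
        for name, size in chromsizes.items():
            if name not in sizes or sizes[name] != size:
                raise ValidationError(
                    f"chromsize mismatch for {name!r}: FASTA has "
                    f"{sizes.get(name)}, chromsizes file says {size}"
                )
    for name, size in sizes.items():
        if size < width:
            log.info("contig %s shorter than window width, no windows", name)
    windows = make_windows(sizes, width, stride)

    scored: list[ScoredWindow] = []
    skipped = 0
    pending: list[tuple[GenomicWindow, np.ndarray]] = []

    def flush() -> None:
        nonlocal pending
        if not pending:
            return
        codes = np.stack([c for _, c in pending])
        if hasattr(oracle, "score_encoded"):
            scores = oracle.score_encoded(codes, [class_name])[:, 0]
        else:
            seqs = [
                Sequence(id=f"{w.chrom}:{w.start}-{w.end}", residues=contigs[w.chrom][w.start : w.end])
                for w, _ in pending
            ]
            scores = score_sequences(oracle, seqs, class_name)
        for (w, _), s in zip(pending, scores):
            scored.append(ScoredWindow(w.chrom, w.start, w.end, float(s)))
        pending = []

    for w in windows:
        sub = contigs[w.chrom][w.start : w.end]
        try:
            codes = encode(sub)
        except ValidationError:
            skipped += 1
            continue
        pending.append((w, codes))
        if len(pending) >= batch:
            flush()
    flush()
    scored.sort(key=lambda sw: (sw.chrom, sw.start))
    return scored, skipped


def read_bedgraph(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Read a bedGraph into per-chrom (starts, ends, values), validated
    sorted and non-overlapping."""
    raw: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            raw.setdefault(chrom, []).append((start, end, value))
    out = {}
    for chrom, rows in raw.items():
        rows.sort()
        starts = np.array([r[0] for r in rows])
        ends = np.array([r[1] for r in rows])
        values = np.array([r[2] for r in rows])
        overlap = np.where(starts[1:] < ends[:-1])[0]
        if len(overlap):
            i = int(overlap[0])
            raise ValidationError(
                f"overlapping bedGraph intervals on {chrom}: "
                f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
            )
        out[chrom] = (starts, ends, values)
    return out


def mean_signal_per_window(
    windows: TypingSequence[GenomicWindow | ScoredWindow],
    signal: str | Path | dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Length-weighted mean of a bedGraph signal over each window.

    Bases not covered by any interval contribute 0 to the mean.
    """
    if not isinstance(signal, dict):
        signal = read_bedgraph(signal)
    # F(x) = integral of the signal from the contig origin to x
    integrals = {}
    for chrom, (starts, ends, values) in signal.items():
        cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
        integrals[chrom] = (starts, ends, values, cum)

    def F(chrom: str, x: int) -> float:
        if chrom not in integrals:
            return 0.0
        starts, ends, values, cum = integrals[chrom]
        j = int(np.searchsorted(starts, x, side="right")) - 1
        if j < 0:
            return 0.0
        return float(cum[j] + values[j] * min(max(x - starts[j], 0), ends[j] - starts[j]))

    return np.array(
        [(F(w.chrom, w.end) - F(w.chrom, w.start)) / w.width for w in windows]
    )


def near_enhancer_filter(
    scored: TypingSequence[ScoredWindow],
    means: np.ndarray | TypingSequence[float],
    score_min: float = 0.3,
    access_max: float | None = None,
    collapse: bool = False,
) -> list[ScoredWindow]:
    """High-score, low-accessibility candidates, sorted by descending score.

    ``access_max`` defaults to the 25th percentile of the window means.
    With ``collapse``, overlapping survivors are reduced greedily to the
    best-scoring window (ties: leftmost).
    """
    means = np.asarray(means, dtype=np.float64)
    if len(means) != len(scored):
        raise ValidationError("one mean per window required")
    if len(scored) == 0:
        return []
    if access_max is None:
        access_max = float(np.percentile(means, 25))
    survivors = [
        replace(w, mean_signal=float(m))
        for w, m in zip(scored, means)
        if w.score > score_min and m <= access_max
    ]
    survivors.sort(key=lambda w: (-w.score, w.chrom, w.start))
    if not collapse:
        return survivors
    kept: list[ScoredWindow] = []
    for w in survivors:
        if all(
            w.chrom != k.chrom or w.start >= k.end or w.end <= k.start for k in kept
        ):
            kept.append(w)
    return kept
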