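"""PWM hit scanning, hit merging, empirical null thresholds and trace censuses.

Significance of motif hits follows an empirical-null convention: for each
motif, the best-hit log-odds score is collected over a set of random
sequences and the per-motif threshold set to mean + 1 sample standard
deviation of those best scores.  A hit is *significant* when its log-odds
meets both the scan floor (default 3.0) and the motif's null threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .motifs import MotifModel
from .oracle import SurrogateOracle
from .seqcore import (
    PositionFrequencyProfile,
    Sequence,
    ValidationError,
    encode,
    generate_random_sequences,
)

__all__ = [
    "MotifHit",
    "NullThreshold",
    "pwm_scan",
    "merge_hits",
    "null_thresholds",
    "threshold_from_scores",
    "annotate_trace",
    "write_hits_bed",
    "background_frequencies",
]

DEFAULT_MIN_LLR = 3.0  # scan floor on the log-odds of a reported hit


@dataclass(frozen=True)
class MotifHit:
    """A scored, stranded motif occurrence (0-based half-open interval)."""

    motif: str
    start: int
    end: int
    strand: str
    score: float
    seq_id: str = "."


@dataclass(frozen=True)
class NullThreshold:
    """Per-motif significance threshold from a random-sequence null."""

    motif: str
    threshold: float
    null_mean: float
    null_sd: float
    n_null: int
    seed: int | None = None


def background_frequencies(
    sequences: TypingSequence[Sequence], pseudocount: float = 0.01
) -> np.ndarray:
    """0-order base frequencies of a sequence set, with pseudocount."""
    counts = np.full(4, pseudocount)
    for s in sequences:
        counts += np.bincount(encode(s.residues), minlength=4)
    return counts / counts.sum()


def _strand_llr(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    w = lo.shape[0]
    O = len(codes) - w + 1
    if O <= 0:
        return np.zeros(0)
    llr = np.zeros(O)
    for i in range(w):
        llr += lo[i][codes[i : i + O]]
    return llr


def pwm_scan(
    sequence: Sequence,
    motif: MotifModel,
    background: np.ndarray | None = None,
    min_llr: float = DEFAULT_MIN_LLR,
    pseudocount: float = 0.01,
) -> list[MotifHit]:
    """Scan both strands; return hits with log-odds >= ``min_llr`` by start.

    ``background`` is a 0-order base-frequency vector; by default it is
    estimated from the scanned sequence itself.
    """
    codes = encode(sequence.residues)
    if background is None:
        background = background_frequencies([sequence])
    lo = motif.log_odds(background=background, pseudocount=pseudocount)
    hits: list[MotifHit] = []
    for strand, mat in (("+", lo), ("-", lo[::-1, ::-1])):
        llr = _strand_llr(codes, mat)
        for o in np.where(llr >= min_llr)[0]:
            hits.append(
                MotifHit(
                    motif=motif.name,
                    start=int(o),
                    end=int(o) + motif.width,
                    strand=strand,
                    score=float(llr[o]),
                    seq_id=sequence.id,
                )
            )
    return sorted(hits, key=lambda h: (h.start, h.strand))


def merge_hits(hits: Iterable[MotifHit], per_motif: bool = True) -> list[MotifHit]:
    """Union strictly overlapping hits; a merged hit carries the max score.

    Merging pools strands within a motif identity by default; bookended
    (touching, non-overlapping) hits are kept separate.  ``per_motif=False``
    additionally merges across motif identities (the merged hit is named
    after its best-scoring member).
    """
    hits = sorted(hits, key=lambda h: (h.seq_id, h.motif if per_motif else "", h.start, h.end))
    out: list[MotifHit] = []
    for h in hits:
        prev = out[-1] if out else None
        same_group = (
            prev is not None
            and prev.seq_id == h.seq_id
            and (not per_motif or prev.motif == h.motif)
        )
        if same_group and h.start < prev.end:
            best = prev if prev.score >= h.score else h
            out[-1] = MotifHit(
                motif=best.motif,
                start=prev.start,
                end=max(prev.end, h.end),
                strand=best.strand,
                score=best.score,
                seq_id=prev.seq_id,
            )
        else:
            out.append(h)
    return sorted(out, key=lambda h: (h.seq_id, h.start, h.end))


def threshold_from_scores(scores: np.ndarray) -> tuple[float, float, float]:
    """(threshold, mean, sd) with threshold = mean + 1 sample s.d. (ddof=1)."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 2:
        raise ValidationError("need at least two null scores")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    return mean + sd, mean, sd


def null_thresholds(
    motifs: TypingSequence[MotifModel],
    n_null: int,
    length: int,
    profile: PositionFrequencyProfile,
    seed: int,
    background: np.ndarray | None = None,
    pseudocount: float = 0.01,
) -> dict[str, NullThreshold]:
    """Per-motif mean + s.d. thresholds over profile-random null sequences.

    For each null sequence the best-hit log-odds (max over offsets and
    strands, unthresholded) is recorded; degenerate all-equal nulls yield
    sd = 0 and threshold = mean.
    """
    if n_null < 2:
        raise ValidationError("n_null must be >= 2")
    nulls = generate_random_sequences(profile, n_null, seed)
    if background is None:
        background = background_frequencies(nulls)
    out: dict[str, NullThreshold] = {}
    for motif in motifs:
        lo = motif.log_odds(background=background, pseudocount=pseudocount)
        best = np.empty(n_null)
        for i, s in enumerate(nulls):
            codes = encode(s.residues)
            fwd = _strand_llr(codes, lo)
            rev = _strand_llr(codes, lo[::-1, ::-1])
            best[i] = max(fwd.max(initial=-np.inf), rev.max(initial=-np.inf))
        thr, mean, sd = threshold_from_scores(best)
        out[motif.name] = NullThreshold(
            motif=motif.name,
            threshold=thr,
            null_mean=mean,
            null_sd=sd,
            n_null=n_null,
            seed=seed,
        )
    return out


def significant_hits(
    sequence: Sequence,
    motifs: TypingSequence[MotifModel],
    thresholds: dict[str, NullThreshold] | None = None,
    background: np.ndarray | None = None,
    min_llr: float = DEFAULT_MIN_LLR,
    per_motif: bool = True,
) -> list[MotifHit]:
    """Merged hits passing both the scan floor and the per-motif null threshold."""
    hits: list[MotifHit] = []
    for motif in motifs:
        floor = min_llr
        if thresholds and motif.name in thresholds:
            floor = max(floor, thresholds[motif.name].threshold)
        hits.extend(pwm_scan(sequence, motif, background=background, min_llr=floor))
    return merge_hits(hits, per_motif=per_motif)


def annotate_trace(
    trace,
    motifs: TypingSequence[MotifModel],
    thresholds: dict[str, NullThreshold] | None = None,
    background: np.ndarray | None = None,
    min_llr: float = DEFAULT_MIN_LLR,
) -> pd.DataFrame:
    """Per-step motif census along an evolution trace.

    Returns one row per step (step 0 = start sequence) with significant
    merged-hit counts per motif, activator/repressor totals, and per-motif
    gain/loss flags relative to the previous step.
    """
    roles = {m.name: m.role for m in motifs}
    if background is None:
        background = background_frequencies(trace.snapshots())
    rows = []
    for step, snap in enumerate(trace.snapshots()):
        hits = significant_hits(
            snap, motifs, thresholds, background=background, min_llr=min_llr
        )
        counts = {m.name: 0 for m in motifs}
        for h in hits:
            counts[h.motif] += 1
        row = {"step": step, **counts}
        row["activator_hits"] = sum(c for n, c in counts.items() if roles[n] == "activator")
        row["repressor_hits"] = sum(c for n, c in counts.items() if roles[n] == "repressor")
        rows.append(row)
    df = pd.DataFrame(rows).set_index("step")
    for name in roles:
        diff = df[name].diff().fillna(0)
        df[f"{name}_gained"] = (diff > 0).astype(int) * diff.astype(int)
        df[f"{name}_lost"] = (diff < 0).astype(int) * (-diff).astype(int)
    return df


def write_hits_bed(hits: Iterable[MotifHit], path: str | Path) -> None:
    """BED6 output; the score column is the log-odds x 100, rounded."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.motif}\t"
                f"{round(h.score * 100)}\t{h.strand}\n"
            )
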