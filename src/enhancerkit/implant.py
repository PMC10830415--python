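"""Exhaustive-position motif implantation and motif-syntax analytics.

A binding site is *implanted* by overwriting the sequence at a chosen offset
(on the forward strand, or with its reverse complement on the reverse
strand).  The canonical placement policy scores every allowed offset on
every allowed strand with the oracle and keeps the best; iterating this over
an ordered site list yields designed enhancers whose syntax (inter-site
spacing, orientation, flank preference) can then be summarized across a
population of designs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence as TypingSequence

import numpy as np

from .oracle import OracleModel, score_sequences
from .seqcore import (
    PositionFrequencyProfile,
    Sequence,
    ValidationError,
    decode,
    encode,
    reverse_complement,
)

__all__ = [
    "ImplantPlacement",
    "FlankPreference",
    "scan_implant",
    "iterative_implant",
    "spacing_analysis",
    "flank_preference",
    "minimal_enhancer",
    "background_robustness",
    "BackgroundRobustness",
]


@dataclass(frozen=True)
class ImplantPlacement:
    """One implanted site: where it went, which strand, and the score after."""

    motif: str
    start: int
    end: int
    strand: str
    score_after: float


def _score_codes(codes: np.ndarray, oracle: OracleModel, class_name: str) -> np.ndarray:
    if hasattr(oracle, "score_encoded"):
        return oracle.score_encoded(codes, [class_name])[:, 0]
    return score_sequences(oracle, [decode(c) for c in codes], class_name)


def _allowed_offsets(L: int, w: int, mask: Iterable[tuple[int, int]]) -> np.ndarray:
    ok = np.ones(L - w + 1, dtype=bool)
    for a, b in mask:
        lo = max(0, a - w + 1)
        ok[lo : min(b, L - w + 1)] = False
    return ok


def scan_implant(
    sequence: Sequence,
    site: str,
    oracle: OracleModel,
    class_name: str,
    site_name: str = "site",
    strands: TypingSequence[str] = ("+", "-"),
    mask_intervals: TypingSequence[tuple[int, int]] = (),
) -> tuple[dict[str, np.ndarray], ImplantPlacement, Sequence]:
    """Write ``site`` in at every allowed offset, score each, keep the best.

    Returns per-strand score arrays (NaN at masked offsets), the best
    placement (ties: lowest offset, then + before -), and the modified
    sequence.
    """
    L, w = len(sequence), len(site)
    if w > L:
        raise ValidationError("site longer than sequence")
    bad = set(strands) - {"+", "-"}
    if bad or not strands:
        raise ValidationError(f"strands must be a non-empty subset of +/-, got {strands}")
    codes = encode(sequence.residues)
    allowed = _allowed_offsets(L, w, mask_intervals)
    if not allowed.any():
        raise ValidationError("mask excludes every offset")
    offsets = np.where(allowed)[0]

    arrays: dict[str, np.ndarray] = {}
    best: tuple[float, int, int] | None = None  # (-score, offset, strand_rank)
    for strand in ("+", "-"):
        if strand not in strands:
            continue
        written = site if strand == "+" else reverse_complement(site)
        site_codes = encode(written)
        variants = np.tile(codes, (len(offsets), 1))
        for j, o in enumerate(offsets):
            variants[j, o : o + w] = site_codes
        scores = _score_codes(variants, oracle, class_name)
        arr = np.full(L - w + 1, np.nan)
        arr[offsets] = scores
        arrays[strand] = arr
        rank = 0 if strand == "+" else 1
        for j, o in enumerate(offsets):
            cand = (-scores[j], int(o), rank)
            if best is None or cand < best:
                best = cand
    neg_score, o, rank = best
    strand = "+" if rank == 0 else "-"
    written = site if strand == "+" else reverse_complement(site)
    new_codes = codes.copy()
    new_codes[o : o + w] = encode(written)
    placement = ImplantPlacement(
        motif=site_name, start=o, end=o + w, strand=strand, score_after=-neg_score
    )
    return arrays, placement, Sequence(id=sequence.id, residues=decode(new_codes))


def _closest_positive_placement(
    sequence: Sequence,
    site: str,
    site_name: str,
    oracle: OracleModel,
    class_name: str,
    anchor: ImplantPlacement,
    strands: TypingSequence[str],
    mask_intervals: TypingSequence[tuple[int, int]],
) -> tuple[ImplantPlacement, Sequence] | None:
    """Nearest offset to the anchor with a positive score change, or None."""
    arrays, _, _ = scan_implant(
        sequence, site, oracle, class_name, site_name, strands, mask_intervals
    )
    base = float(
        _score_codes(encode(sequence.residues)[None, :], oracle, class_name)[0]
    )
    w = len(site)
    candidates: list[tuple[int, int, int]] = []  # (distance, offset, strand_rank)
    for strand, arr in arrays.items():
        rank = 0 if strand == "+" else 1
        for o in np.where(np.nan_to_num(arr - base, nan=-1.0) > 0)[0]:
            o = int(o)
            if o >= anchor.end:
                dist = o - anchor.end
            elif o + w <= anchor.start:
                dist = anchor.start - (o + w)
            else:
                dist = 0
            candidates.append((dist, o, rank))
    if not candidates:
        return None
    dist, o, rank = min(candidates)
    strand = "+" if rank == 0 else "-"
    written = site if strand == "+" else reverse_complement(site)
    codes = encode(sequence.residues)
    codes[o : o + w] = encode(written)
    new_seq = Sequence(id=sequence.id, residues=decode(codes))
    score = float(_score_codes(codes[None, :], oracle, class_name)[0])
    placement = ImplantPlacement(site_name, o, o + w, strand, score)
    return placement, new_seq


def iterative_implant(
    sequence: Sequence,
    sites: TypingSequence[tuple[str, str]],
    oracle: OracleModel,
    class_name: str,
    policy: str | TypingSequence[str] = "best",
    strands: TypingSequence[str] = ("+", "-"),
    allow_overlap: bool = False,
    seed: int | None = None,
    mask_intervals: TypingSequence[tuple[int, int]] = (),
) -> tuple[Sequence, list[ImplantPlacement], list[float]]:
    """Implant an ordered list of (name, site) pairs one by one.

    Placement policies (one for all sites, or one per site):

    - ``best``: exhaustive scan, highest score wins;
    - ``random``: a uniformly random allowed offset and strand (seeded);
    - ``closest_positive``: the allowed offset nearest to the first placed
      site (the anchor) whose implantation raises the score.

    Unless ``allow_overlap``, each placement is added to a mask so later
    sites cannot overwrite earlier ones; ``mask_intervals`` seeds that mask
    with regions that must stay untouched.  Returns the final sequence, the
    placements in implantation order, and the score trajectory (score before
    any implantation, then after each).
    """
    if not sites:
        raise ValidationError("need at least one site")
    policies = [policy] * len(sites) if isinstance(policy, str) else list(policy)
    if len(policies) != len(sites):
        raise ValidationError("one policy required per site")
    rng = np.random.default_rng(seed)
    current = sequence
    placements: list[ImplantPlacement] = []
    mask: list[tuple[int, int]] = [(int(a), int(b)) for a, b in mask_intervals]
    trajectory = [
        float(_score_codes(encode(sequence.residues)[None, :], oracle, class_name)[0])
    ]
    for (name, site), pol in zip(sites, policies):
        if pol == "best":
            _, placement, current = scan_implant(
                current, site, oracle, class_name, name, strands, mask
            )
        elif pol == "random":
            allowed = np.where(_allowed_offsets(len(current), len(site), mask))[0]
            if len(allowed) == 0:
                raise ValidationError("mask excludes every offset")
            o = int(rng.choice(allowed))
            strand = str(rng.choice(list(strands)))
            written = site if strand == "+" else reverse_complement(site)
            codes = encode(current.residues)
            codes[o : o + len(site)] = encode(written)
            current = Sequence(id=current.id, residues=decode(codes))
            score = float(_score_codes(codes[None, :], oracle, class_name)[0])
            placement = ImplantPlacement(name, o, o + len(site), strand, score)
        elif pol == "closest_positive":
            if not placements:
                raise ValidationError("closest_positive requires an anchor placement")
            result = _closest_positive_placement(
                current, site, name, oracle, class_name, placements[0], strands, mask
            )
            if result is None:
                raise ValidationError(
                    f"no positive-delta offset for site {name!r} near the anchor"
                )
            placement, current = result
        else:
            raise ValidationError(f"unknown placement policy {pol!r}")
        placements.append(placement)
        trajectory.append(placement.score_after)
        if not allow_overlap:
            mask.append((placement.start, placement.end))
    return current, placements, trajectory


def spacing_analysis(
    placement_sets: TypingSequence[TypingSequence[ImplantPlacement]],
    anchor_motif: str,
    partner_motif: str,
) -> tuple[dict[str, Counter], int]:
    """Signed inter-site gap histograms across a design population.

    The gap is the number of bases strictly between the anchor and partner
    intervals, negative when the partner lies upstream (5') of the anchor.
    Histograms are keyed ``"same_strand"`` / ``"opposite_strand"``.
    Sequences missing either motif are skipped; their count is returned.
    """
    hists = {"same_strand": Counter(), "opposite_strand": Counter()}
    skipped = 0
    for placements in placement_sets:
        anchor = next((p for p in placements if p.motif == anchor_motif), None)
        partner = next((p for p in placements if p.motif == partner_motif), None)
        if anchor is None or partner is None:
            skipped += 1
            continue
        if partner.start >= anchor.end:
            gap = partner.start - anchor.end
        elif anchor.start >= partner.end:
            gap = -(anchor.start - partner.end)
        else:  # overlapping placements have no between-site gap
            skipped += 1
            continue
        key = "same_strand" if anchor.strand == partner.strand else "opposite_strand"
        hists[key][gap] += 1
    return hists, skipped


@dataclass
class FlankPreference:
    """Centred position-probability matrix around implanted sites, with the
    uniform expectation 0.25 subtracted (columns sum to 0)."""

    matrix: np.ndarray  # (site width + 2w, 4), A,C,G,T columns
    window: int
    n_used: int
    n_skipped: int


def flank_preference(
    sequences: TypingSequence[Sequence],
    placements: TypingSequence[ImplantPlacement],
    window: int,
) -> FlankPreference:
    """Aggregate +-``window`` bp around each placement into a PPM - 0.25.

    Reverse-strand placements are reverse-complemented before alignment so
    all sites point the same way.  Placements whose window crosses a
    sequence boundary are skipped (counted).
    """
    if len(sequences) != len(placements):
        raise ValidationError("one placement per sequence required")
    widths = {p.end - p.start for p in placements}
    if len(widths) != 1:
        raise ValidationError("placements must all have the same site width")
    width = widths.pop()
    span = width + 2 * window
    counts = np.zeros((span, 4))
    used = skipped = 0
    for seq, p in zip(sequences, placements):
        a, b = p.start - window, p.end + window
        if a < 0 or b > len(seq):
            skipped += 1
            continue
        chunk = seq.residues[a:b]
        if p.strand == "-":
            chunk = reverse_complement(chunk)
        counts[np.arange(span), encode(chunk)] += 1
        used += 1
    if used == 0:
        raise ValidationError("no usable placements")
    return FlankPreference(
        matrix=counts / used - 0.25, window=window, n_used=used, n_skipped=skipped
    )


def minimal_enhancer(
    sequence: Sequence,
    placements: TypingSequence[ImplantPlacement],
    flank: int = 0,
) -> Sequence:
    """Cut from the most upstream to the most downstream implanted site,
    plus ``flank`` bp on each side (clipped to the sequence bounds)."""
    if not placements:
        raise ValidationError("need at least one placement")
    start = max(0, min(p.start for p in placements) - flank)
    end = min(len(sequence), max(p.end for p in placements) + flank)
    return Sequence(
        id=f"{sequence.id}_minimal",
        residues=sequence.residues[start:end],
        source=(sequence.id, start, end, "+"),
    )


@dataclass
class BackgroundRobustness:
    """Score distribution of a design over random background replacements."""

    baseline: float
    mean: float
    sd: float
    quantiles: dict[int, float]
    scores: np.ndarray | None = None


def background_robustness(
    sequence: Sequence,
    replace_window: tuple[int, int],
    oracle: OracleModel,
    class_name: str,
    n_backgrounds: int,
    seed: int,
    placements: TypingSequence[ImplantPlacement] = (),
    allow_site_overlap: bool = False,
    profile: PositionFrequencyProfile | None = None,
    keep_scores: bool = False,
) -> BackgroundRobustness:
    """Replace ``replace_window`` with random draws and score each variant.

    The window must not intersect any given placement unless
    ``allow_site_overlap``; draws come from ``profile`` rows covering the
    window when given, else uniform.  Returns mean, s.d. and the 5/25/50/75/95
    percentiles of the resulting score distribution.
    """
    a, b = replace_window
    L = len(sequence)
    if not (0 <= a < b <= L):
        raise ValidationError(f"replace window ({a}, {b}) out of bounds for L={L}")
    if not allow_site_overlap:
        for p in placements:
            if max(a, p.start) < min(b, p.end):
                raise ValidationError(
                    f"replace window intersects placement {p.motif} [{p.start},{p.end})"
                )
    rng = np.random.default_rng(seed)
    codes = encode(sequence.residues)
    w = b - a
    if profile is not None:
        rows = profile.matrix[a:b]
        cdf = np.cumsum(rows, axis=1)
        draws = (rng.random((n_backgrounds, w))[:, :, None] > cdf[None]).sum(axis=2)
    else:
        draws = rng.integers(0, 4, size=(n_backgrounds, w))
    variants = np.tile(codes, (n_backgrounds, 1))
    variants[:, a:b] = draws.astype(np.int8)
    scores = _score_codes(variants, oracle, class_name)
    baseline = float(_score_codes(codes[None, :], oracle, class_name)[0])
    qs = {q: float(np.percentile(scores, q)) for q in (5, 25, 50, 75, 95)}
    return BackgroundRobustness(
        baseline=baseline,
        mean=float(scores.mean()),
        sd=float(scores.std(ddof=1)) if n_backgrounds > 1 else 0.0,
        quantiles=qs,
        scores=scores if keep_scores else None,
    )
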