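"""In silico saturation mutagenesis: the per-substitution delta-score landscape.

Every single-nucleotide substitution of a sequence is enumerated (3 per
position, so 1,500 variants for a 500 bp sequence), scored in one batched
oracle call together with the reference, and the difference to the reference
score recorded per (position, base).  Downstream searches rank mutations by
these deltas; ties break deterministically at the lowest position first, then
base order A < C < G < T.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .oracle import OracleModel
from .seqcore import ALPHABET, Sequence, ValidationError, decode, encode

__all__ = ["DeltaMatrix", "saturation_mutagenesis", "saturation_scores", "ranked_mutations"]


@dataclass
class DeltaMatrix:
    """L x 4 table of score changes for every single-nucleotide substitution.

    The reference-base column is exactly 0.  ``deltas[i, b]`` is
    score(sequence with base b at i) - score(reference).
    """

    reference: Sequence
    class_name: str
    deltas: np.ndarray
    base_score: float

    @property
    def n_variants(self) -> int:
        return 3 * len(self.reference)

    def to_tsv(self, path: str | Path) -> None:
        ref = self.reference.residues
        with open(path, "w") as fh:
            fh.write("position\tref\talt\tdelta\n")
            for i in range(len(ref)):
                for b, base in enumerate(ALPHABET):
                    if base == ref[i]:
                        continue
                    fh.write(f"{i}\t{ref[i]}\t{base}\t{self.deltas[i, b]:.10g}\n")


def _variant_codes(ref: np.ndarray) -> np.ndarray:
    """Reference plus all 3L single-substitution variants, reference first.

    Variant order is position-major, base order A<C<G<T within a position.
    """
    L = len(ref)
    variants = np.tile(ref, (3 * L + 1, 1))
    k = 1
    for p in range(L):
        for b in range(4):
            if b != ref[p]:
                variants[k, p] = b
                k += 1
    return variants


def saturation_scores(
    sequence: Sequence, oracle: OracleModel, class_names: Iterable[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Score the reference and every variant for several classes at once.

    Returns ``(base_scores (C,), variant_scores (L, 4, C))`` where the
    reference-base entries of ``variant_scores`` equal the base scores.
    """
    names = list(class_names)
    for name in names:
        if name not in oracle.class_names:
            raise ValidationError(f"unknown class {name!r}")
    ref = encode(sequence.residues)
    L = len(ref)
    variants = _variant_codes(ref)
    if hasattr(oracle, "score_encoded"):
        scores = oracle.score_encoded(variants, names)
    else:
        all_scores = oracle.score_batch([decode(v) for v in variants])
        cols = [oracle.class_names.index(n) for n in names]
        scores = all_scores[:, cols]
    base = scores[0]
    out = np.empty((L, 4, len(names)))
    out[np.arange(L), ref] = base
    k = 1
    for p in range(L):
        for b in range(4):
            if b != ref[p]:
                out[p, b] = scores[k]
                k += 1
    return base, out


def saturation_mutagenesis(
    sequence: Sequence, oracle: OracleModel, class_name: str
) -> DeltaMatrix:
    """Enumerate and score all single-substitution variants for one class."""
    base, scores = saturation_scores(sequence, oracle, [class_name])
    deltas = scores[:, :, 0] - base[0]
    ref = encode(sequence.residues)
    deltas[np.arange(len(ref)), ref] = 0.0  # reference column exactly zero
    return DeltaMatrix(
        reference=sequence,
        class_name=class_name,
        deltas=deltas,
        base_score=float(base[0]),
    )


def ranked_mutations(
    key: np.ndarray, feasible: np.ndarray | None = None
) -> list[tuple[int, int]]:
    """(position, base) pairs sorted by descending key with the deterministic
    tie-break (lowest position, then A<C<G<T); infeasible entries excluded."""
    L = key.shape[0]
    pos, base = np.meshgrid(np.arange(L), np.arange(4), indexing="ij")
    mask = np.ones_like(key, dtype=bool) if feasible is None else feasible
    p, b, k = pos[mask], base[mask], key[mask]
    order = np.lexsort((b, p, -k))
    return [(int(p[i]), int(b[i])) for i in order]
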