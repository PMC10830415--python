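"""The scoring contract all design algorithms call, plus a surrogate oracle.

An *oracle* maps a batch of equal-length DNA sequences to per-class scores in
[0, 1].  The design algorithms (evolution, implantation, genome scanning) are
model-agnostic: any object satisfying :class:`OracleModel` works, including
adapters around externally trained deep learning models.  The packaged
:class:`SurrogateOracle` is a fully specified, reproducible stand-in built
from transcription-factor binding-site models: its raw score is a weighted
sum of thresholded log-odds motif hits (activators positive, repressors
negative) passed through a logistic link,

    r(s) = sum_m  w_m * sum_{hits h: LLR_h >= tau_m} (LLR_h - tau_m)
           + sum_{qualifying activator hit pairs} beta_pair
    score(s) = 1 / (1 + exp(-(r - b)))

Without proximity bonuses r is an exact sum of per-hit terms, which the
exact attribution mode exploits.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence as TypingSequence, runtime_checkable

import numpy as np
from scipy.special import expit

from .motifs import MotifModel, motif_from_consensus, read_cb, read_meme_minimal, write_cb
from .seqcore import Sequence, ValidationError, encode

__all__ = [
    "OracleModel",
    "SurrogateMotif",
    "PairBonus",
    "SurrogateClassSpec",
    "SurrogateOracle",
    "GcContentOracle",
    "ContributionTrack",
    "contribution_scores",
    "score_sequences",
    "fly_surrogate",
    "human_surrogate",
    "FLY_SITES",
    "HUMAN_SITES",
    "WEAK_HUMAN_SITES",
    "load_surrogate_toml",
    "save_surrogate_toml",
]


@runtime_checkable
class OracleModel(Protocol):
    """Contract: a batch of equal-length sequences -> (n, C) scores in [0, 1].

    ``input_length`` is either a required integer length or ``"any"``.
    Scoring must be deterministic and free of cross-sequence interaction.
    """

    class_names: tuple[str, ...]
    input_length: int | str

    def score_batch(self, sequences: TypingSequence[Sequence | str]) -> np.ndarray: ...


def _as_codes(sequences: TypingSequence[Sequence | str]) -> np.ndarray:
    rows = [encode(s.residues if isinstance(s, Sequence) else s) for s in sequences]
    if len({len(r) for r in rows}) > 1:
        raise ValidationError("batch sequences must have equal length")
    return np.stack(rows)


def score_sequences(
    oracle: OracleModel, sequences: TypingSequence[Sequence | str], class_name: str
) -> np.ndarray:
    """Score a batch for one named class; batch order is preserved."""
    if class_name not in oracle.class_names:
        raise ValidationError(f"unknown class {class_name!r}; oracle knows {oracle.class_names}")
    if not sequences:
        return np.empty(0)
    L = len(sequences[0].residues if isinstance(sequences[0], Sequence) else sequences[0])
    if oracle.input_length != "any" and L != oracle.input_length:
        raise ValidationError(
            f"oracle expects length {oracle.input_length}, got {L}"
        )
    scores = oracle.score_batch(sequences)
    return scores[:, oracle.class_names.index(class_name)]


# ---------------------------------------------------------------------------
# surrogate oracle


@dataclass(frozen=True)
class SurrogateMotif:
    """A motif with its surrogate weight and hit threshold.

    ``weight`` is positive for activators, negative for repressors;
    ``tau`` is the log-odds threshold above which an occurrence counts as a
    hit.  If ``tau`` is None it defaults to 0.8 times the motif's maximal
    log-odds, which admits essentially consensus-quality sites only.
    """

    motif: MotifModel
    weight: float
    tau: float | None = None

    @property
    def threshold(self) -> float:
        return 0.8 * self.motif.max_log_odds() if self.tau is None else self.tau


@dataclass(frozen=True)
class PairBonus:
    """Proximity bonus: every pair of qualifying hits of ``motif_a`` and
    ``motif_b`` separated by at most ``max_gap`` bases (strictly between the
    two intervals) adds ``bonus`` to the raw score."""

    motif_a: str
    motif_b: str
    max_gap: int
    bonus: float


@dataclass
class SurrogateClassSpec:
    motifs: list[SurrogateMotif]
    intercept: float = 4.0
    pairs: list[PairBonus] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sm in self.motifs:
            if sm.motif.role == "activator" and sm.weight <= 0:
                raise ValidationError(f"activator {sm.motif.name!r} needs weight > 0")
            if sm.motif.role == "repressor" and sm.weight >= 0:
                raise ValidationError(f"repressor {sm.motif.name!r} needs weight < 0")

    @property
    def additive(self) -> bool:
        return not self.pairs


@dataclass(frozen=True)
class _Hit:
    motif: str
    start: int
    end: int
    strand: str
    llr: float


class SurrogateOracle:
    """Motif-additive logistic oracle over named classes.

    Both strands are scanned at every offset; an offset's LLR is the max of
    the forward and reverse-complement log-odds, so a hit is counted once per
    offset regardless of orientation.
    """

    input_length: int | str = "any"

    def __init__(self, classes: dict[str, SurrogateClassSpec]) -> None:
        if not classes:
            raise ValidationError("surrogate needs at least one class")
        self.classes = classes
        self.class_names: tuple[str, ...] = tuple(classes)

    # -- scanning core ------------------------------------------------------

    @staticmethod
    def _offset_llr(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
        """Per-offset log-odds of motif matrix ``lo`` (w, 4) on (n, L) codes."""
        n, L = codes.shape
        w = lo.shape[0]
        O = L - w + 1
        if O <= 0:
            return np.zeros((n, 0))
        llr = np.zeros((n, O))
        for i in range(w):
            llr += lo[i][codes[:, i : i + O]]
        return llr

    def _motif_excess(self, codes: np.ndarray, sm: SurrogateMotif) -> np.ndarray:
        """Sum over qualifying hits of (LLR - tau), per sequence."""
        lo = sm.motif.log_odds()
        fwd = self._offset_llr(codes, lo)
        rev = self._offset_llr(codes, lo[::-1, ::-1])
        best = np.maximum(fwd, rev)
        return np.maximum(best - sm.threshold, 0.0).sum(axis=1)

    def raw_scores(
        self, codes: np.ndarray, class_names: Iterable[str] | None = None
    ) -> np.ndarray:
        """Raw (pre-link) scores r(s) for an encoded (n, L) batch."""
        names = tuple(class_names) if class_names is not None else self.class_names
        n = codes.shape[0]
        out = np.zeros((n, len(names)), dtype=np.float64)
        # motif terms are shared between classes that reuse a (motif, tau) pair
        cache: dict[tuple[int, float], np.ndarray] = {}
        for ci, name in enumerate(names):
            spec = self.classes[name]
            for sm in spec.motifs:
                key = (id(sm.motif), sm.threshold)
                if key not in cache:
                    cache[key] = self._motif_excess(codes, sm)
                out[:, ci] += sm.weight * cache[key].astype(np.float64)
            if spec.pairs:
                for i in range(n):
                    out[i, ci] += self._pair_bonus(codes[i], spec)
        return out

    def _pair_bonus(self, codes_1d: np.ndarray, spec: SurrogateClassSpec) -> float:
        hits = self._hits_encoded(codes_1d, spec)
        by_name: dict[str, list[_Hit]] = {}
        for h in hits:
            by_name.setdefault(h.motif, []).append(h)
        total = 0.0
        for pb in spec.pairs:
            sub = 0.0
            for ha in by_name.get(pb.motif_a, []):
                for hb in by_name.get(pb.motif_b, []):
                    if ha is hb:
                        continue
                    gap = max(ha.start, hb.start) - min(ha.end, hb.end)
                    if 0 <= gap <= pb.max_gap:
                        sub += pb.bonus
            # a same-motif pair enumerates every unordered hit pair twice
            total += sub / 2.0 if pb.motif_a == pb.motif_b else sub
        return total

    def _hits_encoded(self, codes_1d: np.ndarray, spec: SurrogateClassSpec) -> list[_Hit]:
        codes = codes_1d[None, :]
        hits: list[_Hit] = []
        for sm in spec.motifs:
            lo = sm.motif.log_odds()
            fwd = self._offset_llr(codes, lo)[0]
            rev = self._offset_llr(codes, lo[::-1, ::-1])[0]
            tau = sm.threshold
            w = sm.motif.width
            for o in range(fwd.shape[0]):
                llr = max(fwd[o], rev[o])
                if llr >= tau:
                    strand = "+" if fwd[o] >= rev[o] else "-"
                    hits.append(_Hit(sm.motif.name, o, o + w, strand, float(llr)))
        return hits

    # -- public API ---------------------------------------------------------

    def score_batch(self, sequences: TypingSequence[Sequence | str]) -> np.ndarray:
        return self.score_encoded(_as_codes(sequences))

    def score_encoded(
        self, codes: np.ndarray, class_names: Iterable[str] | None = None
    ) -> np.ndarray:
        """Fast path: score an already-encoded (n, L) int batch."""
        names = tuple(class_names) if class_names is not None else self.class_names
        n = codes.shape[0]
        out = np.empty((n, len(names)), dtype=np.float64)
        # chunk rows so per-motif work arrays stay cache-friendly
        chunk = max(64, int(4e6 // (8 * max(codes.shape[1], 1))))
        b = np.array([self.classes[c].intercept for c in names])
        for lo_i in range(0, n, chunk):
            sl = slice(lo_i, lo_i + chunk)
            out[sl] = expit(self.raw_scores(codes[sl], names) - b)
        return out

    def hits(self, sequence: Sequence | str, class_name: str) -> list[_Hit]:
        """Qualifying hits (LLR >= tau) of every motif of one class."""
        residues = sequence.residues if isinstance(sequence, Sequence) else sequence
        return self._hits_encoded(encode(residues), self.classes[class_name])


class GcContentOracle:
    """A deliberately simple oracle scoring GC fraction through a logistic link.

    Useful as a cheap, fully deterministic stand-in when exercising the
    search machinery at scale (the structure of a search does not depend on
    which oracle guides it).
    """

    input_length: int | str = "any"
    class_names: tuple[str, ...] = ("GC",)

    def __init__(self, midpoint: float = 0.5, steepness: float = 20.0) -> None:
        self.midpoint = midpoint
        self.steepness = steepness

    def score_batch(self, sequences: TypingSequence[Sequence | str]) -> np.ndarray:
        return self.score_encoded(_as_codes(sequences))

    def score_encoded(
        self, codes: np.ndarray, class_names: Iterable[str] | None = None
    ) -> np.ndarray:
        gc = ((codes == 1) | (codes == 2)).mean(axis=1)
        return expit(self.steepness * (gc - self.midpoint))[:, None]


# ---------------------------------------------------------------------------
# packaged surrogate presets

FLY_SITES = {
    "Ey": "TGCTCACTCAAGCGTAA",
    "Mef2": "CTATTTATAG",
    "Onecut": "ATCGAT",
    "Sr": "CCACCC",
}
# CAATTA is a repressor site class; the second fly repressor (Mamo) has no
# published consensus, so a synthetic 5-mer stand-in is used.
FLY_REPRESSORS = {"CAATTA": "CAATTA", "Mamo_standin": "CGTCA"}

# synthetic stand-in activators for a second fly class so that dual-code
# (augment/prune) objectives are exercisable out of the box
T_NEURON_SITES = {"Tact1_standin": "TAATCCGGTA", "Tact2_standin": "GGATCCGA"}

HUMAN_SITES = {
    "SOX10": "AACAATGGGCCCATTGTT",
    "MITF": "GTCACGTGAC",
    "TFAP2": "GCCTGAGGC",
}
# ZEB-class E-box used as the human repressor stand-in
HUMAN_REPRESSORS = {"ZEB_standin": "CACCTG"}

# weaker binding-site variants lifted from a native human enhancer
WEAK_HUMAN_SITES = {
    "SOX10_1": "GTGAATGACAGCTTTGTT",
    "SOX10_2": "TACAAGTATCTCCATTGT",
    "MITF_1": "ATCATGTGAA",
    "MITF_2": "GCCATATGAC",
    "TFAP2_1": "TCTTCAGGC",
    "TFAP2_2": "CCCTGTGGT",
}

_ACT_W, _REP_W, _INTERCEPT = 1.0, -2.5, 4.0


def _spec_from_sites(
    activators: dict[str, str], repressors: dict[str, str]
) -> SurrogateClassSpec:
    motifs = [
        SurrogateMotif(motif_from_consensus(n, s, "activator"), _ACT_W)
        for n, s in activators.items()
    ] + [
        SurrogateMotif(motif_from_consensus(n, s, "repressor"), _REP_W)
        for n, s in repressors.items()
    ]
    return SurrogateClassSpec(motifs=motifs, intercept=_INTERCEPT)


def fly_surrogate() -> SurrogateOracle:
    """Packaged fly-brain surrogate with a Kenyon-cell class ("KC") and a
    second, synthetic optic-lobe-like class ("T_neuron") for dual-code work."""
    return SurrogateOracle(
        {
            "KC": _spec_from_sites(FLY_SITES, FLY_REPRESSORS),
            "T_neuron": _spec_from_sites(T_NEURON_SITES, FLY_REPRESSORS),
        }
    )


def human_surrogate() -> SurrogateOracle:
    """Packaged human melanoma surrogate with a melanocytic class ("MEL")."""
    return SurrogateOracle({"MEL": _spec_from_sites(HUMAN_SITES, HUMAN_REPRESSORS)})


# ---------------------------------------------------------------------------
# attribution


@dataclass
class ContributionTrack:
    """Per-reference-nucleotide contribution values for one class."""

    values: np.ndarray
    method: str


def contribution_scores(
    oracle: OracleModel,
    sequence: Sequence,
    class_name: str,
    method: str = "ism_mean_delta",
) -> ContributionTrack:
    """Per-nucleotide attribution of the oracle's class score.

    ``ism_mean_delta`` (model-agnostic): value_i = score(ref) minus the mean
    score over the three alternate bases at i — the average cost of losing
    the reference base.  ``surrogate_exact`` (additive surrogates only):
    each qualifying hit's raw term w_m*(LLR - tau_m) is distributed over the
    hit's positions in proportion to their per-position log-odds, so the
    values sum exactly to the raw score.
    """
    if method == "ism_mean_delta":
        L = len(sequence)
        ref = encode(sequence.residues)
        variants = np.tile(ref, (3 * L + 1, 1))
        k = 1
        for p in range(L):
            for b in range(4):
                if b != ref[p]:
                    variants[k, p] = b
                    k += 1
        if hasattr(oracle, "score_encoded"):
            scores = oracle.score_encoded(variants, [class_name])[:, 0]
        else:
            from .seqcore import decode

            scores = score_sequences(
                oracle, [decode(v) for v in variants], class_name
            )
        base = scores[0]
        values = base - scores[1:].reshape(L, 3).mean(axis=1)
        return ContributionTrack(values=values, method=method)

    if method == "surrogate_exact":
        if not isinstance(oracle, SurrogateOracle):
            raise ValidationError("surrogate_exact requires a SurrogateOracle")
        spec = oracle.classes[class_name]
        if not spec.additive:
            raise ValidationError(
                "surrogate_exact is undefined for oracles with proximity bonuses"
            )
        codes = encode(sequence.residues)
        values = np.zeros(len(codes), dtype=np.float64)
        by_name = {sm.motif.name: sm for sm in spec.motifs}
        for hit in oracle._hits_encoded(codes, spec):
            sm = by_name[hit.motif]
            lo = sm.motif.log_odds()
            if hit.strand == "-":
                lo = lo[::-1, ::-1]
            per_pos = lo[np.arange(sm.motif.width), codes[hit.start : hit.end]]
            llr = per_pos.sum()
            term = sm.weight * (llr - sm.threshold)
            values[hit.start : hit.end] += term * (per_pos / llr)
        return ContributionTrack(values=values, method=method)

    raise ValidationError(f"unknown attribution method {method!r}")


# ---------------------------------------------------------------------------
# TOML serialization


def save_surrogate_toml(
    oracle: SurrogateOracle, path: str | Path, motif_format: str = "cb"
) -> None:
    """Write the surrogate spec as TOML with motif matrices in side files."""
    path = Path(path)
    lines: list[str] = []
    for name, spec in oracle.classes.items():
        motif_path = path.with_name(f"{path.stem}.{name}.cb")
        write_cb([sm.motif for sm in spec.motifs], motif_path)
        lines.append(f"[class.{name}]")
        lines.append(f'motif_file = "{motif_path.name}"')
        lines.append(f"intercept = {spec.intercept}")
        roles = ", ".join(f'"{sm.motif.role}"' for sm in spec.motifs)
        weights = ", ".join(str(sm.weight) for sm in spec.motifs)
        taus = ", ".join(str(sm.threshold) for sm in spec.motifs)
        lines.append(f"roles = [{roles}]")
        lines.append(f"weights = [{weights}]")
        lines.append(f"taus = [{taus}]")
        for pb in spec.pairs:
            lines.append(f"[[class.{name}.pair]]")
            lines.append(f'motif_a = "{pb.motif_a}"')
            lines.append(f'motif_b = "{pb.motif_b}"')
            lines.append(f"max_gap = {pb.max_gap}")
            lines.append(f"bonus = {pb.bonus}")
        lines.append("")
    path.write_text("\n".join(lines))


def load_surrogate_toml(path: str | Path) -> SurrogateOracle:
    path = Path(path)
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    classes: dict[str, SurrogateClassSpec] = {}
    for name, sec in cfg.get("class", {}).items():
        motif_path = path.with_name(sec["motif_file"])
        if motif_path.suffix == ".cb":
            motifs = read_cb(motif_path)
        else:
            motifs = read_meme_minimal(motif_path)
        roles = sec.get("roles", ["activator"] * len(motifs))
        weights = sec["weights"]
        taus = sec.get("taus", [None] * len(motifs))
        sms = []
        for m, role, w, tau in zip(motifs, roles, weights, taus):
            m.role = role
            sms.append(SurrogateMotif(m, w, tau))
        pairs = [
            PairBonus(p["motif_a"], p["motif_b"], p["max_gap"], p["bonus"])
            for p in sec.get("pair", [])
        ]
        classes[name] = SurrogateClassSpec(
            motifs=sms, intercept=sec.get("intercept", 4.0), pairs=pairs
        )
    return SurrogateOracle(classes)
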