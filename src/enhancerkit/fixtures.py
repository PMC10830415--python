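"""Deterministic synthetic fixtures for every pipeline stage.

Real enhancer-design studies start from external region sets and genomes;
this module generates self-contained stand-ins with known ground truth so
every operation in the package can be exercised and validated end to end:

* ``random_profile`` — GC-graded profile-random sequences;
* ``implanted_positive`` — sequences carrying the full activator site
  combination with all repressor hits ablated (score > 0.9 under the
  packaged fly surrogate by the calibration property);
* ``near_enhancer`` — activator sites present plus two planted repressor
  hits, so a short evolution budget rescues them;
* ``toy_genome`` — a small multi-contig genome with planted positive loci
  and a matching accessibility bedGraph (one planted locus accessible, one
  not), giving the genome scan a recoverable answer;
* ``gan_training_set`` — motif-implanted one-hot training sequences for
  smoke-scale generator training.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .oracle import FLY_REPRESSORS, FLY_SITES, SurrogateOracle, fly_surrogate
from .implant import ImplantPlacement, iterative_implant
from .seqcore import (
    PositionFrequencyProfile,
    Sequence,
    ValidationError,
    decode,
    default_profile,
    encode,
    generate_random_sequences,
    one_hot,
    write_bed,
    write_fasta,
)

__all__ = [
    "ablate_repressor_hits",
    "random_profile_fixture",
    "implanted_positive_fixture",
    "near_enhancer_fixture",
    "toy_genome_fixture",
    "gan_training_set",
    "ToyGenome",
    "make_fixtures",
]

FIXTURE_KINDS = (
    "random_profile",
    "near_enhancer",
    "implanted_positive",
    "toy_genome",
    "gan_training_set",
)


def ablate_repressor_hits(
    sequence: Sequence,
    oracle: SurrogateOracle,
    class_name: str,
    max_rounds: int = 20,
) -> Sequence:
    """Destroy every qualifying repressor hit by point mutation.

    Each round mutates the centre base of each remaining repressor hit to
    the alternative with the lowest log-odds under that motif (a single
    mismatch pushes any near-consensus hit below its threshold); re-scans
    until no repressor hit remains.
    """
    spec = oracle.classes[class_name]
    by_name = {sm.motif.name: sm for sm in spec.motifs}
    codes = encode(sequence.residues)
    for _ in range(max_rounds):
        rep_hits = [
            h
            for h in oracle._hits_encoded(codes, spec)
            if by_name[h.motif].motif.role == "repressor"
        ]
        if not rep_hits:
            return Sequence(id=sequence.id, residues=decode(codes))
        for h in rep_hits:
            sm = by_name[h.motif]
            lo = sm.motif.log_odds()
            if h.strand == "-":
                lo = lo[::-1, ::-1]
            centre = h.start + sm.motif.width // 2
            codes[centre] = int(lo[centre - h.start].argmin())
    raise ValidationError("repressor ablation did not converge")


def random_profile_fixture(
    n: int, seed: int, length: int = 500, profile: PositionFrequencyProfile | None = None
) -> list[Sequence]:
    return generate_random_sequences(profile or default_profile(length), n, seed)


def implanted_positive_fixture(
    n: int,
    seed: int,
    length: int = 500,
    oracle: SurrogateOracle | None = None,
    class_name: str = "KC",
) -> tuple[list[Sequence], list[list[ImplantPlacement]]]:
    """Sequences carrying all activator sites at their best positions with
    repressor hits ablated."""
    oracle = oracle or fly_surrogate()
    sites = list(FLY_SITES.items())
    out, placements = [], []
    for i, start in enumerate(random_profile_fixture(n, seed, length)):
        clean = ablate_repressor_hits(start, oracle, class_name)
        designed, pl, _ = iterative_implant(clean, sites, oracle, class_name)
        designed = ablate_repressor_hits(designed, oracle, class_name)
        out.append(Sequence(id=f"implanted_{i}", residues=designed.residues))
        placements.append(pl)
    return out, placements


def near_enhancer_fixture(
    n: int,
    seed: int,
    length: int = 500,
    oracle: SurrogateOracle | None = None,
    class_name: str = "KC",
) -> list[Sequence]:
    """All activator sites present plus two planted repressor consensus hits.

    The repressor sites dominate, holding the score low; ablating them (a
    few point mutations) releases the activators, so a 6-step evolution
    budget suffices to cross 0.5.
    """
    oracle = oracle or fly_surrogate()
    rng = np.random.default_rng(seed)
    starts = random_profile_fixture(n, seed + 1, length)
    # activator sites at random (not score-optimal) positions: present but not
    # over-optimized, so the two repressor hits dominate the raw score
    sites = list(FLY_SITES.values()) + list(FLY_REPRESSORS.values())[:2]
    out = []
    for i, start in enumerate(starts):
        clean = ablate_repressor_hits(start, oracle, class_name)
        base_codes = encode(clean.residues)
        for _ in range(50):  # redraw placements if stray hits push the start high
            codes = base_codes.copy()
            occupied: list[tuple[int, int]] = []
            for site in sites:
                w = len(site)
                for _ in range(1000):
                    o = int(rng.integers(0, length - w + 1))
                    if not any(max(o, s) < min(o + w, e) for s, e in occupied):
                        break
                else:  # pragma: no cover - essentially impossible at these densities
                    raise ValidationError("could not place site")
                codes[o : o + w] = encode(site)
                occupied.append((o, o + w))
            if oracle.score_encoded(codes[None, :], [class_name])[0, 0] < 0.5:
                break
        else:  # pragma: no cover
            raise ValidationError("could not construct a sub-0.5 near-enhancer")
        out.append(Sequence(id=f"near_enhancer_{i}", residues=decode(codes)))
    return out


@dataclass
class ToyGenome:
    contigs: dict[str, str]
    signal: dict[str, list[tuple[int, int, float]]]
    planted_low_signal: list[tuple[str, int, int]]  # expected near-enhancer hits
    planted_high_signal: list[tuple[str, int, int]]  # accessible, must be excluded


def toy_genome_fixture(
    seed: int,
    contig_length: int = 3000,
    window: int = 500,
    oracle: SurrogateOracle | None = None,
    class_name: str = "KC",
) -> ToyGenome:
    """Three-contig genome with two planted surrogate-positive 500 bp loci.

    The locus on contig chrA carries no accessibility signal (a true
    near-enhancer); the one on chrB sits under a high-signal bedGraph block
    and must be rejected by the accessibility filter.
    """
    oracle = oracle or fly_surrogate()
    rng = np.random.default_rng(seed)
    positives, _ = implanted_positive_fixture(2, seed + 7, window, oracle, class_name)
    contigs = {}
    for name in ("chrA", "chrB", "chrC"):
        contigs[name] = decode(rng.integers(0, 4, contig_length).astype(np.int8))

    def plant(chrom: str, at: int, seq: Sequence) -> None:
        s = contigs[chrom]
        contigs[chrom] = s[:at] + seq.residues + s[at + window :]

    a_at, b_at = 500, 1000  # window-grid-aligned so a scan window matches exactly
    plant("chrA", a_at, positives[0])
    plant("chrB", b_at, positives[1])
    signal = {
        "chrB": [(b_at - 100, b_at + window + 100, 8.0)],
        "chrC": [(0, contig_length, 1.0)],
    }
    return ToyGenome(
        contigs=contigs,
        signal=signal,
        planted_low_signal=[("chrA", a_at, a_at + window)],
        planted_high_signal=[("chrB", b_at, b_at + window)],
    )


def gan_training_set(
    n: int,
    seq_len: int,
    seed: int,
    site: str = FLY_SITES["Onecut"],
    position: int | None = None,
) -> tuple[np.ndarray, list[Sequence]]:
    """Uniform-random sequences with one consensus site at a fixed position.

    A fixed implantation position makes the motif signal learnable at smoke
    scale; real training sets have positionally variable sites.
    Returns (one-hot (n, seq_len, 4), sequences).
    """
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(n, seq_len)).astype(np.int8)
    pos = (seq_len - len(site)) // 2 if position is None else position
    codes[:, pos : pos + len(site)] = encode(site)
    seqs = [Sequence(id=f"train_{i}", residues=decode(codes[i])) for i in range(n)]
    return one_hot(codes), seqs


def _write_bedgraph(signal: dict[str, list[tuple[int, int, float]]], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(signal):
            for start, end, value in sorted(signal[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def make_fixtures(kind: str, out_dir: str | Path, seed: int, **params) -> dict[str, str]:
    """Generate a named fixture kind on disk; returns a manifest of files.

    Deterministic: the same kind, seed and params produce byte-identical
    files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    if kind == "random_profile":
        seqs = random_profile_fixture(
            params.get("n", 10), seed, params.get("length", 500)
        )
        path = out_dir / "random_profile.fa"
        write_fasta(seqs, path)
        files["fasta"] = str(path)
    elif kind == "implanted_positive":
        seqs, _ = implanted_positive_fixture(
            params.get("n", 5), seed, params.get("length", 500)
        )
        path = out_dir / "implanted_positive.fa"
        write_fasta(seqs, path)
        files["fasta"] = str(path)
    elif kind == "near_enhancer":
        seqs = near_enhancer_fixture(
            params.get("n", 5), seed, params.get("length", 500)
        )
        path = out_dir / "near_enhancer.fa"
        write_fasta(seqs, path)
        files["fasta"] = str(path)
    elif kind == "toy_genome":
        toy = toy_genome_fixture(seed, params.get("contig_length", 3000))
        fa = out_dir / "toy_genome.fa"
        write_fasta(
            [Sequence(id=c, residues=s) for c, s in sorted(toy.contigs.items())], fa
        )
        bg = out_dir / "toy_genome.bedgraph"
        _write_bedgraph(toy.signal, bg)
        bed = out_dir / "toy_genome.planted.bed"
        with open(bed, "w") as fh:
            for chrom, start, end in toy.planted_low_signal:
                fh.write(f"{chrom}\t{start}\t{end}\tplanted_low_signal\n")
            for chrom, start, end in toy.planted_high_signal:
                fh.write(f"{chrom}\t{start}\t{end}\tplanted_high_signal\n")
        files.update(fasta=str(fa), bedgraph=str(bg), planted_bed=str(bed))
    elif kind == "gan_training_set":
        _, seqs = gan_training_set(
            params.get("n", 128), params.get("seq_len", 100), seed
        )
        path = out_dir / "gan_training_set.fa"
        write_fasta(seqs, path)
        files["fasta"] = str(path)
    else:
        raise ValidationError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}"
        )
    return files
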