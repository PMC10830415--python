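"""Position weight models: construction, log-odds, information content, file I/O.

Two text dialects are supported: the Cluster-Buster-style count matrix
(``>name`` followed by one whitespace-separated A C G T count row per
position) and MEME-minimal (``MOTIF name`` blocks with a
``letter-probability matrix`` header).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .seqcore import ALPHABET, ValidationError, encode

__all__ = [
    "MotifModel",
    "motif_from_consensus",
    "trim_by_information_content",
    "read_cb",
    "write_cb",
    "read_meme_minimal",
    "write_meme_minimal",
]


@dataclass
class MotifModel:
    """A probability matrix over A,C,G,T with an activator/repressor role.

    ``matrix`` has shape (w, 4); rows sum to 1.  ``role`` is advisory — it is
    how the surrogate oracle and the motif census interpret the model.
    """

    name: str
    matrix: np.ndarray
    role: str = "activator"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) == 0:
            raise ValidationError(f"motif {self.name!r}: matrix must be (w, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError(f"motif {self.name!r}: rows must sum to 1")
        if self.role not in ("activator", "repressor"):
            raise ValidationError(f"motif {self.name!r}: bad role {self.role!r}")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def log_odds(
        self, background: np.ndarray | None = None, pseudocount: float = 0.0
    ) -> np.ndarray:
        """(w, 4) log-odds versus a 0-order background (default uniform)."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        p = self.matrix + pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        return np.log(p / bg)

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(self.name, self.matrix[::-1, ::-1].copy(), self.role)

    def max_log_odds(self, **kw) -> float:
        return float(self.log_odds(**kw).max(axis=1).sum())

    def information_content(self) -> np.ndarray:
        """Per-position IC in bits against a uniform background."""
        p = np.clip(self.matrix, 1e-12, 1.0)
        return 2.0 + (p * np.log2(p)).sum(axis=1)


def motif_from_consensus(
    name: str, consensus: str, role: str = "activator", match: float = 0.85
) -> MotifModel:
    """Build a PWM from a consensus site: ``match`` probability on the
    consensus base, the remainder split evenly over the other three."""
    codes = encode(consensus.upper())
    off = (1.0 - match) / 3.0
    matrix = np.full((len(codes), 4), off)
    matrix[np.arange(len(codes)), codes] = match
    return MotifModel(name, matrix, role)


def trim_by_information_content(motif: MotifModel, threshold: float = 0.1) -> MotifModel:
    """Trim low-information flanks: keep the span between the first and last
    position whose IC exceeds ``threshold`` bits."""
    ic = motif.information_content()
    keep = np.where(ic > threshold)[0]
    if len(keep) == 0:
        raise ValidationError(f"motif {motif.name!r}: no position above IC threshold")
    return MotifModel(motif.name, motif.matrix[keep[0] : keep[-1] + 1].copy(), motif.role)


# ---------------------------------------------------------------------------
# file dialects


def read_cb(path: str | Path, role: str = "activator") -> list[MotifModel]:
    """Read a Cluster-Buster-style count matrix file (``>name`` + count rows)."""
    motifs: list[MotifModel] = []
    name, rows = None, []

    def flush():
        if name is None:
            return
        if not rows:
            raise ValidationError(f"motif {name!r}: no count rows")
        counts = np.asarray(rows, dtype=np.float64)
        motifs.append(MotifModel(name, counts / counts.sum(axis=1, keepdims=True), role))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].strip(), []
            else:
                parts = line.split()
                if len(parts) != 4:
                    raise ValidationError(f"{path}:{lineno}: expected 4 columns")
                rows.append([float(x) for x in parts])
    flush()
    return motifs


def write_cb(motifs: Iterable[MotifModel], path: str | Path, scale: float = 100.0) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.name}\n")
            for row in m.matrix:
                fh.write("\t".join(f"{scale * v:.4f}" for v in row) + "\n")


def read_meme_minimal(path: str | Path, role: str = "activator") -> list[MotifModel]:
    """Read a MEME-minimal motif file (MOTIF blocks with letter-probability
    matrices)."""
    motifs: list[MotifModel] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ValidationError(f"{path}:{i + 1}: MOTIF line without a name")
            name = parts[1]
            w = None
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise ValidationError(f"{path}: motif {name!r} has no matrix")
                i += 1
            if i >= len(lines):
                raise ValidationError(f"{path}: motif {name!r} has no matrix")
            m = re.search(r"w=\s*(\d+)", lines[i])
            if m:
                w = int(m.group(1))
            i += 1
            rows = []
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                rows.append([float(x) for x in stripped.split()])
                i += 1
            matrix = np.asarray(rows, dtype=np.float64)
            if w is not None and len(matrix) != w:
                raise ValidationError(
                    f"{path}: motif {name!r} declares w={w} but has {len(matrix)} rows"
                )
            motifs.append(MotifModel(name, matrix, role))
        else:
            i += 1
    return motifs


def write_meme_minimal(motifs: Iterable[MotifModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.matrix:
                fh.write("  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
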