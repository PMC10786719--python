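"""Trinucleotide position indexing over a reference genome.

Used wherever mutations are re-placed at context-matched sites: the
doublet permutation null, the topography-matched simulations, and the
synthetic-study generator.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_BASES = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Sequence as uint8 codes (A=0,C=1,G=2,T=3; 255 for anything else)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def tri_code(tri: str) -> int:
    return _BASES.index(tri[0]) * 16 + _BASES.index(tri[1]) * 4 + _BASES.index(tri[2])


def tri_label(code: int) -> str:
    return _BASES[code // 16] + _BASES[(code // 4) % 4] + _BASES[code % 4]


def trinucleotide_codes(seq: str) -> np.ndarray:
    """Per-position trinucleotide code for interior positions.

    Entry i corresponds to the window starting at 0-based position i
    (centered on i+1); windows containing a non-ACGT base get code 255.
    """
    b = encode(seq)
    if b.size < 3:
        return np.empty(0, dtype=np.int16)
    valid = (b[:-2] < 4) & (b[1:-1] < 4) & (b[2:] < 4)
    tri = (
        b[:-2].astype(np.int16) * 16
        + b[1:-1].astype(np.int16) * 4
        + b[2:].astype(np.int16)
    )
    tri[~valid] = 255
    return tri


class ContextIndex:
    """Genome-wide positions of every trinucleotide.

    Positions are 1-based coordinates of the *center* base of each
    occurrence, per contig.
    """

    def __init__(self, genome) -> None:
        chroms = list(genome.keys()) if hasattr(genome, "keys") else list(genome)
        self.chroms: list[str] = [str(c) for c in chroms]
        per_code: dict[int, list[tuple[int, np.ndarray]]] = {}
        for ci, chrom in enumerate(self.chroms):
            seq = str(genome[chrom][:]).upper()
            tri = trinucleotide_codes(seq)
            for code in range(64):
                pos = np.flatnonzero(tri == code) + 2  # 1-based center
                if pos.size:
                    per_code.setdefault(code, []).append((ci, pos))
        self._index: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for code, parts in per_code.items():
            chrom_idx = np.concatenate(
                [np.full(p.size, ci, dtype=np.int32) for ci, p in parts]
            )
            pos = np.concatenate([p for _, p in parts])
            self._index[code] = (chrom_idx, pos)

    def count(self, tri: str) -> int:
        entry = self._index.get(tri_code(tri))
        return 0 if entry is None else entry[1].size

    def sample(self, tri: str, rng: np.random.Generator) -> tuple[str, int]:
        """Uniform random occurrence of a trinucleotide: (chrom, 1-based pos)."""
        entry = self._index.get(tri_code(tri))
        if entry is None:
            raise KeyError(f"no occurrence of context {tri}")
        chrom_idx, pos = entry
        i = int(rng.integers(pos.size))
        return self.chroms[chrom_idx[i]], int(pos[i])


class DinucIndex:
    """Per-contig 1-based start positions of every dinucleotide."""

    def __init__(self, genome) -> None:
        chroms = list(genome.keys()) if hasattr(genome, "keys") else list(genome)
        self.chroms = [str(c) for c in chroms]
        self._index: dict[str, dict[int, np.ndarray]] = {}
        for chrom in self.chroms:
            seq = str(genome[chrom][:]).upper()
            b = encode(seq)
            if b.size < 2:
                continue
            valid = (b[:-1] < 4) & (b[1:] < 4)
            di = b[:-1].astype(np.int16) * 4 + b[1:]
            di[~valid] = 255
            self._index[chrom] = {
                code: np.flatnonzero(di == code) + 1
                for code in range(16)
                if (di == code).any()
            }

    def positions(self, chrom: str, dinuc: str) -> np.ndarray:
        code = _BASES.index(dinuc[0]) * 4 + _BASES.index(dinuc[1])
        return self._index.get(chrom, {}).get(code, np.empty(0, dtype=np.int64))

    def count(self, dinuc: str) -> int:
        return sum(self.positions(c, dinuc).size for c in self.chroms)

    def sample(self, dinuc: str, rng: np.random.Generator) -> tuple[str, int]:
        counts = np.array([self.positions(c, dinuc).size for c in self.chroms])
        total = counts.sum()
        if total == 0:
            raise KeyError(f"no occurrence of dinucleotide {dinuc}")
        flat = int(rng.integers(total))
        ci = int(np.searchsorted(np.cumsum(counts), flat, side="right"))
        offset = flat - int(np.concatenate(([0], np.cumsum(counts)))[ci])
        return self.chroms[ci], int(self.positions(self.chroms[ci], dinuc)[offset])
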