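"""Sequence and coverage containers.

Two genome backends expose the same two-method interface (``fetch`` and
``__contains__``): :class:`ArrayGenome` holds synthetic chromosomes as byte
arrays in memory, :class:`FastaGenome` wraps an indexed FASTA on disk via
pyfaidx.  Either can be handed to the internal-priming filter and the
poly(A)-signal scan.

:class:`CoverageTrack` is a dense per-base read-coverage container used by
the RUD estimator; it reads and writes bedGraph.
"""

from __future__ import annotations

import numpy as np
import pyfaidx

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class ArrayGenome:
    """In-memory genome: chrom name -> uint8 array of ASCII base codes."""

    def __init__(self, chroms: dict[str, np.ndarray]):
        self._chroms = chroms

    @classmethod
    def random(cls, sizes: dict[str, int], rng: np.random.Generator) -> "ArrayGenome":
        return cls({name: _BASES[rng.integers(0, 4, size=n)].copy() for name, n in sizes.items()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def chrom_size(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand sequence of half-open interval [start, end)."""
        arr = self._chroms[chrom]
        if start < 0 or end > len(arr):
            raise IndexError(f"{chrom}:{start}-{end} outside genome bounds (size {len(arr)})")
        return self._chroms[chrom][start:end].tobytes().decode("ascii")

    def plant(self, chrom: str, pos: int, seq: str, strand: str) -> None:
        """Overwrite genome so the *transcript-strand* sequence at ``pos`` is ``seq``.

        On '+' the sequence occupies [pos, pos+len); on '-' it occupies
        [pos-len+1, pos+1) as the reverse complement, so that reading the
        minus strand 5'->3' starting at ``pos`` yields ``seq``.
        """
        if strand == "+":
            start, placed = pos, seq
        else:
            start, placed = pos - len(seq) + 1, revcomp(seq)
        arr = self._chroms[chrom]
        if start < 0 or start + len(placed) > len(arr):
            raise IndexError(f"plant at {chrom}:{start} outside genome bounds")
        arr[start : start + len(placed)] = np.frombuffer(placed.encode("ascii"), dtype=np.uint8)

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self._chroms:
                fh.write(f">{name}\n")
                s = self._chroms[name].tobytes().decode("ascii")
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")


class FastaGenome:
    """pyfaidx-backed genome with the same fetch interface as ArrayGenome."""

    def __init__(self, path: str):
        self._fa = pyfaidx.Fasta(path)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fa

    def chrom_size(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > len(self._fa[chrom]):
            raise IndexError(f"{chrom}:{start}-{end} outside genome bounds")
        return str(self._fa[chrom][start:end])


def fetch_transcript_strand(genome, chrom: str, start: int, end: int, strand: str) -> str:
    """Transcript-strand (5'->3') sequence of genomic interval [start, end)."""
    seq = genome.fetch(chrom, start, end)
    return seq if strand == "+" else revcomp(seq)


class CoverageTrack:
    """Dense per-base coverage, one float array per chromosome."""

    def __init__(self, sizes: dict[str, int]):
        self._cov = {name: np.zeros(n, dtype=np.float64) for name, n in sizes.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self._cov)

    def array(self, chrom: str) -> np.ndarray:
        return self._cov[chrom]

    def add(self, chrom: str, start: int, values: np.ndarray) -> None:
        """Add per-base values over [start, start+len(values))."""
        self._cov[chrom][start : start + len(values)] += values

    def mean(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        return float(self._cov[chrom][start:end].mean())

    def total(self, chrom: str, start: int, end: int) -> float:
        return float(self._cov[chrom][start:end].sum())

    def write_bedgraph(self, path: str) -> None:
        """Run-length-encoded bedGraph; zero runs are omitted."""
        with open(path, "w") as fh:
            for chrom, arr in self._cov.items():
                if not len(arr):
                    continue
                # run boundaries where the value changes
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    @classmethod
    def read_bedgraph(cls, path: str, sizes: dict[str, int] | None = None) -> "CoverageTrack":
        """Load a bedGraph.  Without ``sizes``, chromosome sizes are taken as
        the right-most covered coordinate."""
        rows: list[tuple[str, int, int, float]] = []
        maxima: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, s, e, v = line.split("\t")
                s, e, v = int(s), int(e), float(v)
                rows.append((chrom, s, e, v))
                maxima[chrom] = max(maxima.get(chrom, 0), e)
        track = cls(sizes if sizes is not None else maxima)
        for chrom, s, e, v in rows:
            track._cov[chrom][s:e] += v
        return track
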