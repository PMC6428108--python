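"""Core domain types shared across the pipeline.

Coordinate conventions
----------------------
All internal coordinates are 0-based.  Genomic intervals are half-open
``[start, end)`` (BED convention); GTF output converts to 1-based inclusive
on write.

A gene's 3'UTR is described strand-aware through two quantities:

``stop_pos``
    genomic coordinate of the *first* 3'UTR base, i.e. the base immediately
    downstream (in transcription direction) of the stop codon.
``utr_len``
    number of 3'UTR bases.

Positions along the UTR are addressed by their *distance from the stop
codon*, ``d`` in ``1..utr_len`` (d=1 is the first UTR base).  ``pos_at``
and ``distance_of`` convert between distances and genomic coordinates on
either strand, so the rest of the code never branches on strand for UTR
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware 3'UTR anatomy of one gene.

    ``exons`` are half-open genomic intervals sorted by genomic start; the
    UTR is contained in the terminal exon.  ``tx_start``/``tx_end`` bound
    the transcribed locus in genomic coordinates (half-open).
    """

    gene_id: str
    chrom: str
    strand: str
    stop_pos: int
    utr_len: int
    exons: tuple[tuple[int, int], ...] = ()
    tx_start: int = -1
    tx_end: int = -1

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.utr_len <= 0:
            raise ValueError(f"{self.gene_id}: utr_len must be positive")

    # -- UTR distance arithmetic -------------------------------------------
    def pos_at(self, d: int) -> int:
        """Genomic coordinate of the UTR base at distance ``d`` from the stop codon."""
        if self.strand == "+":
            return self.stop_pos + (d - 1)
        return self.stop_pos - (d - 1)

    def distance_of(self, pos: int) -> int:
        """Distance from the stop codon (1-based) of genomic coordinate ``pos``."""
        if self.strand == "+":
            return pos - self.stop_pos + 1
        return self.stop_pos - pos + 1

    @property
    def utr3_end(self) -> int:
        """Genomic coordinate of the annotated 3' terminus (last UTR base)."""
        return self.pos_at(self.utr_len)

    @property
    def utr_interval(self) -> tuple[int, int]:
        """Half-open genomic interval covered by the 3'UTR."""
        if self.strand == "+":
            return (self.stop_pos, self.stop_pos + self.utr_len)
        return (self.stop_pos - self.utr_len + 1, self.stop_pos + 1)

    def contains_utr(self, pos: int) -> bool:
        lo, hi = self.utr_interval
        return lo <= pos < hi

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return tuple(out)


@dataclass
class GeneAPAProfile:
    """Ordered 3'UTR pA sites of one gene in one sample.

    ``sites`` is a list of ``(distance_from_stop, tag_count)`` with strictly
    increasing distances; the substrate of the weighted 3'UTR-length (eUTR)
    statistic.
    """

    gene_id: str
    condition: str
    sites: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        dists = [d for d, _ in self.sites]
        if any(d <= 0 for d in dists):
            raise ValueError(f"{self.gene_id}: site distances must be positive")
        if any(b <= a for a, b in zip(dists, dists[1:])):
            raise ValueError(f"{self.gene_id}: site distances must be strictly increasing")
        if any(c < 0 for _, c in self.sites):
            raise ValueError(f"{self.gene_id}: tag counts must be non-negative")

    @property
    def total_tags(self) -> int:
        return int(sum(c for _, c in self.sites))

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def classify_delta(delta: float, cutoff: float) -> str:
    """Shortening / lengthening call at one effect-size cutoff.

    Boundaries are inclusive: ``delta <= -cutoff`` is "shortened",
    ``delta >= +cutoff`` is "lengthened", anything between is "unchanged".
    A relative epsilon keeps deltas that hit a decimal cutoff exactly from
    being misclassified by floating-point representation (0.45 - 0.50
    evaluates a hair above -0.05).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    eps = 1e-9 * cutoff
    if delta <= -cutoff + eps:
        return "shortened"
    if delta >= cutoff - eps:
        return "lengthened"
    return "unchanged"


@dataclass
class EUTRRecord:
    """Per-gene eUTR comparison between two conditions."""

    gene_id: str
    eutr_ctrl: float
    eutr_kd: float
    delta_eutr: float
    classes: dict[float, str]


@dataclass
class RUDRecord:
    """Per-gene RUD (distal-usage index) comparison between two conditions."""

    gene_id: str
    rud_ctrl: float
    rud_kd: float
    delta_rud: float
    classes: dict[float, str]


def genes_by_id(genes: Iterable[GeneModel]) -> dict[str, GeneModel]:
    out: dict[str, GeneModel] = {}
    for g in genes:
        if g.gene_id in out:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        out[g.gene_id] = g
    return out
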