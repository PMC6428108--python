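"""Two-condition APA simulator with known ground truth.

Emulates the statistical structure of a knockdown-vs-control 3'UTR study:
each gene carries a proximal and a distal pA site in its 3'UTR, and a
per-gene *long-isoform fraction* ``f_long`` governs distal-site usage.  In
"shifted" genes ``f_long`` differs between conditions (a knockdown that
favours the proximal site lowers it), which is exactly a 3'UTR shortening
event.  Three read types are generated per study:

* PA-seq tags: 3'-end tags whose tail-proximal mate begins with a poly(T)
  head ("TTT...") and aligns antisense at the cleavage position; a
  configurable contaminant fraction carries non-T heads to exercise the
  strand-correction filter.
* RNA-seq coverage: per-base Poisson coverage, full rate over the common
  UTR (cUTR) and rate scaled by ``f_long`` over the alternative UTR (aUTR)
  — so a gene's true distal-usage index (RUD) equals its ``f_long``.
* CLIP tags: uniform background over the 3'UTR (plus a small flank across
  both pA sites, so windows at either site sample the same background),
  with an optional multiplicative enrichment near proximal sites of
  shifted genes.

By construction the true eUTR of a gene is
``f_long * d_distal + (1 - f_long) * d_proximal``.

Randomness is organised as one pseudo-random stream per
(data-type, gene, condition), derived from the master seed with
``numpy.random.SeedSequence`` spawn keys, so adding genes or simulating
conditions in a different order never perturbs another gene's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ArrayGenome, CoverageTrack
from .models import GeneModel

CONDITIONS = ("ctrl", "kd")

# spawn-key stream codes
_LAYOUT, _PASEQ, _RNASEQ, _CLIP, _GENOME = 0, 1, 2, 3, 4

_CDS_EXON1 = 200
_INTRON = 150
_CDS_EXON2 = 100
_CDS_SPAN = _CDS_EXON1 + _INTRON + _CDS_EXON2
_LEFT_MARGIN = 1000

TRUTH_COLUMNS = [
    "gene_id", "chrom", "strand", "tx_start", "tx_end", "stop_pos", "utr_len",
    "prox_dist", "dist_dist", "proximal_pos", "distal_pos",
    "f_long_ctrl", "f_long_kd", "is_shifted", "decoy_dist", "decoy_pos",
    "true_eutr_ctrl", "true_eutr_kd",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _as_range(value, name: str) -> tuple[float, float]:
    if np.isscalar(value):
        return (float(value), float(value))
    lo, hi = value
    if lo > hi:
        raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
    return (float(lo), float(hi))


@dataclass
class SimConfig:
    """Study design of a simulated two-condition APA experiment.

    Fraction-like fields accept a scalar or a ``(lo, hi)`` range sampled
    uniformly per gene.  Depths are expected counts (Poisson means):
    ``pa_depth`` tags per gene per condition, ``cov_depth`` per-base
    RNA-seq coverage over the cUTR, ``clip_depth`` CLIP tags per gene.
    """

    n_genes: int = 100
    utr_len_range: tuple[int, int] = (600, 1200)
    proximal_frac_range: tuple[float, float] = (0.4, 0.7)
    f_long_ctrl: float | tuple[float, float] = 0.7
    f_long_kd: float | tuple[float, float] = 0.4
    shifted_gene_frac: float = 0.3
    pa_depth: float = 200.0
    cov_depth: float = 50.0
    clip_depth: float = 50.0
    clip_prox_enrich: float = 2.0
    clip_enrich_halfwidth: int = 200
    clip_flank: int = 200
    jitter_sd: float = 5.0
    contaminant_frac: float = 0.1
    ip_decoy_frac: float = 0.0
    decoy_tag_frac: float = 0.25
    gene_spacing: int = 5000
    chrom: str = "simchr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes: must be >= 0")
        lo, hi = self.utr_len_range
        if lo < 20 or lo > hi:
            raise ValueError("utr_len_range: need 20 <= lo <= hi")
        plo, phi = _as_range(self.proximal_frac_range, "proximal_frac_range")
        if not (0.0 < plo <= phi < 1.0):
            raise ValueError("proximal_frac_range: bounds must lie strictly inside (0,1)")
        for name in ("f_long_ctrl", "f_long_kd"):
            flo, fhi = _as_range(getattr(self, name), name)
            if not (0.0 <= flo <= fhi <= 1.0):
                raise ValueError(f"{name}: bounds must lie in [0,1]")
        for name in ("shifted_gene_frac", "contaminant_frac", "ip_decoy_frac",
                     "decoy_tag_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}: must lie in [0,1]")
        for name in ("pa_depth", "cov_depth", "clip_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd: must be >= 0")
        if self.clip_prox_enrich < 0:
            raise ValueError("clip_prox_enrich: must be >= 0")
        if self.gene_spacing < 0:
            raise ValueError("gene_spacing: must be >= 0")

    def condition_f_long(self, row: pd.Series, condition: str) -> float:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
        return float(row[f"f_long_{condition}"])


def _draw(rng: np.random.Generator, rng_range: tuple[float, float]) -> float:
    lo, hi = rng_range
    return lo if lo == hi else float(rng.uniform(lo, hi))


def make_gene_models(config: SimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Lay out ``n_genes`` non-overlapping two-pA-site genes on one synthetic
    chromosome, alternating strands, and return (gene models, truth table)."""
    genes: list[GeneModel] = []
    rows: list[dict] = []
    offset = _LEFT_MARGIN
    fc_range = _as_range(config.f_long_ctrl, "f_long_ctrl")
    fk_range = _as_range(config.f_long_kd, "f_long_kd")

    for i in range(config.n_genes):
        rng = _rng(config.seed, _LAYOUT, i)
        lo, hi = config.utr_len_range
        utr_len = int(rng.integers(lo, hi + 1))
        frac = _draw(rng, _as_range(config.proximal_frac_range, "proximal_frac_range"))
        prox_dist = int(np.clip(round(frac * utr_len), 1, utr_len - 1))
        fc = _draw(rng, fc_range)
        is_shifted = bool(rng.random() < config.shifted_gene_frac)
        fk = _draw(rng, fk_range) if is_shifted else fc
        has_decoy = bool(rng.random() < config.ip_decoy_frac)
        decoy_dist = max(1, round(prox_dist * 0.5)) if has_decoy else -1

        strand = "+" if i % 2 == 0 else "-"
        span = _CDS_SPAN + utr_len
        tx_start, tx_end = offset, offset + span
        offset = tx_end + config.gene_spacing

        if strand == "+":
            stop_pos = tx_start + _CDS_SPAN
            exons = ((tx_start, tx_start + _CDS_EXON1),
                     (tx_start + _CDS_EXON1 + _INTRON, tx_end))
        else:
            stop_pos = tx_start + utr_len - 1
            exons = ((tx_start, tx_start + utr_len + _CDS_EXON2),
                     (tx_start + utr_len + _CDS_EXON2 + _INTRON, tx_end))

        gene = GeneModel(
            gene_id=f"g{i:05d}", chrom=config.chrom, strand=strand,
            stop_pos=stop_pos, utr_len=utr_len, exons=exons,
            tx_start=tx_start, tx_end=tx_end,
        )
        genes.append(gene)
        rows.append({
            "gene_id": gene.gene_id, "chrom": gene.chrom, "strand": strand,
            "tx_start": tx_start, "tx_end": tx_end, "stop_pos": stop_pos,
            "utr_len": utr_len, "prox_dist": prox_dist, "dist_dist": utr_len,
            "proximal_pos": gene.pos_at(prox_dist), "distal_pos": gene.pos_at(utr_len),
            "f_long_ctrl": fc, "f_long_kd": fk, "is_shifted": is_shifted,
            "decoy_dist": decoy_dist,
            "decoy_pos": gene.pos_at(decoy_dist) if has_decoy else -1,
            "true_eutr_ctrl": fc * utr_len + (1 - fc) * prox_dist,
            "true_eutr_kd": fk * utr_len + (1 - fk) * prox_dist,
        })

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return genes, truth


def chrom_sizes(truth: pd.DataFrame, config: SimConfig) -> dict[str, int]:
    if truth.empty:
        return {config.chrom: _LEFT_MARGIN + config.gene_spacing}
    return {
        chrom: int(sub["tx_end"].max()) + config.gene_spacing
        for chrom, sub in truth.groupby("chrom")
    }


def _pos_at(strand: np.ndarray | str, stop_pos, d):
    """Vectorised distance -> genomic coordinate."""
    sign = 1 if (isinstance(strand, str) and strand == "+") else -1
    return stop_pos + sign * (d - 1)


_BASE_CHARS = np.array(list("ACGT"))
_NONT_CHARS = np.array(list("ACG"))


def _tail_prefixes(rng: np.random.Generator, n: int) -> list[str]:
    suffix = _BASE_CHARS[rng.integers(0, 4, size=(n, 5))]
    return ["TTT" + "".join(s) for s in suffix]


def _contaminant_prefixes(rng: np.random.Generator, n: int) -> list[str]:
    # first base drawn from {A,C,G} so a contaminant can never pass the
    # TTT-head filter; the rest is uniform
    head = _NONT_CHARS[rng.integers(0, 3, size=n)]
    rest = _BASE_CHARS[rng.integers(0, 4, size=(n, 7))]
    return [h + "".join(r) for h, r in zip(head, rest)]


def simulate_paseq_reads(truth: pd.DataFrame, config: SimConfig,
                         condition: str) -> pd.DataFrame:
    """Simulate aligned PA-seq tag records for one condition.

    Returns a DataFrame with columns chrom, pos (cleavage coordinate of the
    true tag), aligned_strand (strand the T-headed mate maps to: antisense
    to the transcript), prefix (first bases of that mate), sample_id and
    gene_id.  Tag counts are Poisson(``pa_depth``) per gene; each true tag
    chooses the distal site with probability ``f_long``, is jittered by a
    rounded Normal(0, ``jitter_sd``) along the transcription direction and
    clipped to the UTR.  Internal-priming decoy sites (if laid out) receive
    ``decoy_tag_frac * pa_depth`` expected tags, T-headed like true tags.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    cond_idx = CONDITIONS.index(condition)
    frames: list[pd.DataFrame] = []
    for i, row in enumerate(truth.itertuples(index=False)):
        rng = _rng(config.seed, _PASEQ, i, cond_idx)
        f_long = getattr(row, f"f_long_{condition}")
        n = int(rng.poisson(config.pa_depth))
        is_long = rng.random(n) < f_long
        d = np.where(is_long, row.dist_dist, row.prox_dist).astype(np.int64)
        n_decoy = 0
        if row.decoy_dist > 0 and config.decoy_tag_frac > 0:
            n_decoy = int(rng.poisson(config.pa_depth * config.decoy_tag_frac))
            d = np.concatenate([d, np.full(n_decoy, row.decoy_dist, dtype=np.int64)])
        if config.jitter_sd > 0 and len(d):
            d = d + np.rint(rng.normal(0.0, config.jitter_sd, size=len(d))).astype(np.int64)
        d = np.clip(d, 1, row.utr_len)
        pos = _pos_at(row.strand, row.stop_pos, d)

        total = len(d)
        is_cont = rng.random(total) < config.contaminant_frac
        n_cont = int(is_cont.sum())
        prefixes = np.empty(total, dtype=object)
        prefixes[~is_cont] = _tail_prefixes(rng, total - n_cont)
        prefixes[is_cont] = _contaminant_prefixes(rng, n_cont)

        frames.append(pd.DataFrame({
            "chrom": row.chrom,
            "pos": pos,
            "aligned_strand": "-" if row.strand == "+" else "+",
            "prefix": prefixes,
            "sample_id": condition,
            "gene_id": row.gene_id,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "aligned_strand", "prefix",
                                     "sample_id", "gene_id"])
    return pd.concat(frames, ignore_index=True)


def simulate_rnaseq_coverage(truth: pd.DataFrame, config: SimConfig,
                             condition: str) -> CoverageTrack:
    """Per-base 3'UTR coverage for one condition.

    cUTR bases draw Poisson(``cov_depth``); aUTR bases draw
    Poisson(``cov_depth * f_long``), so the expected aUTR/cUTR density
    ratio — the true RUD — equals ``f_long``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    cond_idx = CONDITIONS.index(condition)
    track = CoverageTrack(chrom_sizes(truth, config))
    for i, row in enumerate(truth.itertuples(index=False)):
        rng = _rng(config.seed, _RNASEQ, i, cond_idx)
        f_long = getattr(row, f"f_long_{condition}")
        cutr = rng.poisson(config.cov_depth, size=row.prox_dist).astype(np.float64)
        autr = rng.poisson(config.cov_depth * f_long,
                           size=row.utr_len - row.prox_dist).astype(np.float64)
        if row.strand == "+":
            track.add(row.chrom, row.stop_pos, cutr)
            track.add(row.chrom, row.stop_pos + row.prox_dist, autr)
        else:
            track.add(row.chrom, row.stop_pos - row.prox_dist + 1, cutr[::-1])
            track.add(row.chrom, row.stop_pos - row.utr_len + 1, autr[::-1])
    return track


def simulate_clip_tags(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """CLIP tag 5'-end positions, one row per tag.

    Background tags fall uniformly over the 3'UTR extended by
    ``clip_flank`` nt on both sides at per-nt rate ``clip_depth/utr_len``;
    shifted genes additionally draw tags at ``(clip_prox_enrich - 1)`` times
    that rate inside +/- ``clip_enrich_halfwidth`` nt of the proximal site.
    """
    frames: list[pd.DataFrame] = []
    flank = config.clip_flank
    for i, row in enumerate(truth.itertuples(index=False)):
        rng = _rng(config.seed, _CLIP, i)
        if config.clip_depth == 0:
            continue
        lam = config.clip_depth / row.utr_len
        n_bg = int(rng.poisson(lam * (row.utr_len + 2 * flank)))
        d = rng.integers(1 - flank, row.utr_len + flank + 1, size=n_bg)
        if row.is_shifted and config.clip_prox_enrich != 1.0:
            hw = config.clip_enrich_halfwidth
            extra_rate = lam * (config.clip_prox_enrich - 1.0) * 2 * hw
            n_extra = int(rng.poisson(max(extra_rate, 0.0)))
            d_extra = rng.integers(row.prox_dist - hw, row.prox_dist + hw, size=n_extra)
            d = np.concatenate([d, d_extra])
        pos = _pos_at(row.strand, row.stop_pos, d)
        frames.append(pd.DataFrame({
            "chrom": row.chrom, "pos": pos, "strand": row.strand,
            "gene_id": row.gene_id,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "gene_id"])
    return pd.concat(frames, ignore_index=True)


def build_genome(truth: pd.DataFrame, config: SimConfig) -> ArrayGenome:
    """Synthetic genome consistent with the truth table.

    Uniform A/C/G/T background with, per true pA site, an AATAAA hexamer
    planted 10-30 nt upstream (transcript strand) and an A-depleted 10-mer
    immediately downstream (so true sites never trip the internal-priming
    filter).  Internal-priming decoy positions get a 10-nt poly(A) run
    planted downstream instead, and no signal.
    """
    genome = ArrayGenome.random(chrom_sizes(truth, config), _rng(config.seed, _GENOME))
    nont = np.array(list("CGT"))
    for i, row in enumerate(truth.itertuples(index=False)):
        rng = _rng(config.seed, _GENOME, i)
        for d_site in (row.prox_dist, row.dist_dist):
            u = int(rng.integers(10, 31))  # hexamer 3' end sits u nt upstream of the site
            hex_5p = _pos_at(row.strand, row.stop_pos, d_site - u - 5)
            genome.plant(row.chrom, hex_5p, "AATAAA", row.strand)
            # downstream 10-mer free of A (transcript strand)
            downstream = "".join(nont[rng.integers(0, 3, size=10)])
            ds_start_pos = _pos_at(row.strand, row.stop_pos, d_site + 1)
            genome.plant(row.chrom, ds_start_pos, downstream, row.strand)
        if row.decoy_dist > 0:
            ds_start_pos = _pos_at(row.strand, row.stop_pos, row.decoy_dist + 1)
            genome.plant(row.chrom, ds_start_pos, "A" * 10, row.strand)
    return genome
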