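"""Per-gene APA usage metrics and shortening/lengthening classification.

Two complementary statistics quantify a gene's 3'UTR usage:

eUTR (effective 3'UTR length)
    the tag-abundance-weighted mean distance of the gene's 3'UTR pA sites
    from the stop codon, computed from 3'-end tag counts.  It uses *all*
    sites in the UTR, weighting each by its fraction of the gene's tags.

RUD (relative usage of the distal site)
    the RNA-seq read density over the alternative UTR (proximal -> distal
    pA, present only in the long isoform) divided by the density over the
    common UTR (stop codon -> proximal pA, shared by all isoforms).  Only
    the most proximal and most distal site enter; under a two-isoform
    mixture its expectation is the long-isoform fraction.

Between-condition deltas (knockdown minus control) are classified at
effect-size cutoffs with inclusive boundaries: delta <= -c is "shortened",
delta >= +c "lengthened".  Default cutoff ladders are 50/100/200/400 nt
for eUTR and 0.05/0.1/0.2/0.3 for RUD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genome import CoverageTrack
from .models import EUTRRecord, GeneAPAProfile, GeneModel, RUDRecord, classify_delta

EUTR_CUTOFFS = (50.0, 100.0, 200.0, 400.0)
RUD_CUTOFFS = (0.05, 0.1, 0.2, 0.3)

DEFAULT_MIN_GENE_TAGS = 20
DEFAULT_MIN_CUTR_LEN = 100
DEFAULT_MIN_CUTR_READS = 30


def build_gene_profiles(clusters: pd.DataFrame, genes: list[GeneModel],
                        sample_id: str,
                        min_gene_tags: int = DEFAULT_MIN_GENE_TAGS,
                        extension: int = 0) -> dict[str, GeneAPAProfile]:
    """Collect each gene's 3'UTR pA sites into an ordered profile.

    Uses UTR3/known_pA clusters that are not internal-priming flagged and
    whose ``mode_pos`` lies within the gene's 3'UTR (optionally extended
    ``extension`` nt past the annotated terminus).  Counts come from the
    ``n_<sample_id>`` column.  Genes with fewer than ``min_gene_tags``
    total tags or a single site are omitted (no APA measurable).

    Raises if a cluster falls in the (extended) UTR of two genes.
    """
    col = f"n_{sample_id}"
    if col not in clusters.columns:
        raise ValueError(f"clusters carry no counts for sample {sample_id!r} ({col} missing)")
    trees: dict[tuple[str, str], IntervalTree] = {}
    by_id = {g.gene_id: g for g in genes}
    for g in genes:
        lo, hi = g.utr_interval
        if g.strand == "+":
            hi += extension
        else:
            lo -= extension
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(lo, hi, g.gene_id)

    eligible = clusters
    if "category" in clusters.columns:
        eligible = eligible[eligible["category"].isin(["UTR3", "known_pA"])]
    if "internal_priming" in clusters.columns:
        eligible = eligible[~eligible["internal_priming"]]

    sites: dict[str, list[tuple[int, int]]] = {}
    for row in eligible.itertuples(index=False):
        tree = trees.get((row.chrom, row.strand))
        if tree is None:
            continue
        hits = tree[row.mode_pos]
        if not hits:
            continue
        if len(hits) > 1:
            names = sorted(h.data for h in hits)
            raise ValueError(
                f"cluster at {row.chrom}:{row.mode_pos} overlaps multiple genes: {names}")
        gid = next(iter(hits)).data
        d = by_id[gid].distance_of(row.mode_pos)
        count = int(getattr(row, col))
        if d > 0 and count > 0:
            sites.setdefault(gid, []).append((d, count))

    profiles: dict[str, GeneAPAProfile] = {}
    for gid, lst in sites.items():
        merged: dict[int, int] = {}
        for d, c in lst:
            merged[d] = merged.get(d, 0) + c
        ordered = sorted(merged.items())
        prof = GeneAPAProfile(gene_id=gid, condition=sample_id, sites=ordered)
        if prof.n_sites >= 2 and prof.total_tags >= min_gene_tags:
            profiles[gid] = prof
    return profiles


def compute_eutr(profile: GeneAPAProfile) -> float:
    """Tag-abundance-weighted mean pA-site distance from the stop codon."""
    total = profile.total_tags
    if total == 0:
        raise ValueError(f"{profile.gene_id}: eUTR undefined with zero tags")
    return float(sum(d * c for d, c in profile.sites) / total)


def delta_eutr(profile_ctrl: GeneAPAProfile, profile_kd: GeneAPAProfile,
               cutoffs: tuple[float, ...] = EUTR_CUTOFFS) -> EUTRRecord:
    """eUTR difference (knockdown - control) with classes per cutoff."""
    if profile_ctrl.gene_id != profile_kd.gene_id:
        raise ValueError(
            f"gene mismatch: {profile_ctrl.gene_id} vs {profile_kd.gene_id}")
    e_ctrl = compute_eutr(profile_ctrl)
    e_kd = compute_eutr(profile_kd)
    delta = e_kd - e_ctrl
    return EUTRRecord(
        gene_id=profile_ctrl.gene_id, eutr_ctrl=e_ctrl, eutr_kd=e_kd,
        delta_eutr=delta, classes={c: classify_delta(delta, c) for c in cutoffs},
    )


@dataclass
class RUDResult:
    gene_id: str
    density_c: float
    density_a: float
    rud: float
    exclude_reason: str | None = None


def compute_rud(gene: GeneModel, proximal: int, distal: int,
                coverage: CoverageTrack,
                min_cutr_len: int = DEFAULT_MIN_CUTR_LEN,
                min_cutr_reads: float = DEFAULT_MIN_CUTR_READS) -> RUDResult:
    """Distal-usage index of one gene from per-base RNA-seq coverage.

    ``proximal``/``distal`` are genomic coordinates of the two pA sites.
    cUTR spans stop codon -> proximal site, aUTR proximal -> distal site
    (strand-aware).  Genes whose cUTR is shorter than ``min_cutr_len`` nt,
    carries less than ``min_cutr_reads`` summed coverage, or has zero
    density are excluded with a reason code instead of a value.
    """
    d_prox = gene.distance_of(proximal)
    d_dist = gene.distance_of(distal)
    if not (0 < d_prox < d_dist):
        raise ValueError(
            f"{gene.gene_id}: need stop < proximal < distal in transcription "
            f"direction (distances {d_prox}, {d_dist})")
    if d_prox < min_cutr_len:
        return RUDResult(gene.gene_id, np.nan, np.nan, np.nan, "cutr_too_short")

    def interval(d_lo: int, d_hi: int) -> tuple[int, int]:
        a, b = gene.pos_at(d_lo), gene.pos_at(d_hi)
        return (a, b + 1) if gene.strand == "+" else (b, a + 1)

    c_start, c_end = interval(1, d_prox)
    a_start, a_end = interval(d_prox + 1, d_dist)
    c_mass = coverage.total(gene.chrom, c_start, c_end)
    if c_mass < min_cutr_reads:
        return RUDResult(gene.gene_id, np.nan, np.nan, np.nan, "cutr_low_coverage")
    density_c = c_mass / (c_end - c_start)
    density_a = coverage.total(gene.chrom, a_start, a_end) / (a_end - a_start)
    if density_c == 0:
        return RUDResult(gene.gene_id, density_c, density_a, np.nan, "cutr_zero_density")
    return RUDResult(gene.gene_id, density_c, density_a, density_a / density_c)


def delta_rud(rud_ctrl: float, rud_kd: float, gene_id: str = "",
              cutoffs: tuple[float, ...] = RUD_CUTOFFS) -> RUDRecord:
    """RUD difference (knockdown - control) with classes per cutoff."""
    if not (np.isfinite(rud_ctrl) and np.isfinite(rud_kd)):
        raise ValueError(f"{gene_id}: RUD undefined in at least one condition")
    delta = rud_kd - rud_ctrl
    return RUDRecord(
        gene_id=gene_id, rud_ctrl=float(rud_ctrl), rud_kd=float(rud_kd),
        delta_rud=delta, classes={c: classify_delta(delta, c) for c in cutoffs},
    )


def two_sample_test(values_a, values_b, log2_transform: bool = False) -> tuple[float, float]:
    """Welch two-sided t-test between two value lists, optionally on log2 scale."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples contain non-finite values")
    if log2_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log2 transform requires strictly positive values")
        a, b = np.log2(a), np.log2(b)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def overlap_sets(named_sets: dict[str, set]) -> pd.DataFrame:
    """Membership-region counts for >= 2 named gene sets.

    One row per nonempty membership pattern (which sets an element belongs
    to), with the exclusive count of that region; plus one row per set with
    its total.  Percentages are relative to the union of all sets.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(named_sets)
    union = set().union(*named_sets.values())
    n_union = len(union)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set().union(*(named_sets[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            exclusive = inside - outside
            if exclusive:
                rows.append({
                    "region": "&".join(combo), "kind": "exclusive",
                    "count": len(exclusive),
                    "pct_of_union": 100.0 * len(exclusive) / n_union,
                })
    for n in names:
        rows.append({
            "region": n, "kind": "total", "count": len(named_sets[n]),
            "pct_of_union": (100.0 * len(named_sets[n]) / n_union) if n_union else 0.0,
        })
    return pd.DataFrame(rows, columns=["region", "kind", "count", "pct_of_union"])


def pairwise_overlap(set_a: set, set_b: set) -> int:
    return len(set_a & set_b)


def shortened_genes(records: list[EUTRRecord] | list[RUDRecord], cutoff: float) -> set[str]:
    """Gene ids classified "shortened" at one cutoff."""
    return {r.gene_id for r in records if r.classes.get(cutoff) == "shortened"}
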