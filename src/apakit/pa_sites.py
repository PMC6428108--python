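"""pA-site identification from aligned 3'-end tags.

The chain is: strand correction (keep only reads whose tail-proximal mate
begins with a poly(T) head), single-linkage clustering of cleavage
positions per (chromosome, strand), internal-priming flagging against the
genome, genomic annotation against gene models and an optional known-site
catalog, and poly(A)-signal classification of the upstream sequence.

Clusters are carried as a pandas DataFrame with one row per cluster and
columns::

    chrom  strand  start  end  mode_pos  n_<sample>...  total
    [internal_priming  category  signal_class]

``start``/``end`` are the half-open genomic span of the member tags and
``mode_pos`` the most-supported cleavage coordinate (ties resolved to the
most upstream position in transcription direction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import fetch_transcript_strand
from .models import GeneModel

CATEGORIES = ("known_pA", "UTR3", "exon", "intron", "intergenic")
SIGNAL_CLASSES = ("AATAAA", "ATTAAA", "other")

DEFAULT_MAX_GAP = 24
DEFAULT_MIN_CLUSTER_TAGS = 5
DEFAULT_KNOWN_TOL = 24


def strand_correct(reads: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Apply the poly(T)-head filter and flip to transcript strand.

    ``reads`` needs columns ``chrom``, ``pos``, ``aligned_strand``,
    ``prefix`` and ``sample_id``.  Exactly the records whose prefix begins
    with "TTT" (case-insensitive) are kept; their transcript strand is the
    opposite of the T-headed mate's alignment strand and ``cleavage_pos``
    is the mate's aligned position.  Returns (kept tags, number discarded).
    """
    required = {"chrom", "pos", "aligned_strand", "prefix", "sample_id"}
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"read records lack columns: {sorted(missing)}")
    if reads.empty:
        kept = pd.DataFrame(columns=["chrom", "strand", "cleavage_pos", "sample_id"])
        return kept, 0
    prefixes = reads["prefix"]
    if prefixes.isna().any():
        bad = reads.index[prefixes.isna()][0]
        raise ValueError(f"read record {bad} lacks a prefix string")
    is_tail = prefixes.str.upper().str.startswith("TTT")
    kept_reads = reads[is_tail]
    kept = pd.DataFrame({
        "chrom": kept_reads["chrom"].to_numpy(),
        "strand": np.where(kept_reads["aligned_strand"].to_numpy() == "+", "-", "+"),
        "cleavage_pos": kept_reads["pos"].to_numpy(dtype=np.int64),
        "sample_id": kept_reads["sample_id"].to_numpy(),
    })
    return kept, int((~is_tail).sum())


def _mode_position(positions: np.ndarray, strand: str) -> int:
    """Most frequent coordinate; ties go to the most upstream position
    (smallest on '+', largest on '-')."""
    vals, counts = np.unique(positions, return_counts=True)  # vals ascending
    best = counts == counts.max()
    return int(vals[best][0] if strand == "+" else vals[best][-1])


def cluster_tags(tags: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP) -> pd.DataFrame:
    """Single-linkage clustering of cleavage positions per (chrom, strand).

    Two tags belong to one cluster iff their coordinate gap is <= ``max_gap``
    transitively (the boundary is inclusive).  Per-sample tag counts are
    conserved: their grand total equals the number of input tags.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    samples = sorted(pd.unique(tags["sample_id"])) if len(tags) else []
    rows: list[dict] = []
    if len(tags):
        for (chrom, strand), sub in tags.groupby(["chrom", "strand"], sort=True):
            pos = np.sort(sub["cleavage_pos"].to_numpy(dtype=np.int64))
            breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
            bounds = np.concatenate(([0], breaks, [len(pos)]))
            # per-sample positions for counting
            by_sample = {s: g["cleavage_pos"].to_numpy(dtype=np.int64)
                         for s, g in sub.groupby("sample_id")}
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                members = pos[lo:hi]
                left, right = int(members[0]), int(members[-1])
                row = {
                    "chrom": chrom, "strand": strand,
                    "start": left, "end": right + 1,
                    "mode_pos": _mode_position(members, strand),
                }
                total = 0
                for s in samples:
                    p = by_sample.get(s)
                    c = 0 if p is None else int(((p >= left) & (p <= right)).sum())
                    row[f"n_{s}"] = c
                    total += c
                row["total"] = total
                rows.append(row)
    cols = ["chrom", "strand", "start", "end", "mode_pos"] + [f"n_{s}" for s in samples] + ["total"]
    return pd.DataFrame(rows, columns=cols)


def filter_min_tags(clusters: pd.DataFrame, min_tags: int = DEFAULT_MIN_CLUSTER_TAGS) -> pd.DataFrame:
    """Drop clusters supported by fewer than ``min_tags`` tags summed over samples."""
    if clusters.empty:
        return clusters
    return clusters[clusters["total"] >= min_tags].reset_index(drop=True)


def filter_internal_priming(clusters: pd.DataFrame, genome, window: int = 10,
                            min_a_run: int = 6, min_a_frac: float = 0.7) -> pd.DataFrame:
    """Flag clusters that look like oligo(dT) internal priming.

    The ``window``-nt genomic stretch immediately downstream of
    ``mode_pos`` in transcription direction (transcript strand) is flagged
    when it contains >= ``min_a_run`` consecutive A or >= ``min_a_frac``
    A overall.  Flagged clusters stay in the table with
    ``internal_priming=True``; downstream APA metrics exclude them.
    """
    run_probe = "A" * min_a_run
    flags = []
    for row in clusters.itertuples(index=False):
        if row.chrom not in genome:
            raise ValueError(f"cluster locus {row.chrom}:{row.mode_pos} not in genome")
        if row.strand == "+":
            start, end = row.mode_pos + 1, row.mode_pos + 1 + window
        else:
            start, end = row.mode_pos - window, row.mode_pos
        seq = fetch_transcript_strand(genome, row.chrom, start, end, row.strand).upper()
        a_frac = seq.count("A") / len(seq) if seq else 0.0
        flags.append(run_probe in seq or a_frac >= min_a_frac)
    out = clusters.copy()
    out["internal_priming"] = pd.Series(flags, dtype=bool) if flags else pd.Series([], dtype=bool)
    return out


def _build_trees(genes: list[GeneModel]):
    utr: dict[tuple[str, str], IntervalTree] = {}
    exon: dict[tuple[str, str], IntervalTree] = {}
    tx: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        key = (g.chrom, g.strand)
        lo, hi = g.utr_interval
        utr.setdefault(key, IntervalTree()).addi(lo, hi, g.gene_id)
        for s, e in g.exons:
            exon.setdefault(key, IntervalTree()).addi(s, e, g.gene_id)
        if g.tx_end > g.tx_start:
            tx.setdefault(key, IntervalTree()).addi(g.tx_start, g.tx_end, g.gene_id)
    return utr, exon, tx


def annotate_clusters(clusters: pd.DataFrame, genes: list[GeneModel],
                      known_pa: pd.DataFrame | None = None,
                      known_tol: int = DEFAULT_KNOWN_TOL) -> pd.DataFrame:
    """Assign each cluster a genomic category by fixed priority.

    Priority: known_pA (``mode_pos`` within +/- ``known_tol`` of a
    known-site coordinate on the same strand) > UTR3 (inside an annotated
    3'UTR) > exon > intron (inside the transcribed span but not exonic) >
    intergenic.  ``known_pa`` needs columns chrom, pos, strand.
    """
    known: dict[tuple[str, str], np.ndarray] = {}
    if known_pa is not None and len(known_pa):
        missing = {"chrom", "pos", "strand"} - set(known_pa.columns)
        if missing:
            raise ValueError(f"known-pA records lack columns: {sorted(missing)}")
        if known_pa["pos"].isna().any() or (known_pa["pos"] < 0).any():
            raise ValueError("known-pA records contain malformed positions")
        for (chrom, strand), sub in known_pa.groupby(["chrom", "strand"]):
            known[(chrom, strand)] = np.sort(sub["pos"].to_numpy(dtype=np.int64))
    utr_t, exon_t, tx_t = _build_trees(genes)

    cats = []
    for row in clusters.itertuples(index=False):
        key = (row.chrom, row.strand)
        pos = row.mode_pos
        sites = known.get(key)
        if sites is not None and len(sites):
            j = np.searchsorted(sites, pos)
            near = min(
                abs(pos - sites[max(j - 1, 0)]),
                abs(pos - sites[min(j, len(sites) - 1)]),
            )
            if near <= known_tol:
                cats.append("known_pA")
                continue
        if key in utr_t and utr_t[key].overlaps_point(pos):
            cats.append("UTR3")
        elif key in exon_t and exon_t[key].overlaps_point(pos):
            cats.append("exon")
        elif key in tx_t and tx_t[key].overlaps_point(pos):
            cats.append("intron")
        else:
            cats.append("intergenic")
    out = clusters.copy()
    out["category"] = pd.Series(cats, dtype=object) if cats else pd.Series([], dtype=object)
    return out


def scan_polya_signal(clusters: pd.DataFrame, genome, window: int = 40) -> pd.DataFrame:
    """Classify the poly(A) signal upstream of each cluster.

    The transcript-strand sequence in the ``window`` nt upstream of
    ``mode_pos`` (excluding the cleavage base itself) is searched for
    AATAAA first, then ATTAAA; the first hexamer found by that priority
    names the class, else "other".
    """
    if window <= 0:
        raise ValueError("window must be positive")
    classes = []
    for row in clusters.itertuples(index=False):
        if row.chrom not in genome:
            raise ValueError(f"cluster locus {row.chrom}:{row.mode_pos} not in genome")
        if row.strand == "+":
            start, end = max(row.mode_pos - window, 0), row.mode_pos
        else:
            start, end = row.mode_pos + 1, min(row.mode_pos + 1 + window,
                                               genome.chrom_size(row.chrom))
        seq = fetch_transcript_strand(genome, row.chrom, start, end, row.strand).upper()
        if "AATAAA" in seq:
            classes.append("AATAAA")
        elif "ATTAAA" in seq:
            classes.append("ATTAAA")
        else:
            classes.append("other")
    out = clusters.copy()
    out["signal_class"] = pd.Series(classes, dtype=object) if classes else pd.Series([], dtype=object)
    return out


def genomic_distribution(clusters: pd.DataFrame) -> pd.Series:
    """Fractions of clusters per category plus the canonical-signal fraction.

    Raises on empty input (fractions undefined).  The returned Series has
    the five category fractions (summing to 1) and, when a
    ``signal_class`` column is present, a ``canonical_signal`` entry: the
    fraction of clusters whose signal is AATAAA or ATTAAA.
    """
    if clusters.empty:
        raise ValueError("genomic_distribution undefined for an empty cluster set")
    if "category" not in clusters.columns:
        raise ValueError("clusters must be annotated before computing the distribution")
    n = len(clusters)
    frac = {cat: float((clusters["category"] == cat).sum()) / n for cat in CATEGORIES}
    out = pd.Series(frac)
    if "signal_class" in clusters.columns:
        out["canonical_signal"] = float(
            clusters["signal_class"].isin(["AATAAA", "ATTAAA"]).sum()) / n
    return out


def call_pa_sites(reads: pd.DataFrame, genes: list[GeneModel], genome=None,
                  known_pa: pd.DataFrame | None = None,
                  max_gap: int = DEFAULT_MAX_GAP,
                  min_tags: int = DEFAULT_MIN_CLUSTER_TAGS,
                  known_tol: int = DEFAULT_KNOWN_TOL,
                  ip_filter: bool = True,
                  signal_window: int = 40) -> tuple[pd.DataFrame, dict]:
    """Full calling chain; returns (annotated clusters, stage counts)."""
    tags, n_discarded = strand_correct(reads)
    clusters = cluster_tags(tags, max_gap=max_gap)
    n_clusters_raw = len(clusters)
    clusters = filter_min_tags(clusters, min_tags)
    if genome is not None and ip_filter:
        clusters = filter_internal_priming(clusters, genome)
    else:
        clusters = clusters.copy()
        clusters["internal_priming"] = False
    clusters = annotate_clusters(clusters, genes, known_pa, known_tol)
    if genome is not None:
        clusters = scan_polya_signal(clusters, genome, window=signal_window)
    counts = {
        "reads_in": int(len(reads)),
        "tags_kept": int(len(tags)),
        "tags_discarded": n_discarded,
        "clusters_raw": n_clusters_raw,
        "clusters_called": int(len(clusters)),
    }
    return clusters, counts
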