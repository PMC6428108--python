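"""End-to-end orchestration: simulate or load inputs, call pA sites,
compute eUTR/RUD deltas, classify shortening, compare CLIP windows, and
write a report bundle.

Every stage logs its input/output record counts and the boundary
identities are asserted (tags in = tags kept + discarded; genes in =
genes scored + genes excluded-with-reason).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as akio
from . import metrics, pa_sites
from .genome import ArrayGenome, CoverageTrack, FastaGenome
from .models import GeneModel
from .simulate import (CONDITIONS, SimConfig, build_genome, chrom_sizes,
                       make_gene_models, simulate_clip_tags,
                       simulate_paseq_reads, simulate_rnaseq_coverage)

log = logging.getLogger("apakit")


@dataclass
class RunConfig:
    """Inputs and thresholds for one end-to-end run.

    Either ``sim`` is set (inputs are generated in memory) or the path
    fields point at files on disk.  Threshold defaults are the analysis
    defaults used throughout the package.
    """

    outdir: str = "apakit_out"
    sim: SimConfig | None = None
    # file-mode inputs
    genes_path: str | None = None          # gene-model TSV
    genome_path: str | None = None         # FASTA
    known_pa_path: str | None = None       # BED6
    paseq_paths: dict[str, str] = field(default_factory=dict)   # condition -> BED6+1
    rnaseq_paths: dict[str, str] = field(default_factory=dict)  # condition -> bedGraph
    clip_path: str | None = None           # BED6
    # pA-site calling
    max_gap: int = pa_sites.DEFAULT_MAX_GAP
    min_cluster_tags: int = pa_sites.DEFAULT_MIN_CLUSTER_TAGS
    known_tol: int = pa_sites.DEFAULT_KNOWN_TOL
    ip_filter: bool = True
    signal_window: int = 40
    # APA metrics
    min_gene_tags: int = metrics.DEFAULT_MIN_GENE_TAGS
    min_cutr_len: int = metrics.DEFAULT_MIN_CUTR_LEN
    min_cutr_reads: float = metrics.DEFAULT_MIN_CUTR_READS
    eutr_cutoffs: tuple[float, ...] = metrics.EUTR_CUTOFFS
    rud_cutoffs: tuple[float, ...] = metrics.RUD_CUTOFFS
    # CLIP
    half_widths: tuple[int, ...] = (100, 200)
    plot: bool = False

    def validate(self) -> None:
        for name in ("eutr_cutoffs", "rud_cutoffs", "half_widths"):
            vals = getattr(self, name)
            if not vals or any(v <= 0 for v in vals):
                raise ValueError(f"{name}: must be a nonempty list of positive values")
        if self.sim is None:
            paths = {"genes_path": self.genes_path}
            paths.update({f"paseq[{c}]": p for c, p in self.paseq_paths.items()})
            paths.update({f"rnaseq[{c}]": p for c, p in self.rnaseq_paths.items()})
            for label, p in (("genome_path", self.genome_path),
                             ("known_pa_path", self.known_pa_path),
                             ("clip_path", self.clip_path)):
                if p is not None:
                    paths[label] = p
            if self.genes_path is None or not self.paseq_paths:
                raise ValueError("file mode requires genes_path and paseq_paths")
            for label, p in paths.items():
                if p is None or not os.path.exists(p):
                    raise ValueError(f"{label}: input path missing or does not exist: {p}")


@dataclass
class ReportBundle:
    category_table: pd.Series
    summary: pd.DataFrame            # per-condition medians + Welch p-values
    class_counts: pd.DataFrame       # shortened/lengthened counts per cutoff
    overlap_table: pd.DataFrame
    clip_table: pd.DataFrame
    gene_table: pd.DataFrame         # per-gene eUTR/RUD values and classes
    clusters: pd.DataFrame
    stage_counts: dict


def _load_inputs(cfg: RunConfig):
    if cfg.sim is not None:
        sim = cfg.sim
        genes, truth = make_gene_models(sim)
        genome = build_genome(truth, sim)
        reads = pd.concat(
            [simulate_paseq_reads(truth, sim, c) for c in CONDITIONS],
            ignore_index=True)
        coverage = {c: simulate_rnaseq_coverage(truth, sim, c) for c in CONDITIONS}
        clip_tags = simulate_clip_tags(truth, sim)
        known_pa = akio.known_pa_from_truth(truth)
        return genes, genome, reads, coverage, clip_tags, known_pa
    genes = akio.read_gene_tsv(cfg.genes_path)
    genome = FastaGenome(cfg.genome_path) if cfg.genome_path else None
    reads = pd.concat(
        [akio.read_paseq_bed(p, sample_id=c) for c, p in cfg.paseq_paths.items()],
        ignore_index=True)
    coverage = {c: CoverageTrack.read_bedgraph(p) for c, p in cfg.rnaseq_paths.items()}
    clip_tags = None
    if cfg.clip_path:
        pts = akio.read_point_bed(cfg.clip_path)
        clip_tags = pts.rename(columns={"name": "gene_id"})
    known_pa = akio.read_point_bed(cfg.known_pa_path) if cfg.known_pa_path else None
    return genes, genome, reads, coverage, clip_tags, known_pa


def run_end_to_end(cfg: RunConfig) -> ReportBundle:
    cfg.validate()
    genes, genome, reads, coverage, clip_tags, known_pa = _load_inputs(cfg)
    conditions = sorted(pd.unique(reads["sample_id"]))
    log.info("inputs: %d genes, %d PA-seq reads, conditions %s",
             len(genes), len(reads), conditions)

    clusters, counts = pa_sites.call_pa_sites(
        reads, genes, genome=genome, known_pa=known_pa,
        max_gap=cfg.max_gap, min_tags=cfg.min_cluster_tags,
        known_tol=cfg.known_tol, ip_filter=cfg.ip_filter,
        signal_window=cfg.signal_window)
    assert counts["tags_kept"] + counts["tags_discarded"] == counts["reads_in"], \
        "stage pa_site_calling: tag conservation violated"
    log.info("pA calling: %(reads_in)d reads -> %(tags_kept)d tags kept, "
             "%(tags_discarded)d discarded, %(clusters_called)d clusters", counts)

    category_table = pa_sites.genomic_distribution(clusters) if len(clusters) else pd.Series(dtype=float)

    # site-matched profiles: cluster boundaries are shared across samples
    profiles = {c: metrics.build_gene_profiles(
        clusters, genes, c, min_gene_tags=cfg.min_gene_tags) for c in conditions}

    eutr_records = []
    if len(conditions) == 2:
        c0, c1 = conditions[0], conditions[1]
        if "ctrl" in conditions:  # knockdown - control orientation when known
            c0 = "ctrl"
            c1 = next(c for c in conditions if c != "ctrl")
        for gid in sorted(set(profiles[c0]) & set(profiles[c1])):
            eutr_records.append(metrics.delta_eutr(
                profiles[c0][gid], profiles[c1][gid], cutoffs=cfg.eutr_cutoffs))

    # proximal/distal site per gene from the pooled profile
    pooled = clusters.assign(n_pooled=clusters["total"]) if len(clusters) else clusters
    site_rows = []
    by_id = {g.gene_id: g for g in genes}
    if len(clusters):
        pooled_profiles = metrics.build_gene_profiles(
            pooled, genes, "pooled", min_gene_tags=cfg.min_gene_tags)
        for gid, prof in sorted(pooled_profiles.items()):
            g = by_id[gid]
            site_rows.append({
                "gene_id": gid, "chrom": g.chrom, "strand": g.strand,
                "proximal_pos": g.pos_at(prof.sites[0][0]),
                "distal_pos": g.pos_at(prof.sites[-1][0]),
            })
    sites_df = pd.DataFrame(site_rows, columns=["gene_id", "chrom", "strand",
                                                "proximal_pos", "distal_pos"])

    rud_records = []
    n_rud_excluded = 0
    if coverage and len(conditions) == 2 and len(sites_df):
        cov0, cov1 = coverage[c0], coverage[c1]
        for row in sites_df.itertuples(index=False):
            g = by_id[row.gene_id]
            r0 = metrics.compute_rud(g, row.proximal_pos, row.distal_pos, cov0,
                                     cfg.min_cutr_len, cfg.min_cutr_reads)
            r1 = metrics.compute_rud(g, row.proximal_pos, row.distal_pos, cov1,
                                     cfg.min_cutr_len, cfg.min_cutr_reads)
            if r0.exclude_reason or r1.exclude_reason:
                n_rud_excluded += 1
                continue
            rud_records.append(metrics.delta_rud(
                r0.rud, r1.rud, gene_id=row.gene_id, cutoffs=cfg.rud_cutoffs))
        assert len(rud_records) + n_rud_excluded == len(sites_df), \
            "stage apa_metrics: RUD gene accounting violated"
    counts["genes_eutr"] = len(eutr_records)
    counts["genes_rud"] = len(rud_records)
    counts["genes_rud_excluded"] = n_rud_excluded
    log.info("metrics: %d genes with eUTR deltas, %d with RUD deltas "
             "(%d excluded)", len(eutr_records), len(rud_records), n_rud_excluded)

    # global summaries
    summary_rows = []
    if eutr_records:
        e0 = [r.eutr_ctrl for r in eutr_records]
        e1 = [r.eutr_kd for r in eutr_records]
        t, p = metrics.two_sample_test(e0, e1, log2_transform=True)
        summary_rows.append({"metric": "eutr", "median_ctrl": float(np.median(e0)),
                             "median_kd": float(np.median(e1)), "welch_t": t, "welch_p": p})
    if rud_records:
        r0 = [r.rud_ctrl for r in rud_records]
        r1 = [r.rud_kd for r in rud_records]
        t, p = metrics.two_sample_test(r0, r1)
        summary_rows.append({"metric": "rud", "median_ctrl": float(np.median(r0)),
                             "median_kd": float(np.median(r1)), "welch_t": t, "welch_p": p})
    summary = pd.DataFrame(summary_rows,
                           columns=["metric", "median_ctrl", "median_kd",
                                    "welch_t", "welch_p"])

    # classification counts per cutoff
    count_rows = []
    for name, records, cutoffs in (("eutr", eutr_records, cfg.eutr_cutoffs),
                                   ("rud", rud_records, cfg.rud_cutoffs)):
        for c in cutoffs:
            shortened = sum(r.classes[c] == "shortened" for r in records)
            lengthened = sum(r.classes[c] == "lengthened" for r in records)
            count_rows.append({"metric": name, "cutoff": c, "shortened": shortened,
                               "lengthened": lengthened,
                               "unchanged": len(records) - shortened - lengthened})
    class_counts = pd.DataFrame(count_rows, columns=["metric", "cutoff", "shortened",
                                                     "lengthened", "unchanged"])

    # cross-method overlap of shortened genes at the base cutoffs
    overlap_table = pd.DataFrame(columns=["region", "kind", "count", "pct_of_union"])
    if eutr_records and rud_records:
        sets = {
            f"eutr_short_{cfg.eutr_cutoffs[0]:g}":
                metrics.shortened_genes(eutr_records, cfg.eutr_cutoffs[0]),
            f"rud_short_{cfg.rud_cutoffs[0]:g}":
                metrics.shortened_genes(rud_records, cfg.rud_cutoffs[0]),
        }
        if all(sets.values()):
            overlap_table = metrics.overlap_sets(sets)

    # CLIP windows around pA sites of shortened genes
    clip_rows = []
    if clip_tags is not None and len(clip_tags) and rud_records and len(sites_df):
        short_ids = metrics.shortened_genes(rud_records, cfg.rud_cutoffs[0])
        short_sites = sites_df[sites_df["gene_id"].isin(short_ids)]
        if len(short_sites):
            from . import clip as clipmod
            table = clipmod.window_table(clip_tags, short_sites,
                                         half_widths=cfg.half_widths)
            for hw in cfg.half_widths:
                try:
                    cmp_ = clipmod.compare_proximal_distal(table, hw)
                except ValueError:
                    continue
                clip_rows.append({"half_width": hw, "n_pairs": cmp_.n_pairs,
                                  "median_prox_rpm": cmp_.median_prox,
                                  "median_dist_rpm": cmp_.median_dist,
                                  "wilcoxon_p": cmp_.wilcoxon_p,
                                  "ttest_p": cmp_.ttest_p})
    clip_table = pd.DataFrame(clip_rows, columns=["half_width", "n_pairs",
                                                  "median_prox_rpm", "median_dist_rpm",
                                                  "wilcoxon_p", "ttest_p"])

    gene_table = _gene_table(eutr_records, rud_records, cfg)
    return ReportBundle(category_table=category_table, summary=summary,
                        class_counts=class_counts, overlap_table=overlap_table,
                        clip_table=clip_table, gene_table=gene_table,
                        clusters=clusters, stage_counts=counts)


def _gene_table(eutr_records, rud_records, cfg: RunConfig) -> pd.DataFrame:
    e = {r.gene_id: r for r in eutr_records}
    r_ = {r.gene_id: r for r in rud_records}
    rows = []
    for gid in sorted(set(e) | set(r_)):
        row: dict = {"gene_id": gid}
        if gid in e:
            row.update(eutr_ctrl=e[gid].eutr_ctrl, eutr_kd=e[gid].eutr_kd,
                       delta_eutr=e[gid].delta_eutr)
            for c in cfg.eutr_cutoffs:
                row[f"eutr_class_{c:g}"] = e[gid].classes[c]
        if gid in r_:
            row.update(rud_ctrl=r_[gid].rud_ctrl, rud_kd=r_[gid].rud_kd,
                       delta_rud=r_[gid].delta_rud)
            for c in cfg.rud_cutoffs:
                row[f"rud_class_{c:g}"] = r_[gid].classes[c]
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(bundle: ReportBundle, outdir: str, plot: bool = False) -> str:
    """Write report tables as TSV plus a markdown summary; returns the
    summary path."""
    os.makedirs(outdir, exist_ok=True)
    bundle.clusters.to_csv(os.path.join(outdir, "clusters.tsv"), sep="\t", index=False)
    bundle.gene_table.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    bundle.summary.to_csv(os.path.join(outdir, "summary.tsv"), sep="\t", index=False)
    bundle.class_counts.to_csv(os.path.join(outdir, "class_counts.tsv"), sep="\t", index=False)
    bundle.overlap_table.to_csv(os.path.join(outdir, "overlaps.tsv"), sep="\t", index=False)
    bundle.clip_table.to_csv(os.path.join(outdir, "clip_windows.tsv"), sep="\t", index=False)

    lines = ["# APA analysis report", ""]
    lines += ["## pA-site genomic distribution", ""]
    if len(bundle.category_table):
        for k, v in bundle.category_table.items():
            lines.append(f"- {k}: {v:.4f}")
    else:
        lines.append("- no clusters called")
    lines += ["", "## Global 3'UTR usage (per-condition medians, Welch test)", ""]
    lines.append(bundle.summary.to_string(index=False) if len(bundle.summary)
                 else "no genes scored")
    lines += ["", "## Shortened / lengthened gene counts per cutoff", ""]
    lines.append(bundle.class_counts.to_string(index=False) if len(bundle.class_counts)
                 else "no classifications")
    lines += ["", "## Cross-method overlap of shortened genes", ""]
    lines.append(bundle.overlap_table.to_string(index=False) if len(bundle.overlap_table)
                 else "no overlap computed")
    lines += ["", "## CLIP density around proximal vs distal pA sites", ""]
    lines.append(bundle.clip_table.to_string(index=False) if len(bundle.clip_table)
                 else "no CLIP comparison computed")
    lines += ["", "## Stage record counts", ""]
    for k, v in bundle.stage_counts.items():
        lines.append(f"- {k}: {v}")
    path = os.path.join(outdir, "report.md")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    if plot:
        _plot(bundle, outdir)
    return path


def _plot(bundle: ReportBundle, outdir: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gt = bundle.gene_table
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    if {"eutr_ctrl", "eutr_kd"}.issubset(gt.columns):
        axes[0].boxplot([np.log2(gt["eutr_ctrl"].dropna()),
                         np.log2(gt["eutr_kd"].dropna())],
                        tick_labels=["ctrl", "kd"])
        axes[0].set_ylabel("log2 eUTR (nt)")
    if {"rud_ctrl", "rud_kd"}.issubset(gt.columns):
        axes[1].boxplot([gt["rud_ctrl"].dropna(), gt["rud_kd"].dropna()],
                        tick_labels=["ctrl", "kd"])
        axes[1].set_ylabel("RUD")
    fig.tight_layout()
    fig.savefig(os.path.join(outdir, "boxplots.png"), dpi=120)
    plt.close(fig)


def simulate_to_dir(sim: SimConfig, outdir: str) -> dict[str, str]:
    """Materialise a full simulated study on disk; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    genes, truth = make_gene_models(sim)
    genome = build_genome(truth, sim)
    paths = {
        "genes_tsv": os.path.join(outdir, "genes.tsv"),
        "gtf": os.path.join(outdir, "genes.gtf"),
        "genome": os.path.join(outdir, "genome.fa"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "known_pa": os.path.join(outdir, "known_pa.bed"),
        "clip": os.path.join(outdir, "clip.bed"),
    }
    akio.write_gene_tsv(genes, paths["genes_tsv"])
    akio.write_gtf(genes, paths["gtf"])
    genome.write_fasta(paths["genome"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    akio.write_point_bed(akio.known_pa_from_truth(truth), paths["known_pa"])
    akio.write_point_bed(simulate_clip_tags(truth, sim), paths["clip"])
    for c in CONDITIONS:
        p_bed = os.path.join(outdir, f"paseq_{c}.bed")
        p_bg = os.path.join(outdir, f"rnaseq_{c}.bedgraph")
        akio.write_paseq_bed(simulate_paseq_reads(truth, sim, c), p_bed)
        simulate_rnaseq_coverage(truth, sim, c).write_bedgraph(p_bg)
        paths[f"paseq_{c}"] = p_bed
        paths[f"rnaseq_{c}"] = p_bg
    return paths
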