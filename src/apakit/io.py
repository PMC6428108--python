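"""Readers and writers for the interchange formats.

Internal coordinates are 0-based half-open throughout; GTF is converted to
1-based inclusive on write and back on read (via gffutils).  BED-like
tables go through pandas.
"""

from __future__ import annotations

import gffutils
import pandas as pd

from .models import GeneModel

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

GENE_TSV_COLUMNS = ["gene_id", "chrom", "strand", "stop_pos", "utr_len",
                    "tx_start", "tx_end", "exons"]


# -- gene models -----------------------------------------------------------

def write_gene_tsv(genes: list[GeneModel], path: str) -> None:
    rows = [{
        "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
        "stop_pos": g.stop_pos, "utr_len": g.utr_len,
        "tx_start": g.tx_start, "tx_end": g.tx_end,
        "exons": ";".join(f"{s}-{e}" for s, e in g.exons),
    } for g in genes]
    pd.DataFrame(rows, columns=GENE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_tsv(path: str) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"exons": str}, keep_default_na=False)
    genes = []
    for row in df.itertuples(index=False):
        exons = tuple(
            tuple(int(x) for x in part.split("-"))
            for part in str(row.exons).split(";") if part
        )
        genes.append(GeneModel(
            gene_id=str(row.gene_id), chrom=str(row.chrom), strand=row.strand,
            stop_pos=int(row.stop_pos), utr_len=int(row.utr_len),
            exons=exons, tx_start=int(row.tx_start), tx_end=int(row.tx_end),
        ))
    return genes


def write_gtf(genes: list[GeneModel], path: str, source: str = "apakit") -> None:
    """gene/exon/CDS features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write("\t".join([
                g.chrom, source, "gene", str(g.tx_start + 1), str(g.tx_end),
                ".", g.strand, ".", attrs]) + "\n")
            utr_lo, utr_hi = g.utr_interval
            for s, e in g.exons:
                fh.write("\t".join([
                    g.chrom, source, "exon", str(s + 1), str(e),
                    ".", g.strand, ".", attrs]) + "\n")
                # CDS = exonic minus the 3'UTR
                cs, ce = s, e
                if g.strand == "+":
                    ce = min(ce, utr_lo)
                else:
                    cs = max(cs, utr_hi)
                if ce > cs:
                    fh.write("\t".join([
                        g.chrom, source, "CDS", str(cs + 1), str(ce),
                        ".", g.strand, "0", attrs]) + "\n")


def read_gtf(path: str) -> list[GeneModel]:
    """Reconstruct gene models from a GTF with gene/exon/CDS features.

    The 3'UTR is inferred as the exonic region downstream (transcription
    direction) of the CDS end.
    """
    db = gffutils.create_db(path, ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique",
                            disable_infer_genes=True, disable_infer_transcripts=True)
    genes = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes["gene_id"][0]
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="exon"))
        cds = [(f.start - 1, f.end) for f in db.children(gene, featuretype="CDS")]
        if not cds or not exons:
            raise ValueError(f"gene {gid}: GTF lacks exon/CDS features")
        if gene.strand == "+":
            cds_end = max(e for _, e in cds)     # half-open end of CDS
            stop_pos = cds_end                    # first UTR base
            utr_len = exons[-1][1] - cds_end
        else:
            cds_end = min(s for s, _ in cds)
            stop_pos = cds_end - 1
            utr_len = cds_end - exons[0][0]
        genes.append(GeneModel(
            gene_id=gid, chrom=gene.seqid, strand=gene.strand,
            stop_pos=stop_pos, utr_len=utr_len, exons=tuple(exons),
            tx_start=gene.start - 1, tx_end=gene.end,
        ))
    return genes


# -- tag records -----------------------------------------------------------

def write_paseq_bed(reads: pd.DataFrame, path: str) -> None:
    """BED6+1: standard BED6 plus the read-prefix column."""
    df = pd.DataFrame({
        "chrom": reads["chrom"], "start": reads["pos"], "end": reads["pos"] + 1,
        "name": [f"tag{i}" for i in range(len(reads))], "score": 0,
        "strand": reads["aligned_strand"], "prefix": reads["prefix"],
    })
    df.to_csv(path, sep="\t", index=False, header=False)


def read_paseq_bed(path: str, sample_id: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=BED6_COLUMNS + ["prefix"],
                     dtype={"chrom": str, "prefix": str})
    return pd.DataFrame({
        "chrom": df["chrom"], "pos": df["start"],
        "aligned_strand": df["strand"], "prefix": df["prefix"],
        "sample_id": sample_id,
    })


def write_point_bed(df: pd.DataFrame, path: str, name_col: str | None = "gene_id") -> None:
    """Single-base BED6 records from a table with chrom/pos/strand columns."""
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["pos"], "end": df["pos"] + 1,
        "name": df[name_col] if name_col and name_col in df.columns else ".",
        "score": 0, "strand": df["strand"],
    })
    out.to_csv(path, sep="\t", index=False, header=False)


def read_point_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=BED6_COLUMNS, dtype={"chrom": str})
    return pd.DataFrame({"chrom": df["chrom"], "pos": df["start"],
                         "strand": df["strand"], "name": df["name"]})


def known_pa_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Known-pA-site catalog (chrom, pos, strand) from a simulator truth table."""
    rows = []
    for row in truth.itertuples(index=False):
        for pos in (row.proximal_pos, row.distal_pos):
            rows.append({"chrom": row.chrom, "pos": int(pos), "strand": row.strand,
                         "gene_id": row.gene_id})
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "gene_id"])


# -- cluster tables --------------------------------------------------------

def write_clusters(clusters: pd.DataFrame, path: str) -> None:
    clusters.to_csv(path, sep="\t", index=False)


def read_clusters(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
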