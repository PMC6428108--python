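"""Compare RNA-binding-protein CLIP-tag density around proximal vs distal
pA sites of shortened genes.

If a factor normally represses the proximal site, its binding (CLIP tags)
should concentrate near proximal sites of the genes that shorten when it
is depleted.  Tag counts in symmetric windows are RPM-normalised and
compared gene-by-gene with a paired Wilcoxon signed-rank test.
"""

import apakit as ak

cfg = ak.SimConfig(n_genes=200, shifted_gene_frac=1.0,
                   clip_prox_enrich=2.0, clip_depth=50, seed=11)
_, truth = ak.make_gene_models(cfg)
tags = ak.simulate_clip_tags(truth, cfg)
sites = truth[["gene_id", "chrom", "strand", "proximal_pos", "distal_pos"]]

table = ak.window_table(tags, sites, half_widths=(100, 200))
for hw in (100, 200):
    out = ak.compare_proximal_distal(table, hw)
    print(f"window +/-{hw} nt: n = {out.n_pairs} genes, "
          f"median RPM proximal = {out.median_prox:.1f}, "
          f"distal = {out.median_dist:.1f}, "
          f"Wilcoxon p = {out.wilcoxon_p:.2e} (paired t p = {out.ttest_p:.2e})")

print("\nThe simulator planted a 2-fold tag-rate enrichment within 200 nt of "
      "proximal sites, so proximal RPM should be about twice distal RPM and "
      "both tests should reject decisively.")
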