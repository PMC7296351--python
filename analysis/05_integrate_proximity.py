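#!/usr/bin/env python
"""Link DHS sets to gene groups by TSS proximity and overlap ChIP peaks.

Measures the fraction of stimulation-specific (TAg) group genes within
50 kb of the nearest tolerized-specific DHS, its distance-bin
distribution, a label-permutation enrichment p-value over the expressed
universe, and the Venn overlap of the iDHS set with the ChIP-like peak
set.

Reads results/run/ (dhs_sets.json, gene_groups.json, genes.tsv, ...);
writes integration.json.
"""
import argparse
from pathlib import Path

from chromaprime import io as cio
from chromaprime.expression import expressed_universe
from chromaprime.linkage import (
    distance_bins,
    fraction_within,
    overlap_venn,
    permutation_enrichment,
)

ap = argparse.ArgumentParser()
ap.add_argument("--rundir", type=Path, default=Path("results/run"))
ap.add_argument("--seed", type=int, default=8)
args = ap.parse_args()
rd = args.rundir

genes = cio.read_gene_table(rd / "genes.tsv")
sizes = cio.read_json(rd / "chrom_sizes.json")
peaks = {p.peak_id: p for p in cio.read_bed(rd / "peaks.bed", with_summits=True)}
sets = cio.read_json(rd / "dhs_sets.json")
groups = cio.read_json(rd / "gene_groups.json")
chip = cio.read_bed(rd / "chip_peaks.bed", chrom_sizes=sizes)

uni = expressed_universe(genes)
by_id = {g.gene_id: g for g in uni}
tag_genes = [by_id[g] for g in groups["TAg_specific"] if g in by_id]
tdhs = [peaks[i] for i in sets["tdhs"]]

frac = fraction_within(tag_genes, tdhs, 50000)
bins = distance_bins(tag_genes, tdhs, [10000, 50000, 100000])
perm = permutation_enrichment(tag_genes, tdhs, uni, 50000, n_perm=1000, seed=args.seed)
venn = overlap_venn([peaks[i].interval for i in sets["tag_idhs"]], chip,
                    name_a="TAg_iDHS", name_b="ChIP")

cio.write_json(rd / "integration.json", {
    "fraction_tag_within_50kb": frac,
    "distance_bins": bins,
    "permutation": perm,
    "venn": {"a_only": venn.a_only, "b_only": venn.b_only,
             "both_a": venn.both_a, "both_b": venn.both_b},
})
print(f"{100*frac:.1f}% of {len(tag_genes)} TAg-specific genes lie within 50 kb "
      f"of a tDHS (universe null {100*perm['null_mean_fraction']:.1f}%, "
      f"permutation p = {perm['p_value']:.4g})")
print("distance bins:", {k: round(v, 3) for k, v in bins.items()})
print(f"Venn iDHS vs ChIP: both {venn.both_a}, iDHS-only {venn.a_only}, "
      f"ChIP-only {venn.b_only}")
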