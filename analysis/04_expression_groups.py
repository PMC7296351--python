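#!/usr/bin/env python
"""Define the expressed gene universe and condition-specific gene groups.

Universe: mean expression >= 3 in at least one condition. Groups:
2-fold up with min count 50 between resting conditions (T0/N0
specific); between stimulated conditions with the additional 2-fold
inducibility requirement (TAg/NAg specific); and the 10-fold
high-variation set over the four condition ratios.

Reads results/run/genes.tsv; writes gene_groups.json.
"""
import argparse
from pathlib import Path

from chromaprime import io as cio
from chromaprime.expression import (
    condition_specific_genes,
    expressed_universe,
    high_variation_set,
    inducible_specific_genes,
)

ap = argparse.ArgumentParser()
ap.add_argument("--rundir", type=Path, default=Path("results/run"))
args = ap.parse_args()

genes = cio.read_gene_table(args.rundir / "genes.tsv")
uni = expressed_universe(genes)
groups = {
    "T0_specific": condition_specific_genes(uni, "T_0", "N_0").members,
    "N0_specific": condition_specific_genes(uni, "N_0", "T_0").members,
    "TAg_specific": inducible_specific_genes(uni, "T_Ag", "N_Ag", "T_0").members,
    "NAg_specific": inducible_specific_genes(uni, "N_Ag", "T_Ag", "N_0").members,
    "high_variation": high_variation_set(
        uni, [("T_0", "N_0"), ("T_Ag", "N_Ag"), ("T_Ag", "T_0"), ("N_Ag", "N_0")]
    ).members,
}
cio.write_json(args.rundir / "gene_groups.json",
               {k: sorted(v) for k, v in groups.items()})
print(f"universe: {len(uni)} of {len(genes)} genes")
for k, v in groups.items():
    print(f"  {k}: {len(v)} genes")
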