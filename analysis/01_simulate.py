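#!/usr/bin/env python
"""Generate the synthetic study bundle.

Emits a 20,000-peak toy genome with planted tolerized-/naive-specific
and inducible DHSs, a 1,000-gene table with planted expression groups
and DHS-gene proximity links, repeat and ChIP-like interval sets, and a
footprint-bearing cut track — everything the later stages consume, plus
the ground truth they are scored against.

Output: results/run/ (peaks.bed, counts.tsv, genes.tsv, truth.json, ...)
"""
import argparse
from pathlib import Path

from chromaprime.pipeline import write_bundle
from chromaprime.simulate import SimulationParams, simulate

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=7)
ap.add_argument("--outdir", type=Path, default=Path("results/run"))
args = ap.parse_args()

bundle = simulate(SimulationParams(seed=args.seed))
args.outdir.mkdir(parents=True, exist_ok=True)
write_bundle(bundle, args.outdir)

n_a = sum(1 for c in bundle.truth.peak_class.values() if c == "A_specific")
n_b = sum(1 for c in bundle.truth.peak_class.values() if c == "B_specific")
n_ind = sum(bundle.truth.peak_inducible.values())
n_link = sum(1 for v in bundle.truth.gene_link.values() if v is not None)
print(f"wrote {args.outdir}: {len(bundle.peaks)} peaks "
      f"({n_a} T-specific, {n_b} N-specific planted, {n_ind} inducible), "
      f"{len(bundle.genes)} genes ({n_link} with planted DHS links), "
      f"{len(bundle.profile_peaks)} profile DHSs")
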