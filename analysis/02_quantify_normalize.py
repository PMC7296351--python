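#!/usr/bin/env python
"""Normalize the peak count matrix by the top-N-median correction factor.

Reads results/run/counts.tsv, computes per-sample correction factors
(geometric-mean reference over the medians of the strongest ~36% of
peaks), and writes the factors and the normalized matrix. After
normalization every sample's top-N median equals the reference, so
fold changes between samples are depth-free.
"""
import argparse
from pathlib import Path

from chromaprime import io as cio
from chromaprime.quantify import correction_factors, normalize, scaled_top_n, top_n_median

ap = argparse.ArgumentParser()
ap.add_argument("--rundir", type=Path, default=Path("results/run"))
args = ap.parse_args()

counts = cio.read_matrix(args.rundir / "counts.tsv")
top_n = scaled_top_n(len(counts))
nf = correction_factors(counts, top_n)
normed = normalize(counts, nf)
cio.write_json(args.rundir / "factors.json",
               {s: nf.factors[s] for s in sorted(nf.factors)})
cio.write_matrix(args.rundir / "normed.tsv", normed.round(4))

print(f"top-N = {top_n} of {len(counts)} peaks; reference median = {nf.reference_median:.2f}")
for s in sorted(nf.factors):
    med = top_n_median(normed[s].to_numpy(), top_n)
    print(f"  {s}: factor {nf.factors[s]:.4f} -> post-norm top-N median {med:.2f}")
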