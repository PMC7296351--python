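#!/usr/bin/env python
"""Classify differential and inducible DHSs and score recovery.

Resting comparison (T_0 vs N_0, >= 2-fold in both replicates) yields
the tolerized-specific (tDHS) and naive-specific sets; the stimulated
comparison plus the >= 3-fold inducibility filter yields the iDHS sets.
An overdispersed count-rate test with BH correction cross-checks the
fold-change calls. Prints recovery against the planted truth.

Reads results/run/ (normed.tsv, counts.tsv, truth.json, repeats.bed).
Writes dhs_sets.json and labels.tsv.
"""
import argparse
from pathlib import Path

import numpy as np

from chromaprime import io as cio
from chromaprime.classify import classify_specific, count_rate_test, exclude_repeats, inducible_filter

ap = argparse.ArgumentParser()
ap.add_argument("--rundir", type=Path, default=Path("results/run"))
args = ap.parse_args()
rd = args.rundir

normed = cio.read_matrix(rd / "normed.tsv")
counts = cio.read_matrix(rd / "counts.tsv")
truth = cio.read_json(rd / "truth.json")
sizes = cio.read_json(rd / "chrom_sizes.json")
peaks = cio.read_bed(rd / "peaks.bed", with_summits=True)
repeats = cio.read_bed(rd / "repeats.bed", chrom_sizes=sizes)
factors = cio.read_json(rd / "factors.json")

kept = exclude_repeats(peaks, repeats)
nm = normed.loc[[p.peak_id for p in kept]]
print(f"{len(peaks)} peaks, {len(kept)} after repeat exclusion")

lab = classify_specific(nm["T_0_rep1"], nm["T_0_rep2"], nm["N_0_rep1"], nm["N_0_rep2"])
tdhs = sorted(lab.index[lab.label == "A_specific"])
ndhs = sorted(lab.index[lab.label == "B_specific"])

ag = classify_specific(nm["T_Ag_rep1"], nm["T_Ag_rep2"], nm["N_Ag_rep1"], nm["N_Ag_rep2"])
tag_spec = sorted(ag.index[ag.label == "A_specific"])
nag_spec = sorted(ag.index[ag.label == "B_specific"])
tag_idhs = sorted(inducible_filter(tag_spec, nm[["T_Ag_rep1", "T_Ag_rep2"]].mean(axis=1),
                                   nm[["T_0_rep1", "T_0_rep2"]].mean(axis=1)))
nag_idhs = sorted(inducible_filter(nag_spec, nm[["N_Ag_rep1", "N_Ag_rep2"]].mean(axis=1),
                                   nm[["N_0_rep1", "N_0_rep2"]].mean(axis=1)))

t_reps, n_reps = ["T_0_rep1", "T_0_rep2"], ["N_0_rep1", "N_0_rep2"]
test = count_rate_test(
    counts.loc[nm.index, t_reps], counts.loc[nm.index, n_reps],
    size_factorsA=1.0 / np.array([factors[s] for s in t_reps]),
    size_factorsB=1.0 / np.array([factors[s] for s in n_reps]),
)
spec = lab.index[lab.label != "shared"]
concord = (test.loc[spec, "qvalue"] < 0.05).mean()

out = lab.copy()
out["qvalue_rest"] = test["qvalue"]
out.round(5).to_csv(rd / "labels.tsv", sep="\t", index_label="peak_id")
cio.write_json(rd / "dhs_sets.json", {"tdhs": tdhs, "ndhs": ndhs,
                                      "tag_idhs": tag_idhs, "nag_idhs": nag_idhs})

true_a = {p for p, c in truth["peak_class"].items() if c == "A_specific"}
tp = len(set(tdhs) & true_a)
print(f"tDHS: {len(tdhs)} called, sensitivity {tp/len(true_a):.3f}, "
      f"FDP {(len(tdhs)-tp)/max(1,len(tdhs)):.3f}")
print(f"nDHS: {len(ndhs)}; T_Ag iDHS: {len(tag_idhs)}; N_Ag iDHS: {len(nag_idhs)}")
print(f"fold-change vs rate-test concordance on specific DHSs: {100*concord:.1f}%")
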