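"""End-to-end orchestration: simulate → quantify/normalize → classify →
expression groups → integrate → profiles/footprints → report.

Stage outputs are plain files under the output directory with a JSON
manifest keyed by the config hash; a rerun with matching hash resumes
from existing outputs, a mismatching hash is an error. Wall-times are
appended to ``run.log`` (kept out of the deterministic outputs so a
rerun with the same seed is byte-identical).
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .classify import classify_specific, count_rate_test, exclude_repeats, inducible_filter
from .config import AnalysisConfig
from .core import Condition
from .expression import (
    condition_specific_genes,
    expressed_universe,
    high_variation_set,
    inducible_specific_genes,
)
from .linkage import fraction_within, overlap_venn, permutation_enrichment
from .profiles import call_footprints
from .quantify import correction_factors, normalize, scaled_top_n
from .simulate import SimulatedBundle, SimulationParams, simulate


def validate_config(source: str | Path | dict | None) -> AnalysisConfig:
    """Normalize a YAML file / dict into an AnalysisConfig with defaults."""
    if source is None:
        return AnalysisConfig()
    if isinstance(source, dict):
        return AnalysisConfig.from_dict(source)
    with open(source) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {source} must be a mapping")
    return AnalysisConfig.from_dict(data)


@dataclass
class RunReport:
    config_hash: str
    seed: int
    counts: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "counts": self.counts,
            "recovery": self.recovery,
        }


def _rep_columns(samples: dict[str, tuple[str, int]], cond: Condition) -> list[str]:
    return sorted(s for s, (c, _r) in samples.items() if c == cond.value)


def write_bundle(bundle: SimulatedBundle, outdir: Path) -> None:
    cio.write_bed(outdir / "peaks.bed", bundle.peaks)
    cio.write_matrix(outdir / "counts.tsv", bundle.counts)
    cio.write_gene_table(outdir / "genes.tsv", bundle.genes)
    cio.write_bed(outdir / "repeats.bed", bundle.repeats)
    cio.write_bed(outdir / "chip_peaks.bed", bundle.chip_peaks)
    cio.write_bed(outdir / "profile_peaks.bed", bundle.profile_peaks)
    cio.write_cut_track(
        outdir / "profile_cuts_plus.bedgraph",
        outdir / "profile_cuts_minus.bedgraph",
        bundle.footprint_track,
    )
    cio.write_json(outdir / "truth.json", bundle.truth.to_json_dict())
    cio.write_json(outdir / "samples.json", bundle.sample_conditions)
    cio.write_json(outdir / "chrom_sizes.json", bundle.chrom_sizes)


def run_all(
    config: AnalysisConfig | None = None,
    outdir: str | Path = "out",
    sim_params: SimulationParams | None = None,
) -> RunReport:
    """Run every stage on a simulated bundle and write a run report.

    ``sim_params.seed`` drives all randomness. The report tabulates
    class counts, group sizes, proximity fractions, Venn counts and
    footprint tallies, plus truth-recovery metrics for the planted
    effects.
    """
    cfg = config or AnalysisConfig()
    params = sim_params or SimulationParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = cio.read_json(manifest_path)
        if manifest.get("config_hash") != cfg.config_hash():
            raise ValueError("config hash mismatch on resume; use a fresh outdir")
    log = open(outdir / "run.log", "a")
    t0 = time.time()

    def tick(stage: str) -> None:
        log.write(f"{stage}\t{time.time() - t0:.2f}s\n")
        log.flush()

    # --- stage: simulate -------------------------------------------------
    bundle = simulate(params)
    write_bundle(bundle, outdir)
    truth = bundle.truth
    tick("simulate")

    # --- stage: normalize ------------------------------------------------
    counts = bundle.counts
    top_n = scaled_top_n(len(counts), cap=cfg.top_n_for_norm)
    factors = correction_factors(counts, top_n)
    normed = normalize(counts, factors)
    cio.write_json(outdir / "factors.json", {s: factors.factors[s] for s in sorted(factors.factors)})
    cio.write_matrix(outdir / "normed.tsv", normed.round(4))
    tick("normalize")

    # --- stage: classify -------------------------------------------------
    peaks = exclude_repeats(bundle.peaks, bundle.repeats)
    kept_ids = [p.peak_id for p in peaks]
    nm = normed.loc[kept_ids]
    # union membership: significant in at least one sample
    sig = nm.ge(cfg.significance_count_cutoff).any(axis=1)
    nm = nm.loc[sig]
    samples = bundle.sample_conditions
    t0_reps = _rep_columns(samples, Condition.T_0)
    n0_reps = _rep_columns(samples, Condition.N_0)
    tag_reps = _rep_columns(samples, Condition.T_Ag)
    nag_reps = _rep_columns(samples, Condition.N_Ag)
    rest_labels = classify_specific(
        nm[t0_reps[0]], nm[t0_reps[1]], nm[n0_reps[0]], nm[n0_reps[1]],
        fc=cfg.specific_fc, pseudocount=cfg.pseudocount,
    )
    tdhs = list(rest_labels.index[rest_labels.label == "A_specific"])
    ndhs = list(rest_labels.index[rest_labels.label == "B_specific"])
    ag_labels = classify_specific(
        nm[tag_reps[0]], nm[tag_reps[1]], nm[nag_reps[0]], nm[nag_reps[1]],
        fc=cfg.specific_fc, pseudocount=cfg.pseudocount,
    )
    tag_spec = list(ag_labels.index[ag_labels.label == "A_specific"])
    nag_spec = list(ag_labels.index[ag_labels.label == "B_specific"])
    tag_idhs = inducible_filter(
        tag_spec, nm[tag_reps].mean(axis=1), nm[t0_reps].mean(axis=1),
        fc=cfg.inducible_fc, pseudocount=cfg.pseudocount,
    )
    nag_idhs = inducible_filter(
        nag_spec, nm[nag_reps].mean(axis=1), nm[n0_reps].mean(axis=1),
        fc=cfg.inducible_fc, pseudocount=cfg.pseudocount,
    )
    test = count_rate_test(
        counts.loc[nm.index, t0_reps], counts.loc[nm.index, n0_reps],
        size_factorsA=1.0 / np.array([factors.factors[s] for s in t0_reps]),
        size_factorsB=1.0 / np.array([factors.factors[s] for s in n0_reps]),
        pseudocount=cfg.pseudocount,
    )
    labels_out = rest_labels.copy()
    labels_out["qvalue_rest"] = test["qvalue"]
    labels_out.round(5).to_csv(outdir / "labels.tsv", sep="\t", index_label="peak_id")
    cio.write_json(outdir / "dhs_sets.json", {
        "tdhs": sorted(tdhs), "ndhs": sorted(ndhs),
        "tag_idhs": sorted(tag_idhs), "nag_idhs": sorted(nag_idhs),
    })
    tick("classify")

    # --- stage: expression groups ---------------------------------------
    universe = expressed_universe(bundle.genes, cfg.expr_universe_min_mean)
    g_t0 = condition_specific_genes(universe, "T_0", "N_0", cfg.specific_fc,
                                    cfg.expr_min_count, cfg.pseudocount, name="T0_specific")
    g_n0 = condition_specific_genes(universe, "N_0", "T_0", cfg.specific_fc,
                                    cfg.expr_min_count, cfg.pseudocount, name="N0_specific")
    g_tag = inducible_specific_genes(universe, "T_Ag", "N_Ag", "T_0", cfg.specific_fc,
                                     cfg.expr_min_count, 2.0, cfg.pseudocount, name="TAg_specific")
    g_nag = inducible_specific_genes(universe, "N_Ag", "T_Ag", "N_0", cfg.specific_fc,
                                     cfg.expr_min_count, 2.0, cfg.pseudocount, name="NAg_specific")
    ratio_pairs = [("T_0", "N_0"), ("T_Ag", "N_Ag"), ("T_Ag", "T_0"), ("N_Ag", "N_0")]
    g_hv = high_variation_set(universe, ratio_pairs, cfg.high_var_fc, cfg.pseudocount)
    groups = {g.name: sorted(g.members) for g in (g_t0, g_n0, g_tag, g_nag, g_hv)}
    cio.write_json(outdir / "gene_groups.json", groups)
    tick("expression")

    # --- stage: integrate -------------------------------------------------
    by_id = {p.peak_id: p for p in bundle.peaks}
    tdhs_peaks = [by_id[i] for i in tdhs]
    gene_by_id = {g.gene_id: g for g in universe}
    tag_genes = [gene_by_id[g] for g in groups["TAg_specific"] if g in gene_by_id]
    proximity: dict = {}
    if tag_genes and tdhs_peaks:
        proximity["fraction_tag_genes_within_50kb_of_tdhs"] = fraction_within(
            tag_genes, tdhs_peaks, cfg.proximity_dist
        )
        perm = permutation_enrichment(
            tag_genes, tdhs_peaks, universe, cfg.proximity_dist,
            n_perm=1000, seed=params.seed + 1,
        )
        proximity["permutation"] = perm
    venn = overlap_venn(
        [by_id[i].interval for i in tag_idhs] or [by_id[i].interval for i in tdhs],
        [iv for iv in bundle.chip_peaks],
        name_a="iDHS", name_b="ChIP",
    )
    cio.write_json(outdir / "integration.json", {
        "proximity": proximity,
        "venn": {"a_only": venn.a_only, "b_only": venn.b_only,
                 "both_a": venn.both_a, "both_b": venn.both_b},
    })
    tick("integrate")

    # --- stage: footprints ------------------------------------------------
    widths = range(cfg.footprint_min_width, cfg.footprint_max_width + 1, 2)
    calls = call_footprints(
        bundle.profile_peaks, bundle.footprint_track,
        window=params.profile_window, widths=widths, flank=cfg.footprint_flank,
        alpha=cfg.fdr_alpha, min_imbalance=cfg.footprint_min_imbalance,
        min_cuts=cfg.footprint_min_cuts,
    )
    fp_rows = pd.DataFrame(
        [{"peak_id": c.peak_id, "start": c.start, "end": c.end,
          "score": round(c.score, 4), "p_value": c.p_value, "q_value": c.q_value,
          "imbalance": round(c.strand_imbalance, 4), "called": c.called} for c in calls]
    )
    fp_rows.to_csv(outdir / "footprints.tsv", sep="\t", index=False,
                   float_format="%.6g")
    tick("footprints")

    # --- stage: report ----------------------------------------------------
    called = {c.peak_id for c in calls if c.called}
    planted = {pid for pid, b in truth.footprint_planted.items() if b}
    true_a = {pid for pid, c in truth.peak_class.items() if c == "A_specific"}
    tp = len(set(tdhs) & true_a)
    recovery = {
        "tdhs_sensitivity": tp / len(true_a) if true_a else float("nan"),
        "tdhs_fdp": (len(tdhs) - tp) / len(tdhs) if tdhs else 0.0,
        "footprint_sensitivity": len(called & planted) / len(planted) if planted else float("nan"),
        "footprint_fdp": len(called - planted) / len(called) if called else 0.0,
    }
    report = RunReport(
        config_hash=cfg.config_hash(),
        seed=params.seed,
        counts={
            "peaks_total": len(bundle.peaks),
            "peaks_after_repeat_exclusion": len(peaks),
            "union_significant": int(sig.sum()),
            "tdhs": len(tdhs),
            "ndhs": len(ndhs),
            "tag_specific": len(tag_spec),
            "nag_specific": len(nag_spec),
            "tag_idhs": len(tag_idhs),
            "nag_idhs": len(nag_idhs),
            "gene_universe": len(universe),
            **{f"genes_{k}": len(v) for k, v in groups.items()},
            "footprints_called": len(called),
            "venn_both": venn.both_a,
        },
        recovery=recovery,
    )
    cio.write_json(outdir / "report.json", report.to_json_dict())
    cio.write_json(manifest_path, {
        "config_hash": cfg.config_hash(),
        "seed": params.seed,
        "stages": ["simulate", "normalize", "classify", "expression",
                   "integrate", "footprints", "report"],
    })
    tick("report")
    log.close()
    return report
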