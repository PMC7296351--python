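"""Seeded synthetic data with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* a toy multi-chromosome genome carrying evenly spaced summit peaks;
* negative-binomially dispersed cut counts per peak and sample, with a
  planted fraction of condition-specific peaks (fold effect applied
  symmetrically around the shared mean so the average cuts per peak stay
  at the configured level) and of inducible peaks (extra fold effect in
  stimulated conditions only);
* genes on a dedicated chromosome whose planted expression groups are
  enriched by construction for proximity to planted specific peaks;
* a profile chromosome with a dense cut track in which footprints are
  carved as localized cut depletions with strand-offset flank cuts;
* repeat intervals and a ChIP-like peak set overlapping designated peak
  classes.

Everything is reproducible byte-identically from the seed; the planted
truth round-trips through JSON.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Condition, CutTrack, GeneRecord, GenomicInterval, SummitPeak

CONDITIONS = (Condition.N_0, Condition.T_0, Condition.N_Ag, Condition.T_Ag)


@dataclass
class SimulationParams:
    # peaks and counts
    n_peaks: int = 20000
    frac_a_specific: float = 0.05
    frac_b_specific: float = 0.05
    frac_inducible: float = 0.5  # fraction of specific peaks also inducible
    specific_effect: float = 4.0
    inducible_effect: float = 4.0
    dispersion: float = 0.05
    mean_cuts: float = 50.0
    n_reps: int = 2
    depth_log2_sd: float = 0.25  # per-sample sequencing-depth spread
    peak_spacing: int = 2000
    peak_width: int = 400
    # genes
    n_genes: int = 1000
    n_group_genes: int = 200  # stimulation-specific (T_Ag) group
    n_t0_group_genes: int = 100  # resting-state (T_0) group
    link_fraction: float = 0.25  # group genes with a planted specific DHS nearby
    background_link_fraction: float = 0.05
    link_dist: int = 50000
    gene_spacing: int = 150000
    expr_baseline: float = 30.0
    expr_group_effect: float = 4.0
    expr_dispersion: float = 0.05
    frac_unexpressed: float = 0.1
    # profile / footprint chromosome
    n_profile_peaks: int = 200
    frac_footprint: float = 0.5
    footprint_width: int = 15
    footprint_depletion: float = 0.6
    footprint_edge_fraction: float = 0.3
    profile_cuts: float = 300.0
    profile_window: int = 400
    # repeats and ChIP-like set
    n_repeat_peaks: int = 50
    n_repeat_background: int = 50
    chip_hit_fraction: float = 0.6  # of A-specific peaks covered by a ChIP peak
    n_chip_background: int = 200
    seed: int = 7

    def __post_init__(self) -> None:
        fr = self.frac_a_specific + self.frac_b_specific
        for name in ("frac_a_specific", "frac_b_specific", "frac_inducible",
                     "link_fraction", "background_link_fraction", "frac_footprint",
                     "footprint_depletion", "frac_unexpressed", "chip_hit_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if fr > 1.0:
            raise ValueError("specific-class fractions sum above 1")
        for name in ("specific_effect", "inducible_effect", "mean_cuts",
                     "expr_baseline", "expr_group_effect", "profile_cuts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0 or self.expr_dispersion < 0:
            raise ValueError("dispersions must be >= 0")


@dataclass
class TruthTables:
    peak_class: dict[str, str] = field(default_factory=dict)
    peak_inducible: dict[str, bool] = field(default_factory=dict)
    gene_group: dict[str, str] = field(default_factory=dict)
    gene_link: dict[str, str | None] = field(default_factory=dict)
    footprint_planted: dict[str, bool] = field(default_factory=dict)
    depth_factors: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json_dict(cls, d: dict) -> "TruthTables":
        return cls(**d)


@dataclass
class SimulatedBundle:
    params: SimulationParams
    chrom_sizes: dict[str, int]
    peaks: list[SummitPeak]
    counts: pd.DataFrame  # raw integer counts, peaks x samples
    sample_conditions: dict[str, tuple[str, int]]  # sample -> (condition, rep)
    genes: list[GeneRecord]
    repeats: list[GenomicInterval]
    chip_peaks: list[GenomicInterval]
    profile_peaks: list[SummitPeak]
    footprint_track: CutTrack
    truth: TruthTables


def _nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """Negative binomial with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _sample_name(cond: Condition, rep: int) -> str:
    return f"{cond.value}_rep{rep}"


def simulate_counts(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[list[SummitPeak], pd.DataFrame, dict[str, tuple[str, int]], TruthTables, dict[str, int]]:
    """Peaks, raw count matrix, sample map, and truth for the main genome."""
    n = params.n_peaks
    n_a = int(round(n * params.frac_a_specific))
    n_b = int(round(n * params.frac_b_specific))
    classes = np.array(
        ["A_specific"] * n_a + ["B_specific"] * n_b + ["shared"] * (n - n_a - n_b)
    )
    rng.shuffle(classes)
    inducible = np.zeros(n, dtype=bool)
    spec_idx = np.flatnonzero(classes != "shared")
    if spec_idx.size:
        k = int(round(spec_idx.size * params.frac_inducible))
        inducible[rng.choice(spec_idx, size=k, replace=False)] = True

    # geometry: evenly spaced peaks across four autosomes
    n_chroms = 4
    per_chrom = int(np.ceil(n / n_chroms))
    chrom_sizes: dict[str, int] = {}
    peaks: list[SummitPeak] = []
    half_w = params.peak_width // 2
    for i in range(n):
        c = i // per_chrom
        j = i % per_chrom
        chrom = f"chr{c + 1}"
        summit = (j + 1) * params.peak_spacing
        iv = GenomicInterval(chrom, summit - half_w, summit + half_w)
        peaks.append(SummitPeak(iv, summit, f"peak_{i:06d}"))
    for c in range(n_chroms):
        chrom_sizes[f"chr{c + 1}"] = (per_chrom + 2) * params.peak_spacing

    samples: dict[str, tuple[str, int]] = {}
    depth: dict[str, float] = {}
    for cond in CONDITIONS:
        for rep in range(1, params.n_reps + 1):
            s = _sample_name(cond, rep)
            samples[s] = (cond.value, rep)
            depth[s] = float(2.0 ** rng.normal(0.0, params.depth_log2_sd))

    sqrt_eff = np.sqrt(params.specific_effect)
    base = np.full(n, params.mean_cuts)
    cols = {}
    for s, (cond_name, _rep) in samples.items():
        cond = Condition(cond_name)
        mult = np.ones(n)
        mult[classes == "A_specific"] = sqrt_eff if cond.tolerized else 1.0 / sqrt_eff
        mult[classes == "B_specific"] = 1.0 / sqrt_eff if cond.tolerized else sqrt_eff
        if cond.stimulated:
            # induction is arm-matched: A-specific inducible peaks open up in
            # the stimulated tolerized arm, B-specific ones in the naive arm
            arm = "A_specific" if cond.tolerized else "B_specific"
            mult[inducible & (classes == arm)] *= params.inducible_effect
        mu = base * mult * depth[s]
        cols[s] = _nb_draw(rng, mu, params.dispersion)
    counts = pd.DataFrame(cols, index=[p.peak_id for p in peaks], dtype=np.int64)

    truth = TruthTables(
        peak_class={p.peak_id: c for p, c in zip(peaks, classes)},
        peak_inducible={p.peak_id: bool(b) for p, b in zip(peaks, inducible)},
        depth_factors=depth,
    )
    return peaks, counts, samples, truth, chrom_sizes


def simulate_genes(
    params: SimulationParams,
    rng: np.random.Generator,
    truth: TruthTables,
) -> tuple[list[GeneRecord], list[SummitPeak], pd.DataFrame]:
    """Gene table with planted groups plus gene-linked specific peaks.

    Linked genes receive a planted A-specific peak within ``link_dist``
    of the TSS on the gene chromosome; the extra peaks come with their
    own count-matrix rows so the classifier can recover them.
    """
    n = params.n_genes
    kinds = ["tag_group"] * params.n_group_genes + ["t0_group"] * params.n_t0_group_genes
    n_unexpr = int(round(n * params.frac_unexpressed))
    kinds += ["unexpressed"] * n_unexpr
    kinds += ["background"] * (n - len(kinds))
    if len(kinds) != n:
        raise ValueError("gene-kind fractions exceed n_genes")
    kinds = np.array(kinds)
    rng.shuffle(kinds)

    eff = params.expr_group_effect
    base = params.expr_baseline
    mu_by_kind = {
        # condition means; T_Ag group genes are stimulation-specific AND
        # inducible within the tolerized arm; T_0 group genes are
        # resting-state specific.
        "tag_group": {"N_0": base, "T_0": base, "N_Ag": base, "T_Ag": base * eff},
        "t0_group": {"N_0": base, "T_0": base * eff, "N_Ag": base, "T_Ag": base * eff},
        "background": {c.value: base for c in CONDITIONS},
        "unexpressed": {c.value: 1.0 for c in CONDITIONS},
    }

    genes: list[GeneRecord] = []
    link_peaks: list[SummitPeak] = []
    link_rows: dict[str, dict[str, int]] = {}
    gene_group: dict[str, str] = {}
    gene_link: dict[str, str | None] = {}
    half_w = params.peak_width // 2
    sqrt_eff = np.sqrt(params.specific_effect)
    depth = truth.depth_factors

    for i in range(n):
        gid = f"gene_{i:04d}"
        kind = str(kinds[i])
        tss = (i + 1) * params.gene_spacing
        expr = {}
        reps = {}
        for cond, mu in mu_by_kind[kind].items():
            draws = _nb_draw(rng, np.full(params.n_reps, mu), params.expr_dispersion)
            reps[cond] = [float(v) for v in draws]
            expr[cond] = float(np.mean(draws))
        genes.append(GeneRecord(gid, "chrG", tss, "+", expr, reps))
        gene_group[gid] = kind

        # proximity planting
        p_link = (
            params.link_fraction if kind == "tag_group"
            else params.background_link_fraction if kind != "unexpressed"
            else 0.0
        )
        if rng.random() < p_link:
            offset = int(rng.integers(-params.link_dist, params.link_dist + 1))
            summit = max(half_w, tss + offset)
            pid = f"linkpeak_{i:04d}"
            link_peaks.append(
                SummitPeak(GenomicInterval("chrG", summit - half_w, summit + half_w), summit, pid)
            )
            gene_link[gid] = pid
            row = {}
            for s in depth:
                cond = Condition(s.rsplit("_rep", 1)[0])
                mult = sqrt_eff if cond.tolerized else 1.0 / sqrt_eff
                if cond.stimulated:
                    mult *= params.inducible_effect
                row[s] = int(_nb_draw(rng, params.mean_cuts * mult * depth[s], params.dispersion))
            link_rows[pid] = row
        else:
            gene_link[gid] = None

    truth.gene_group = gene_group
    truth.gene_link = gene_link
    for pid in link_rows:
        truth.peak_class[pid] = "A_specific"
        truth.peak_inducible[pid] = True
    link_counts = pd.DataFrame.from_dict(link_rows, orient="index").astype(np.int64)
    return genes, link_peaks, link_counts


def simulate_footprint_windows(
    n_dhs: int,
    frac_planted: float = 0.5,
    cuts_per_dhs: float = 300.0,
    width: int = 15,
    depletion: float = 0.6,
    edge_fraction: float = 0.3,
    window: int = 400,
    spacing: int = 600,
    chrom: str = "chrP",
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[list[SummitPeak], CutTrack, dict[str, bool]]:
    """DHS windows with footprints planted in a random subset.

    Background cuts are uniform over the window with random strands. A
    planted footprint thins cuts in the central ``width`` bp by
    ``depletion`` and converts ``edge_fraction`` of all cuts into
    strand-offset edge cuts: plus-strand cuts piled just upstream of the
    footprint and minus-strand cuts just downstream.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    size = (n_dhs + 1) * spacing + window
    plus = np.zeros(size, dtype=np.int64)
    minus = np.zeros(size, dtype=np.int64)
    peaks: list[SummitPeak] = []
    planted: dict[str, bool] = {}
    half = window // 2
    for i in range(n_dhs):
        summit = (i + 1) * spacing
        pid = f"fp_{i:04d}"
        peaks.append(SummitPeak(GenomicInterval(chrom, summit - half, summit + half), summit, pid))
        has_fp = bool(rng.random() < frac_planted)
        planted[pid] = has_fp
        n_cuts = int(rng.poisson(cuts_per_dhs))
        lo = summit - half
        fp_lo, fp_hi = summit - width // 2, summit - width // 2 + width
        if not has_fp:
            pos = rng.integers(lo, lo + window, size=n_cuts)
            strands = rng.random(n_cuts) < 0.5
        else:
            n_edge = int(round(n_cuts * edge_fraction))
            n_body = n_cuts - n_edge
            pos_body = rng.integers(lo, lo + window, size=n_body)
            strand_body = rng.random(n_body) < 0.5
            # thin the footprint interior
            inside = (pos_body >= fp_lo) & (pos_body < fp_hi)
            keep = ~inside | (rng.random(n_body) >= depletion)
            pos_body, strand_body = pos_body[keep], strand_body[keep]
            # strand-offset edge cuts in 10 bp shoulders
            n_up = n_edge // 2
            pos_up = rng.integers(fp_lo - 10, fp_lo, size=n_up)
            pos_dn = rng.integers(fp_hi, fp_hi + 10, size=n_edge - n_up)
            pos = np.concatenate([pos_body, pos_up, pos_dn])
            strands = np.concatenate(
                [strand_body, np.ones(n_up, bool), np.zeros(n_edge - n_up, bool)]
            )
        np.add.at(plus, pos[strands], 1)
        np.add.at(minus, pos[~strands], 1)
    track = CutTrack({chrom: size}, sample_id="footprint_sim", plus={chrom: plus}, minus={chrom: minus})
    return peaks, track, planted


def simulate_poisson_null_windows(
    n_dhs: int,
    cuts_per_dhs: float = 300.0,
    window: int = 400,
    spacing: int = 600,
    chrom: str = "chrP",
    seed: int = 0,
) -> tuple[list[SummitPeak], CutTrack]:
    """Homogeneous Poisson cut windows (no structure) for null calibration."""
    peaks, track, _ = simulate_footprint_windows(
        n_dhs, frac_planted=0.0, cuts_per_dhs=cuts_per_dhs, window=window,
        spacing=spacing, chrom=chrom, seed=seed,
    )
    return peaks, track


def _plant_repeats_and_chip(
    params: SimulationParams,
    rng: np.random.Generator,
    peaks: list[SummitPeak],
    truth: TruthTables,
    chrom_sizes: dict[str, int],
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    shared = [p for p in peaks if truth.peak_class[p.peak_id] == "shared"]
    a_spec = [p for p in peaks if truth.peak_class[p.peak_id] == "A_specific"]
    repeats: list[GenomicInterval] = []
    n_rep = min(params.n_repeat_peaks, len(shared))
    for p in (shared[i] for i in rng.choice(len(shared), size=n_rep, replace=False)) if n_rep else ():
        repeats.append(GenomicInterval(p.chrom, p.interval.start, p.interval.end))
    for _ in range(params.n_repeat_background):
        chrom = f"chr{int(rng.integers(1, 5))}"
        start = int(rng.integers(0, chrom_sizes[chrom] - 300))
        # offset into inter-peak gaps so background repeats stay peak-free
        repeats.append(GenomicInterval(chrom, start, start + 200))
    chip: list[GenomicInterval] = []
    for p in a_spec:
        if rng.random() < params.chip_hit_fraction:
            chip.append(GenomicInterval(p.chrom, p.summit - 150, p.summit + 150))
    for _ in range(params.n_chip_background):
        chrom = f"chr{int(rng.integers(1, 5))}"
        start = int(rng.integers(0, chrom_sizes[chrom] - 400))
        chip.append(GenomicInterval(chrom, start, start + 300))
    return sorted(repeats), sorted(chip)


def simulate(params: SimulationParams | None = None) -> SimulatedBundle:
    """Full synthetic bundle with ground truth, reproducible from the seed."""
    if params is None:
        params = SimulationParams()
    rng = np.random.default_rng(params.seed)
    if params.n_peaks > 0:
        peaks, counts, samples, truth, chrom_sizes = simulate_counts(params, rng)
    else:
        peaks, counts, truth = [], pd.DataFrame(), TruthTables()
        chrom_sizes = {f"chr{c}": params.peak_spacing * 2 for c in range(1, 5)}
        samples = {
            _sample_name(cond, rep): (cond.value, rep)
            for cond in CONDITIONS for rep in range(1, params.n_reps + 1)
        }
        truth.depth_factors = {s: 1.0 for s in samples}
        counts = pd.DataFrame({s: [] for s in samples}, dtype=np.int64)
    genes, link_peaks, link_counts = simulate_genes(params, rng, truth)
    chrom_sizes["chrG"] = (params.n_genes + 2) * params.gene_spacing
    all_peaks = peaks + link_peaks
    if not link_counts.empty:
        counts = pd.concat([counts, link_counts.reindex(columns=counts.columns)])
        counts = counts.astype(np.int64)
    repeats, chip = _plant_repeats_and_chip(params, rng, peaks, truth, chrom_sizes)
    profile_peaks, fp_track, fp_truth = simulate_footprint_windows(
        params.n_profile_peaks,
        frac_planted=params.frac_footprint,
        cuts_per_dhs=params.profile_cuts,
        width=params.footprint_width,
        depletion=params.footprint_depletion,
        edge_fraction=params.footprint_edge_fraction,
        window=params.profile_window,
        rng=rng,
    )
    truth.footprint_planted = fp_truth
    chrom_sizes["chrP"] = fp_track.chrom_sizes["chrP"]
    return SimulatedBundle(
        params=params,
        chrom_sizes=chrom_sizes,
        peaks=all_peaks,
        counts=counts,
        sample_conditions=samples,
        genes=genes,
        repeats=repeats,
        chip_peaks=chip,
        profile_peaks=profile_peaks,
        footprint_track=fp_track,
        truth=truth,
    )
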