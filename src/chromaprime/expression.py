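"""Gene-expression filters defining the expressed universe and gene groups.

The expressed universe is every locus whose mean expression reaches
``min_mean`` (default 3) in at least one condition. Condition-specific
groups are 2-fold up in one condition versus the other with at least one
of the two compared means at or above ``min_count`` (default 50);
inducible-specific groups additionally require the stimulated condition
to be 2-fold up over its own resting state. The high-variation set holds
genes with at least a 10-fold difference (either direction) in any of the
configured condition ratios. Ratios use the pipeline-wide pseudocount.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .core import GeneRecord


@dataclass
class GeneGroup:
    name: str
    members: list[str]
    thresholds: dict = field(default_factory=dict)


def expressed_universe(genes: list[GeneRecord], min_mean: float = 3.0) -> list[GeneRecord]:
    """Genes whose mean expression reaches min_mean in >= 1 condition."""
    return [g for g in genes if g.expression and max(g.expression.values()) >= min_mean]


def condition_specific_genes(
    genes: list[GeneRecord],
    cond_hi: str,
    cond_lo: str,
    fc: float = 2.0,
    min_count: float = 50.0,
    pseudocount: float = 1.0,
    name: str | None = None,
) -> GeneGroup:
    """Genes fc-fold up in cond_hi vs cond_lo with max(hi, lo) >= min_count."""
    if cond_hi == cond_lo:
        raise ValueError("cond_hi and cond_lo must differ")
    p = pseudocount
    members = []
    for g in genes:
        hi = g.expression.get(cond_hi, 0.0)
        lo = g.expression.get(cond_lo, 0.0)
        if max(hi, lo) >= min_count and (hi + p) / (lo + p) >= fc:
            members.append(g.gene_id)
    return GeneGroup(
        name=name or f"{cond_hi}_specific",
        members=members,
        thresholds={"fc": fc, "min_count": min_count, "pseudocount": p,
                    "cond_hi": cond_hi, "cond_lo": cond_lo},
    )


def inducible_specific_genes(
    genes: list[GeneRecord],
    stim_hi: str,
    stim_lo: str,
    rest_of_hi: str,
    fc: float = 2.0,
    min_count: float = 50.0,
    induce_fc: float = 2.0,
    pseudocount: float = 1.0,
    name: str | None = None,
) -> GeneGroup:
    """Stimulation-specific genes that are also inducible within their arm.

    The condition-specific filter on (stim_hi vs stim_lo) is intersected
    with genes where stim_hi is induce_fc-fold up over the resting state
    of the same arm (rest_of_hi).
    """
    base = condition_specific_genes(
        genes, stim_hi, stim_lo, fc=fc, min_count=min_count,
        pseudocount=pseudocount,
    )
    p = pseudocount
    by_id = {g.gene_id: g for g in genes}
    members = []
    for gid in base.members:
        g = by_id[gid]
        hi = g.expression.get(stim_hi, 0.0)
        rest = g.expression.get(rest_of_hi, 0.0)
        if (hi + p) / (rest + p) >= induce_fc:
            members.append(gid)
    return GeneGroup(
        name=name or f"{stim_hi}_specific",
        members=members,
        thresholds={**base.thresholds, "induce_fc": induce_fc, "rest_of_hi": rest_of_hi},
    )


def high_variation_set(
    genes: list[GeneRecord],
    ratio_pairs: list[tuple[str, str]],
    fc: float = 10.0,
    pseudocount: float = 1.0,
) -> GeneGroup:
    """Genes with >= fc-fold difference (either direction) in any listed ratio."""
    if not ratio_pairs:
        raise ValueError("ratio_pairs must be non-empty")
    p = pseudocount
    members = []
    for g in genes:
        for num, den in ratio_pairs:
            a = g.expression.get(num, 0.0) + p
            b = g.expression.get(den, 0.0) + p
            if a / b >= fc or b / a >= fc:
                members.append(g.gene_id)
                break
    return GeneGroup(
        name="high_variation",
        members=members,
        thresholds={"fc": fc, "pseudocount": p, "ratio_pairs": list(ratio_pairs)},
    )
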