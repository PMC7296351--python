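import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chromaprime.core import CutTrack, GenomicInterval, SummitPeak

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_track(rng, chrom_sizes, rate=0.05, sample_id="s"):
    """Sparse random cut track via Poisson draws per base."""
    plus = {c: rng.poisson(rate, size=s).astype(np.int64) for c, s in chrom_sizes.items()}
    minus = {c: rng.poisson(rate, size=s).astype(np.int64) for c, s in chrom_sizes.items()}
    return CutTrack(chrom_sizes, sample_id=sample_id, plus=plus, minus=minus)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100000, max_len=500):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_peaks(rng, n, chroms=("chr1", "chr2"), max_pos=100000, width=200, prefix="p"):
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        summit = start + int(rng.integers(0, width))
        out.append(SummitPeak(GenomicInterval(chrom, start, start + width), summit, f"{prefix}{i:05d}"))
    return out


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the package's interval engine)
# ---------------------------------------------------------------------------

def merge_oracle(intervals):
    """O(n^2) pairwise merge to fixpoint; bookended intervals merge."""
    items = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                ci, si, ei = items[i]
                cj, sj, ej = items[j]
                if ci == cj and si <= ej and sj <= ei:
                    items[i] = (ci, min(si, sj), max(ei, ej))
                    items.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(items)


def bh_oracle(pvals, alpha=0.05):
    """Step-up Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        q[i] = val
        prev = val
    return q
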