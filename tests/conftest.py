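import math
from itertools import combinations

import numpy as np
import pytest

from thermoshift import MeltParams


@pytest.fixture
def std_params() -> MeltParams:
    """Reference melting curve used throughout: midpoint inside the
    51-56 deg C assay window."""
    return MeltParams(tm=53.0, slope=1.0, plateau=0.1)


def logistic_oracle(tm, slope, plateau, t):
    """Independent direct evaluation of the melting sigmoid."""
    return plateau + (1.0 - plateau) / (1.0 + math.exp(slope * (t - tm)))


def hypergeom_upper_tail_enumeration(population_n, set_k, draw_n, overlap_k):
    """P(overlap >= overlap_k) by enumerating every possible draw of
    ``draw_n`` items from a population containing ``set_k`` marked ones.
    Exact and feasible for populations up to ~12."""
    items = list(range(population_n))
    marked = set(items[:set_k])
    total = 0
    hits = 0
    for draw in combinations(items, draw_n):
        total += 1
        if len(marked.intersection(draw)) >= overlap_k:
            hits += 1
    return hits / total


def mannwhitney_two_sided_enumeration(x, y):
    """Exact two-sided Mann-Whitney p-value by enumerating every
    assignment of the pooled ranks to the first sample (tie-free data)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle needs tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)

    def u_stat(sample_ranks):
        r1 = sum(sample_ranks)
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_stat([ranks[v] for v in x])
    mean_u = n1 * n2 / 2
    dev_obs = abs(u_obs - mean_u)
    count = 0
    total = 0
    all_ranks = list(range(1, n1 + n2 + 1))
    for subset in combinations(all_ranks, n1):
        total += 1
        if abs(u_stat(subset) - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


def motif_oracle(sequence, position, max_spacer=4, min_repeats=2, window=10):
    """Brute-force RG-motif scanner, written independently of the
    package classifier: regex-free linear scan building unit spans and a
    transitive chain around the site."""
    i = position - 1
    assert sequence[i] == "R"
    n = len(sequence)
    if i + 1 >= n or sequence[i + 1] != "G":
        return "non_rg"

    spans = []
    for j in range(n - 1):
        if sequence[j] == "R" and sequence[j + 1] == "G":
            end = j + 2 if (j + 2 < n and sequence[j + 2] == "G") else j + 1
            spans.append((j, end))
    spans = [s for s in spans if abs(s[0] - i) <= window]

    members = {i}
    changed = True
    while changed:
        changed = False
        for a in spans:
            if a[0] in members:
                continue
            for b in spans:
                if b[0] not in members:
                    continue
                lo, hi = (a, b) if a[0] < b[0] else (b, a)
                if hi[0] - lo[1] - 1 <= max_spacer:
                    members.add(a[0])
                    changed = True
                    break
    return "canonical_rg" if len(members) >= min_repeats else "noncanonical_rg"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
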