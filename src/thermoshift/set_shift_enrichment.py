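"""Annotation-set statistics for stability screens.

Three families of tests operate on the per-protein log2 stability
ratios produced by the differential module:

* hypergeometric overlap of two regulated sets with a representation
  factor (observed overlap over the overlap expected under
  independence), computed in log space so astronomically small tails
  (p ~ 1e-330) survive floating point;
* rank-based distribution-shift tests of an annotated subset against
  the remaining proteome (Mann-Whitney U) or between paired columns of
  the same proteins (Wilcoxon signed-rank);
* pre-ranked running-sum enrichment with gene-permutation
  normalization (normalized enrichment score, NES).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError

MODE_WILCOXON_PAIRED = "wilcoxon_paired_columns"
MODE_MANN_WHITNEY = "mann_whitney_vs_background"

_LOG10E = math.log10(math.e)


@dataclass(frozen=True)
class AnnotationSet:
    """A named set of protein identifiers (one GMT line)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise InvalidArgumentError(f"annotation set {self.name!r} is empty")


@dataclass
class OverlapResult:
    population_n: int
    set_k: int
    draw_n: int
    overlap_k: int
    p_upper: float
    log10_p: float
    representation_factor: float


@dataclass
class RankShiftResult:
    statistic: float
    p_value: float
    median_shift: float
    mode: str


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p_perm: float
    n_perm: int
    set_size: int
    seed: int


def read_gmt(path) -> list[AnnotationSet]:
    """Parse a GMT file: name <tab> description <tab> member..."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidArgumentError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
                )
            members = frozenset(m for m in fields[2:] if m)
            sets.append(AnnotationSet(fields[0], members, fields[1]))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def overlap_test(population_n: int, set_k: int, draw_n: int, overlap_k: int) -> OverlapResult:
    """Upper-tail hypergeometric overlap test with representation factor.

    p_upper = P(X >= overlap_k) for X ~ Hypergeom(population_n, set_k,
    draw_n), evaluated through the log survival function so that
    sub-normal tails are reported exactly as log10 values.  The
    representation factor is overlap_k * population_n / (set_k * draw_n).
    """
    counts = (population_n, set_k, draw_n, overlap_k)
    if any(int(c) != c or c < 0 for c in counts):
        raise InvalidArgumentError(f"counts must be non-negative integers, got {counts}")
    if not (overlap_k <= min(set_k, draw_n) <= population_n):
        raise InvalidArgumentError(
            f"inconsistent counts: overlap {overlap_k} > min({set_k}, {draw_n}) "
            f"or sets exceed population {population_n}"
        )
    if set_k > population_n or draw_n > population_n:
        raise InvalidArgumentError("set sizes cannot exceed the population")

    if overlap_k == 0:
        log_p = 0.0
    else:
        log_p = float(stats.hypergeom.logsf(overlap_k - 1, population_n, set_k, draw_n))
    p_upper = math.exp(log_p) if log_p > -700 else 0.0
    rf = (
        overlap_k * population_n / (set_k * draw_n)
        if set_k > 0 and draw_n > 0
        else math.nan
    )
    return OverlapResult(
        population_n=population_n,
        set_k=set_k,
        draw_n=draw_n,
        overlap_k=overlap_k,
        p_upper=p_upper,
        log10_p=log_p * _LOG10E,
        representation_factor=rf,
    )


def rank_shift_test(subset_values, background_values, mode: str = MODE_MANN_WHITNEY) -> RankShiftResult:
    """Two-sided rank test of a subset against a background.

    Mann-Whitney U compares an annotated subset to the remaining
    proteome (exact null when both groups are small and tie-free, tie-
    corrected normal approximation with continuity correction
    otherwise).  The paired Wilcoxon signed-rank mode compares two
    columns of the same proteins, e.g. stability vs abundance ratios,
    dropping zero differences.
    """
    x = np.asarray(subset_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("samples must be non-empty")

    if mode == MODE_MANN_WHITNEY:
        exact = (
            x.size <= 12
            and y.size <= 12
            and np.unique(np.concatenate([x, y])).size == x.size + y.size
        )
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        shift = float(np.median(x) - np.median(y))
        return RankShiftResult(float(res.statistic), float(res.pvalue), shift, mode)
    if mode == MODE_WILCOXON_PAIRED:
        if x.size != y.size:
            raise InvalidArgumentError("paired mode needs equal-length vectors")
        d = x - y
        if np.all(d == 0):
            return RankShiftResult(0.0, 1.0, 0.0, mode)
        res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
        return RankShiftResult(float(res.statistic), float(res.pvalue), float(np.median(d)), mode)
    raise InvalidArgumentError(f"unknown mode {mode!r}")


def _running_sum_es(
    sorted_scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: float
) -> float:
    """Signed extremum of the weighted running sum over a ranked list."""
    n = sorted_scores.size
    n_hit = int(hit_mask.sum())
    n_miss = n - n_hit
    if n_hit == 0 or n_miss == 0:
        return 0.0
    w = np.abs(sorted_scores) ** weight_exponent
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total <= 0:
        # all hit scores are zero: fall back to equal increments
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    running = np.cumsum(hit_w / total - (~hit_mask) / n_miss)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    top, bottom = running[i_max], running[i_min]
    return float(top if abs(top) >= abs(bottom) else bottom)


def preranked_enrichment(
    ranked_scores: pd.Series | dict[str, float],
    sets: list[AnnotationSet],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Pre-ranked running-sum enrichment with gene-permutation NES.

    Proteins are ranked by decreasing score (ties broken by id for
    determinism).  For each annotation set the enrichment score is the
    signed extremum of the running sum, with hit increments
    proportional to |score|^weight_exponent and miss decrements of
    1/(N - set size).  The null is built by resampling same-size member
    sets from the ranked universe: NES divides the observed score by
    the mean |ES| of same-sign permutation scores, and the nominal
    permutation p-value is the add-one-smoothed fraction of same-sign
    permutation scores at least as extreme as the observed one.
    Sets intersecting the universe in fewer than ``min_size`` members
    are skipped.
    """
    if isinstance(ranked_scores, dict):
        ranked_scores = pd.Series(ranked_scores)
    if ranked_scores.empty:
        raise InvalidArgumentError("ranked universe is empty")
    if not np.isfinite(ranked_scores.to_numpy()).all():
        raise InvalidArgumentError("scores must be finite")

    frame = ranked_scores.rename("score").rename_axis("protein_id").reset_index()
    frame = frame.sort_values(["score", "protein_id"], ascending=[False, True], kind="stable")
    ids = frame["protein_id"].to_numpy()
    scores = frame["score"].to_numpy(dtype=float)
    pos_of = {pid: i for i, pid in enumerate(ids)}
    n = ids.size

    rng = np.random.default_rng(seed)
    rows = []
    for s in sets:
        hit_idx = np.array(sorted(pos_of[m] for m in s.members if m in pos_of), dtype=int)
        k = hit_idx.size
        if k < min_size:
            continue
        mask = np.zeros(n, dtype=bool)
        mask[hit_idx] = True
        es = _running_sum_es(scores, mask, weight_exponent)

        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            pmask = np.zeros(n, dtype=bool)
            pmask[rng.choice(n, size=k, replace=False)] = True
            perm_es[b] = _running_sum_es(scores, pmask, weight_exponent)

        same_sign = perm_es * es > 0 if es != 0 else np.ones(n_perm, dtype=bool)
        n_same = int(same_sign.sum())
        denom = float(np.mean(np.abs(perm_es[same_sign]))) if n_same else math.nan
        nes = es / denom if denom and not math.isnan(denom) else math.nan
        extreme = int(np.sum(same_sign & (np.abs(perm_es) >= abs(es))))
        # nominal p within the same-sign permutation null (add-one smoothed)
        p_perm = (1 + extreme) / (n_same + 1)
        rows.append(
            {
                "name": s.name,
                "es": es,
                "nes": nes,
                "p_perm": p_perm,
                "n_perm": n_perm,
                "set_size": k,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
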