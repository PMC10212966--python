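"""Differential thermal-stability testing with abundance decoupling.

The statistical core is an empirical-Bayes moderated two-group t-test:
per-protein sample variances are shrunk toward a common prior whose
scale ``s0^2`` and degrees of freedom ``d0`` are estimated by matching
the moments of ``log s_g^2`` to a log scaled-F distribution (the
digamma/trigamma moment equations familiar from limma's squeezeVar).
The moderated statistic

    t_g = (mean_a - mean_b) / (s_post_g * sqrt(1/n_a + 1/n_b)),
    s_post_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

is referred to a Student t with ``d0 + d_g`` degrees of freedom.

A protein is called regulated when |log2 ratio| exceeds 0.1 and the raw
moderated p-value falls below 0.01; Benjamini-Hochberg adjusted values
are reported alongside so the corresponding FDR can be audited.  Joint
classification against the abundance arm separates genuine stability
changes from expression changes that propagate into the pooled
stability channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import QuantMatrix
from .errors import DegenerateInputError, InvalidArgumentError

REG_UP = "up"
REG_DOWN = "down"
REG_NONE = "none"

JOINT_STABILITY_ONLY = "stability_only"
JOINT_ABUNDANCE_ONLY = "abundance_only"
JOINT_CONCORDANT = "concordant_both"
JOINT_DISCORDANT = "discordant"
JOINT_NONE = "none"

_VAR_FLOOR = 1e-12
_LOWESS_FRAC = 0.4
_LOWESS_IT = 2


@dataclass(frozen=True)
class ShrinkageEstimate:
    """Estimated variance prior: degrees of freedom (possibly inf) and scale."""

    prior_df: float
    prior_var: float

    def __post_init__(self) -> None:
        if not (self.prior_var > 0):
            raise InvalidArgumentError("prior_var must be > 0")
        if self.prior_df < 0:
            raise InvalidArgumentError("prior_df must be >= 0")


def normalize_log_intensities(matrix: QuantMatrix) -> QuantMatrix:
    """Global intensity-dependent normalization of a log2 matrix.

    Each sample is median-centred to the grand median; a locally
    weighted regression of the per-sample deviation against the
    row-mean intensity is then subtracted, removing intensity-dependent
    bowing; medians are re-centred afterwards.
    """
    x = matrix.data.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise InvalidArgumentError(
            "matrix contains missing/non-finite values; drop incomplete rows first"
        )
    grand = np.median(x)
    x = x - (np.median(x, axis=0) - grand)
    rowmean = x.mean(axis=1)
    order = np.argsort(rowmean, kind="stable")
    for j in range(x.shape[1]):
        dev = x[:, j] - rowmean
        trend = np.empty_like(dev)
        trend[order] = lowess(
            dev[order],
            rowmean[order],
            frac=_LOWESS_FRAC,
            it=_LOWESS_IT,
            return_sorted=False,
        )
        x[:, j] = x[:, j] - trend
    x = x - (np.median(x, axis=0) - grand)
    out = matrix.data.copy()
    out.loc[:, :] = x
    return QuantMatrix(out, matrix.channel, dict(matrix.conditions), dict(matrix.replicates))


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df_resid: float) -> ShrinkageEstimate:
    """Moment-match ``log s^2`` to a log scaled-F to get (d0, s0^2)."""
    s2 = np.maximum(np.asarray(s2, dtype=float), _VAR_FLOOR)
    z = np.log(s2)
    half = df_resid / 2.0
    e = z - float(special.digamma(half)) + math.log(half)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    t2 = e_var - float(special.polygamma(1, half))
    if t2 > 0:
        d0 = 2.0 * _trigamma_inverse(t2)
        s02 = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    elif e_var > 0:
        d0 = math.inf
        s02 = math.exp(e_mean)
    else:
        # exact tie: every sample variance identical.  The spread carries
        # no information, so the common observed variance is the prior and
        # moderation reduces to the ordinary pooled statistic.
        d0 = math.inf
        s02 = float(np.exp(np.mean(z)))
    return ShrinkageEstimate(prior_df=d0, prior_var=s02)


def moderated_t_test(
    matrix: QuantMatrix,
    group_a: list[str],
    group_b: list[str],
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> tuple[pd.DataFrame, ShrinkageEstimate]:
    """Empirical-Bayes moderated two-group test per protein.

    Returns a frame (log2fc = mean_a - mean_b, t, p_value, df_total)
    and the fitted prior.  ``prior_df``/``prior_var`` override the
    estimated prior; ``prior_df=0`` recovers the ordinary pooled
    two-sample t-test, ``prior_df=inf`` a common-variance statistic.
    """
    for name, grp in (("group_a", group_a), ("group_b", group_b)):
        if len(grp) < 2:
            raise InvalidArgumentError(f"{name} needs >= 2 samples, got {len(grp)}")
    xa = matrix.data[list(group_a)].to_numpy(dtype=float)
    xb = matrix.data[list(group_b)].to_numpy(dtype=float)
    if not (np.isfinite(xa).all() and np.isfinite(xb).all()):
        raise InvalidArgumentError("matrix contains missing values; filter rows first")
    na, nb = xa.shape[1], xb.shape[1]
    df_resid = na + nb - 2

    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    if np.all(s2 <= 0):
        raise DegenerateInputError("zero variance in every protein; nothing to moderate")

    if prior_df is None:
        prior = estimate_variance_prior(s2, df_resid)
    else:
        pv = prior_var if prior_var is not None else float(np.mean(np.maximum(s2, _VAR_FLOOR)))
        prior = ShrinkageEstimate(prior_df=float(prior_df), prior_var=pv)

    if math.isinf(prior.prior_df):
        s2_post = np.full_like(s2, prior.prior_var)
        df_total = np.inf
    else:
        s2_post = (prior.prior_df * prior.prior_var + df_resid * s2) / (prior.prior_df + df_resid)
        df_total = prior.prior_df + df_resid

    diff = mean_a - mean_b
    denom = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)

    out = pd.DataFrame(
        {"log2fc": diff, "t": t, "p_value": p, "df_total": df_total},
        index=matrix.data.index,
    )
    return out, prior


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InvalidArgumentError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def call_regulated(
    log2fc,
    p,
    fc_threshold: float = 0.1,
    p_threshold: float = 0.01,
) -> np.ndarray:
    """Regulation call: |log2 ratio| above threshold and p below threshold."""
    if fc_threshold <= 0 or p_threshold <= 0:
        raise InvalidArgumentError("thresholds must be positive")
    fc = np.atleast_1d(np.asarray(log2fc, dtype=float))
    pv = np.atleast_1d(np.asarray(p, dtype=float))
    out = np.full(fc.shape, REG_NONE, dtype=object)
    out[(fc > fc_threshold) & (pv < p_threshold)] = REG_UP
    out[(fc < -fc_threshold) & (pv < p_threshold)] = REG_DOWN
    return out


def joint_stability_abundance_classify(
    log2fc_stability,
    regulated_stability,
    log2fc_abundance,
    regulated_abundance,
    concordance_margin: float = 0.1,
) -> np.ndarray:
    """Classify each protein by joint stability/abundance behaviour.

    ``concordant_both`` (same-sign regulation with nearly equal log2
    ratios) flags apparent stability changes that are expression-driven:
    an abundance shift propagates one-for-one into the pooled stability
    channel, so matching ratios point to gene expression, not melting
    behaviour.
    """
    fc_s = np.atleast_1d(np.asarray(log2fc_stability, dtype=float))
    fc_a = np.atleast_1d(np.asarray(log2fc_abundance, dtype=float))
    reg_s = np.atleast_1d(np.asarray(regulated_stability, dtype=object))
    reg_a = np.atleast_1d(np.asarray(regulated_abundance, dtype=object))
    if not (fc_s.shape == fc_a.shape == reg_s.shape == reg_a.shape):
        raise InvalidArgumentError("stability and abundance channels must align")

    out = np.full(fc_s.shape, JOINT_NONE, dtype=object)
    s_reg = reg_s != REG_NONE
    a_reg = reg_a != REG_NONE
    out[s_reg & ~a_reg] = JOINT_STABILITY_ONLY
    out[~s_reg & a_reg] = JOINT_ABUNDANCE_ONLY
    both = s_reg & a_reg
    same_sign = reg_s == reg_a
    close = np.abs(fc_s - fc_a) <= concordance_margin
    out[both & same_sign & close] = JOINT_CONCORDANT
    out[both & ~(same_sign & close)] = JOINT_DISCORDANT
    return out


def run_differential(
    stability: QuantMatrix,
    abundance: QuantMatrix,
    condition_a: str,
    condition_b: str,
    fc_threshold: float = 0.1,
    p_threshold: float = 0.01,
    concordance_margin: float = 0.1,
    normalize: bool = True,
) -> pd.DataFrame:
    """Full two-channel differential analysis for one treatment contrast.

    ``condition_a`` is the treated arm and ``condition_b`` the control,
    so positive log2fc means stabilization (or higher abundance).
    """
    shared = stability.protein_ids.intersection(abundance.protein_ids)
    if shared.empty:
        raise InvalidArgumentError("stability and abundance matrices share no proteins")

    results = {}
    for label, qm in (("stability", stability), ("abundance", abundance)):
        if normalize:
            qm = normalize_log_intensities(qm)
        tab, _ = moderated_t_test(qm, qm.samples_for(condition_a), qm.samples_for(condition_b))
        tab = tab.loc[shared]
        results[label] = tab

    out = pd.DataFrame(index=shared.copy())
    for label, tab in results.items():
        out[f"log2fc_{label}"] = tab["log2fc"]
        out[f"p_{label}"] = tab["p_value"]
        out[f"fdr_{label}"] = bh_adjust(tab["p_value"].to_numpy())
        out[f"regulated_{label}"] = call_regulated(
            tab["log2fc"].to_numpy(), tab["p_value"].to_numpy(), fc_threshold, p_threshold
        )
    out["joint_class"] = joint_stability_abundance_classify(
        out["log2fc_stability"].to_numpy(),
        out["regulated_stability"].to_numpy(),
        out["log2fc_abundance"].to_numpy(),
        out["regulated_abundance"].to_numpy(),
        concordance_margin,
    )
    out.index.name = "protein_id"
    return out
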