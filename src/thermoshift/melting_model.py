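"""Melting-curve evaluation and fitting, the pooled-window (PISA)
solubility statistic, and nested-model two-condition curve comparison.

The melting curve is a three-parameter logistic in temperature,

    f(T) = plateau + (1 - plateau) / (1 + exp(slope * (T - tm)))

which is strictly decreasing for positive slope, equals
``plateau + (1 - plateau)/2`` at ``T = tm`` and approaches 1 (fully
soluble) at low temperature.  The pooled-window statistic is the
arithmetic mean of ``f`` over the gradient temperatures; because the
pooled sample combines equal aliquots from each temperature this mean is
proportional to the measured soluble signal, and the proportionality
constant cancels in log ratios.

Two-condition comparison follows the nested F-test of NPARC
(nonparametric analysis of response curves): the null model fits one
shared curve to both conditions (3 parameters), the alternative fits one
curve per condition (6 parameters), and

    F = ((rss_null - rss_alt) / (p_alt - p_null)) / (rss_alt / (n - p_alt))

is referred to an F distribution with (p_alt - p_null, n - p_alt)
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import MeltParams
from .errors import DegenerateInputError, InvalidArgumentError

TM_BOUNDS = (35.0, 75.0)
SLOPE_BOUNDS = (1e-6, 5.0)
PLATEAU_BOUNDS = (0.0, 0.5)
_TM_GRID_STEP = 2.0
_N_POLISH_STARTS = 3
_GTOL = 1e-8
_MAX_ITER = 500


@dataclass
class CurveFit:
    """Result of a bounded least-squares melting-curve fit."""

    params: MeltParams
    rss: float
    n_obs: int
    converged: bool


@dataclass
class NparcResult:
    """Nested-model comparison of one shared vs two per-condition curves."""

    rss_null: float
    rss_alt: float
    df_num: int
    df_den: int
    f_stat: float
    p_value: float
    perfect_fit: bool = False


def melt_fraction(params: MeltParams, t) -> np.ndarray | float:
    """Soluble fraction at temperature(s) ``t`` in deg C."""
    t = np.asarray(t, dtype=float)
    out = params.plateau + (1.0 - params.plateau) / (
        1.0 + np.exp(params.slope * (t - params.tm))
    )
    return out if out.ndim else float(out)


def pisa_value(params: MeltParams, temperatures) -> float:
    """Mean soluble fraction over the pooled temperature window."""
    temps = np.asarray(list(temperatures), dtype=float)
    if temps.size == 0:
        raise InvalidArgumentError("temperature window must be non-empty")
    return float(np.mean(melt_fraction(params, temps)))


def _curve(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    tm, slope, plateau = theta
    return plateau + (1.0 - plateau) / (1.0 + np.exp(slope * (t - tm)))


def _rss(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
    r = _curve(theta, t) - y
    return float(r @ r)


def fit_melting_curve(
    temperatures,
    quantities,
    normalize_to_lowest: bool = False,
) -> CurveFit:
    """Fit the logistic melting curve by bounded least squares.

    Multi-start: candidate tm values on a 2 deg C grid across the tm
    bounds are scored by initial residual sum of squares, and the best
    few are polished with a trust-region reflective solver.  Ties
    between polished starts are broken by lowest rss, then lowest tm.

    With ``normalize_to_lowest`` the quantities are first divided by
    their mean at the lowest observed temperature, mapping them onto the
    soluble-fraction scale the model expects.
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(quantities, dtype=float)
    if t.shape != y.shape:
        raise InvalidArgumentError("temperatures and quantities must align")
    if np.unique(t).size < 3:
        raise InvalidArgumentError("need >= 3 distinct temperatures to fit a curve")
    if np.any(y < 0):
        raise InvalidArgumentError("quantities must be non-negative")
    if np.all(y == 0):
        raise DegenerateInputError("all quantities are zero")

    if normalize_to_lowest:
        low = y[t == t.min()]
        ref = float(np.mean(low))
        if ref <= 0:
            raise DegenerateInputError("mean quantity at the lowest temperature is zero")
        y = y / ref

    lo = np.array([TM_BOUNDS[0], SLOPE_BOUNDS[0], PLATEAU_BOUNDS[0]])
    hi = np.array([TM_BOUNDS[1], SLOPE_BOUNDS[1], PLATEAU_BOUNDS[1]])

    tm_grid = np.arange(TM_BOUNDS[0], TM_BOUNDS[1] + 1e-9, _TM_GRID_STEP)
    plateau0 = float(min(max(y.min(), 0.0), PLATEAU_BOUNDS[1]))
    starts = np.column_stack(
        [tm_grid, np.full_like(tm_grid, 1.0), np.full_like(tm_grid, plateau0)]
    )
    scores = [_rss(s, t, y) for s in starts]
    order = np.argsort(scores, kind="stable")[:_N_POLISH_STARTS]

    best = None
    for idx in order:
        res = optimize.least_squares(
            lambda th: _curve(th, t) - y,
            starts[idx],
            bounds=(lo, hi),
            method="trf",
            gtol=_GTOL,
            xtol=1e-12,
            ftol=1e-12,
            max_nfev=_MAX_ITER,
        )
        rss = float(2.0 * res.cost)
        key = (rss, res.x[0])
        if best is None or key < best[0]:
            best = (key, res, rss)
    _, res, rss = best
    params = MeltParams(tm=float(res.x[0]), slope=float(res.x[1]), plateau=float(res.x[2]))
    return CurveFit(params=params, rss=rss, n_obs=int(t.size), converged=bool(res.status > 0))


def nparc_compare(
    table: pd.DataFrame,
    protein_id: str | None = None,
    rss_tol: float = 1e-12,
) -> NparcResult:
    """Compare melting behaviour between the two conditions of one protein.

    ``table`` uses the gradient dialect (protein_id, condition,
    temperature_c, replicate, quantity).  Quantities are normalized per
    protein to the mean over all points (both conditions) at the lowest
    temperature.  A single shared reference keeps the null calibrated:
    dividing each condition by its own noisy reference injects a random
    per-condition scale that the nested F-test mistakes for a curve
    difference.  Equal spike-in amounts per condition are therefore
    assumed; amplitude imbalances should be corrected upstream (e.g.
    against the carrier proteome) before calling this function.
    """
    if protein_id is not None:
        table = table[table["protein_id"] == protein_id]
    conditions = sorted(table["condition"].unique())
    if len(conditions) != 2:
        raise InvalidArgumentError(f"need exactly 2 conditions, got {conditions}")

    ts, ys = [], []
    for cond in conditions:
        sub = table[table["condition"] == cond]
        if sub["temperature_c"].nunique() < 3:
            raise InvalidArgumentError(
                f"condition {cond!r} has fewer than 3 temperatures"
            )
        ts.append(sub["temperature_c"].to_numpy(dtype=float))
        ys.append(sub["quantity"].to_numpy(dtype=float))

    t_min = min(t.min() for t in ts)
    ref_vals = np.concatenate([y[t == t_min] for t, y in zip(ts, ys)])
    ref = float(np.mean(ref_vals)) if ref_vals.size else 0.0
    if ref <= 0:
        raise DegenerateInputError("zero quantity at the lowest temperature")
    ys = [y / ref for y in ys]

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys)
    n_obs = int(t_all.size)
    p_null, p_alt = 3, 6
    if n_obs <= p_alt:
        raise InvalidArgumentError(f"need more than {p_alt} observations, got {n_obs}")

    rss_null = fit_melting_curve(t_all, y_all).rss
    rss_alt = sum(fit_melting_curve(t, y).rss for t, y in zip(ts, ys))
    # the per-condition fits nest inside the shared fit; numerical slack only
    rss_null = max(rss_null, rss_alt)

    df_num = p_alt - p_null
    df_den = n_obs - p_alt
    if rss_alt <= rss_tol:
        if rss_null - rss_alt <= rss_tol:
            return NparcResult(rss_null, rss_alt, df_num, df_den, 0.0, 1.0, True)
        return NparcResult(rss_null, rss_alt, df_num, df_den, np.inf, 0.0, True)
    f_stat = ((rss_null - rss_alt) / df_num) / (rss_alt / df_den)
    p_value = float(stats.f.sf(f_stat, df_num, df_den))
    return NparcResult(rss_null, rss_alt, df_num, df_den, float(f_stat), p_value)


def carrier_normalize(table: pd.DataFrame, carrier_ids) -> pd.DataFrame:
    """Normalize a gradient table against carrier proteins.

    For every (condition, temperature, replicate) cell the scaling
    factor is the median, over carrier proteins, of the ratio between
    the carrier quantity in that cell and the carrier's mean across all
    cells of the same temperature.  Dividing by it removes
    loading/acquisition differences between replicates and conditions
    while leaving genuine melting behaviour (the temperature trend)
    untouched.
    """
    carrier_ids = set(carrier_ids)
    carrier = table[table["protein_id"].isin(carrier_ids)]
    if carrier.empty:
        raise InvalidArgumentError("no carrier proteins present in the table")
    temp_mean = (
        carrier.groupby(["protein_id", "temperature_c"])["quantity"].transform("mean")
    )
    ratios = carrier.assign(ratio=carrier["quantity"] / temp_mean)
    factors = (
        ratios.groupby(["condition", "temperature_c", "replicate"])["ratio"]
        .median()
        .rename("scale")
    )
    out = table.merge(factors, on=["condition", "temperature_c", "replicate"], how="left")
    if out["scale"].isna().any():
        raise InvalidArgumentError(
            "carrier does not cover every (condition, temperature, replicate) cell"
        )
    out["quantity"] = out["quantity"] / out["scale"]
    return out.drop(columns="scale")


def nparc_scan(table: pd.DataFrame, protein_ids=None) -> pd.DataFrame:
    """Run :func:`nparc_compare` for each protein in a gradient table."""
    if protein_ids is None:
        protein_ids = sorted(table["protein_id"].unique())
    rows = []
    for pid in protein_ids:
        r = nparc_compare(table, protein_id=pid)
        rows.append(
            {
                "protein_id": pid,
                "rss_null": r.rss_null,
                "rss_alt": r.rss_alt,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "f_stat": r.f_stat,
                "p_value": r.p_value,
                "perfect_fit": r.perfect_fit,
            }
        )
    return pd.DataFrame(rows)
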