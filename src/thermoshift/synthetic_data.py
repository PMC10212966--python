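"""Ground-truth-labelled synthetic thermal-proteome experiments.

The generator emulates the statistical structure of a pooled-window
(PISA) thermal-stability screen paired with a protein-abundance arm:

* every protein carries a logistic melting curve with midpoint (Tm)
  drawn so the 51-56 deg C assay window straddles the typical
  transition;
* a minority "substrate" subset receives a positive Tm shift under
  treatment (drug-engagement-like stabilization);
* an independent subset changes abundance only, which propagates into
  the pooled stability channel as well (this is what the abundance arm
  is there to decouple);
* replicate noise is multiplicative log-normal, parameterized by the
  coefficient of variation, because reporter-intensity noise scales
  with signal.

All operations are deterministic under an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MeltParams, QuantMatrix, lognormal_noise, sample_name
from .errors import InvalidArgumentError
from .melting_model import melt_fraction

DEFAULT_PISA_WINDOW = (51.0, 52.0, 53.0, 54.0, 55.0, 56.0)
DEFAULT_GRADIENT_TEMPS = (49.0, 51.0, 53.0, 55.0, 57.0)

LABEL_NULL = "null"
LABEL_STABILIZED = "substrate_stabilized"
LABEL_DESTABILIZED = "substrate_destabilized"
LABEL_ABUNDANCE = "abundance_changed"


@dataclass
class ProteomeModel:
    """A synthetic proteome: ids, melting parameters and base abundance."""

    protein_ids: list[str]
    melt: list[MeltParams]
    base_abundance: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.protein_ids)
        if len(set(self.protein_ids)) != n:
            raise InvalidArgumentError("protein ids must be unique")
        if len(self.melt) != n or len(self.base_abundance) != n:
            raise InvalidArgumentError("melt and base_abundance must align with ids")
        self.base_abundance = np.asarray(self.base_abundance, dtype=float)
        if np.any(self.base_abundance <= 0):
            raise InvalidArgumentError("base abundances must be positive")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)


@dataclass
class TreatmentEffect:
    """Per-protein ground-truth effects of a treatment."""

    protein_ids: list[str]
    delta_tm: np.ndarray
    log2_abundance_effect: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.protein_ids)
        if not (len(self.delta_tm) == len(self.log2_abundance_effect) == len(self.labels) == n):
            raise InvalidArgumentError("effect arrays must align with protein ids")
        self.delta_tm = np.asarray(self.delta_tm, dtype=float)
        self.log2_abundance_effect = np.asarray(self.log2_abundance_effect, dtype=float)

    def ground_truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "label": self.labels,
                "true_delta_tm": self.delta_tm,
                "true_log2_abundance_effect": self.log2_abundance_effect,
            }
        ).set_index("protein_id")


@dataclass
class ExperimentDesign:
    """Replicate layout, assay window and noise level of one experiment.

    ``n_reps_*_abundance`` default to the stability-arm counts; set
    ``n_reps_treated_abundance=2`` for the unbalanced 3-vs-2 abundance
    design.
    """

    temperatures: tuple[float, ...] = DEFAULT_PISA_WINDOW
    n_reps_control: int = 3
    n_reps_treated: int = 3
    noise_cv: float = 0.08
    seed: int = 0
    n_reps_control_abundance: int | None = None
    n_reps_treated_abundance: int | None = None

    def __post_init__(self) -> None:
        if len(self.temperatures) < 2:
            raise InvalidArgumentError("need >= 2 temperatures in the assay window")
        if self.n_reps_control < 2 or self.n_reps_treated < 2:
            raise InvalidArgumentError("need >= 2 replicates per arm")
        if self.noise_cv < 0:
            raise InvalidArgumentError("noise_cv must be >= 0")
        if self.n_reps_control_abundance is None:
            self.n_reps_control_abundance = self.n_reps_control
        if self.n_reps_treated_abundance is None:
            self.n_reps_treated_abundance = self.n_reps_treated


def sample_proteome_model(
    n_proteins: int,
    seed: int = 0,
    tm_mean: float = 52.5,
    tm_sd: float = 2.0,
    plateau_max: float = 0.2,
    slope_log_mean: float = 0.0,
    slope_log_sd: float = 0.25,
    abundance_log10_mean: float = 6.0,
    abundance_log10_sd: float = 1.0,
) -> ProteomeModel:
    """Draw a proteome of melting curves and base abundances.

    Tm comes from a normal truncated to [40, 70] deg C, slope from a
    log-normal (median ``exp(slope_log_mean)`` per deg C, capped at the
    fitting bound), plateau uniform on [0, plateau_max], and base
    abundance log-normal wide enough to span several orders of
    magnitude, mimicking the dynamic range of a deep proteome.
    """
    if n_proteins < 1:
        raise InvalidArgumentError("n_proteins must be >= 1")
    if tm_sd <= 0:
        raise InvalidArgumentError("tm_sd must be > 0")
    if not (0.0 <= plateau_max < 1.0):
        raise InvalidArgumentError("plateau_max must be in [0, 1)")

    rng = np.random.default_rng(seed)
    a, b = (40.0 - tm_mean) / tm_sd, (70.0 - tm_mean) / tm_sd
    tm = stats.truncnorm.rvs(a, b, loc=tm_mean, scale=tm_sd, size=n_proteins, random_state=rng)
    slope = np.clip(rng.lognormal(slope_log_mean, slope_log_sd, n_proteins), 0.1, 5.0)
    plateau = rng.uniform(0.0, plateau_max, n_proteins) if plateau_max > 0 else np.zeros(n_proteins)
    abundance = 10.0 ** rng.normal(abundance_log10_mean, abundance_log10_sd, n_proteins)

    ids = [f"P{i:06d}" for i in range(n_proteins)]
    melt = [MeltParams(float(t), float(s), float(p)) for t, s, p in zip(tm, slope, plateau)]
    return ProteomeModel(ids, melt, abundance)


def apply_treatment_effect(
    model: ProteomeModel,
    frac_stabilized: float = 0.05,
    mean_delta_tm: float = 1.5,
    sd_delta_tm: float = 0.5,
    frac_abundance: float = 0.0,
    mean_log2_abund: float = -0.5,
    sd_log2_abund: float = 0.25,
    seed: int = 0,
    disjoint: bool = True,
) -> TreatmentEffect:
    """Assign treatment effects to a deterministic subset of proteins.

    ``round(frac * n)`` proteins are drawn without replacement for each
    effect class; with ``disjoint=True`` (default) the abundance subset
    avoids the substrate subset.  Substrate Tm shifts are normal around
    ``mean_delta_tm``; labels follow the sign of the drawn shift.
    """
    for name, frac in (("frac_stabilized", frac_stabilized), ("frac_abundance", frac_abundance)):
        if not (0.0 <= frac <= 1.0):
            raise InvalidArgumentError(f"{name} must be in [0, 1], got {frac}")
    if disjoint and frac_stabilized + frac_abundance > 1.0:
        raise InvalidArgumentError("disjoint effect fractions must sum to <= 1")

    n = model.n_proteins
    rng = np.random.default_rng(seed)
    n_stab = round(frac_stabilized * n)
    n_abund = round(frac_abundance * n)

    all_idx = np.arange(n)
    stab_idx = rng.choice(all_idx, size=n_stab, replace=False) if n_stab else np.array([], dtype=int)
    pool = np.setdiff1d(all_idx, stab_idx) if disjoint else all_idx
    abund_idx = rng.choice(pool, size=n_abund, replace=False) if n_abund else np.array([], dtype=int)

    delta_tm = np.zeros(n)
    log2_abund = np.zeros(n)
    if n_stab:
        delta_tm[stab_idx] = rng.normal(mean_delta_tm, sd_delta_tm, n_stab)
    if n_abund:
        log2_abund[abund_idx] = rng.normal(mean_log2_abund, sd_log2_abund, n_abund)

    labels = [LABEL_NULL] * n
    for i in abund_idx:
        labels[i] = LABEL_ABUNDANCE
    for i in stab_idx:
        labels[i] = LABEL_STABILIZED if delta_tm[i] > 0 else LABEL_DESTABILIZED
    return TreatmentEffect(list(model.protein_ids), delta_tm, log2_abund, labels)


def _shifted(params: MeltParams, delta: float) -> MeltParams:
    if delta == 0.0:
        return params
    return replace(params, tm=float(np.clip(params.tm + delta, 30.0, 80.0)))


def simulate_pisa_dataset(
    model: ProteomeModel,
    effect: TreatmentEffect,
    design: ExperimentDesign,
    condition_names: tuple[str, str] = ("control", "treated"),
) -> tuple[QuantMatrix, QuantMatrix, pd.DataFrame]:
    """Simulate paired stability/abundance matrices for one treatment.

    The stability-channel quantity of a replicate is

        base * 2^(abundance effect, treated arm only)
             * mean_T f(T; tm [+ delta_tm]) * noise

    i.e. the pooled-window soluble signal; the abundance channel omits
    the melting factor.  Both matrices are returned log2-transformed
    with ground truth alongside.
    """
    if list(model.protein_ids) != list(effect.protein_ids):
        raise InvalidArgumentError("model and effect must cover the same proteins")
    temps = np.asarray(design.temperatures, dtype=float)
    if temps.size == 0:
        raise InvalidArgumentError("empty temperature window")

    rng = np.random.default_rng(design.seed)
    control_name, treated_name = condition_names
    n = model.n_proteins

    pisa_control = np.array(
        [np.mean(melt_fraction(p, temps)) for p in model.melt]
    )
    pisa_treated = np.array(
        [np.mean(melt_fraction(_shifted(p, d), temps)) for p, d in zip(model.melt, effect.delta_tm)]
    )
    abund_factor = 2.0 ** effect.log2_abundance_effect

    def columns(channel, n_ctrl, n_trt, mean_ctrl, mean_trt):
        cols, names, conds, reps = [], [], {}, {}
        for k in range(1, n_ctrl + 1):
            name = sample_name(control_name, channel, k)
            cols.append(mean_ctrl * lognormal_noise(rng, design.noise_cv, n))
            names.append(name)
            conds[name], reps[name] = control_name, k
        for k in range(1, n_trt + 1):
            name = sample_name(treated_name, channel, k)
            cols.append(mean_trt * lognormal_noise(rng, design.noise_cv, n))
            names.append(name)
            conds[name], reps[name] = treated_name, k
        df = pd.DataFrame(
            np.log2(np.column_stack(cols)), index=pd.Index(model.protein_ids, name="protein_id"),
            columns=names,
        )
        return QuantMatrix(df, channel, conds, reps)

    base = model.base_abundance
    stability = columns(
        "sta",
        design.n_reps_control,
        design.n_reps_treated,
        base * pisa_control,
        base * abund_factor * pisa_treated,
    )
    abundance = columns(
        "abu",
        design.n_reps_control_abundance,
        design.n_reps_treated_abundance,
        base,
        base * abund_factor,
    )
    return stability, abundance, effect.ground_truth()


def simulate_gradient_dataset(
    targets: dict[str, tuple[MeltParams, MeltParams]],
    temperatures=DEFAULT_GRADIENT_TEMPS,
    n_reps: int = 2,
    noise_cv: float = 0.05,
    seed: int = 0,
    carrier: ProteomeModel | None = None,
    condition_names: tuple[str, str] = ("control", "treated"),
) -> pd.DataFrame:
    """Simulate a spike-in temperature-gradient table.

    ``targets`` maps a protein id to its (control, treated) melting
    parameters; spiked targets have unit amplitude while optional
    carrier proteins (identical curves in both conditions) keep their
    base abundance.  Output columns: protein_id, condition,
    temperature_c, replicate, quantity.
    """
    temps = np.asarray(list(temperatures), dtype=float)
    if temps.size < 3:
        raise InvalidArgumentError("need >= 3 temperatures for curve comparison")
    if n_reps < 2:
        raise InvalidArgumentError("need >= 2 replicates")

    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def emit(pid, cond, params, amplitude):
        frac = melt_fraction(params, temps)
        for rep in range(1, n_reps + 1):
            noise = lognormal_noise(rng, noise_cv, temps.size)
            for t, f, eps in zip(temps, frac, noise):
                rows.append(
                    {
                        "protein_id": pid,
                        "condition": cond,
                        "temperature_c": float(t),
                        "replicate": rep,
                        "quantity": float(amplitude * f * eps),
                    }
                )

    for pid, (ctrl_params, trt_params) in targets.items():
        emit(pid, condition_names[0], ctrl_params, 1.0)
        emit(pid, condition_names[1], trt_params, 1.0)
    if carrier is not None:
        for pid, params, base in zip(carrier.protein_ids, carrier.melt, carrier.base_abundance):
            emit(pid, condition_names[0], params, base)
            emit(pid, condition_names[1], params, base)
    return pd.DataFrame(rows)


def simulate_methyl_peptide_table(
    true_occupancy: dict[str, dict[str, float]],
    loading: dict[str, float],
    noise_cv: float = 0.05,
    seed: int = 0,
    state_weights: dict[str, float] | None = None,
    base_intensity: float = 1e6,
) -> pd.DataFrame:
    """Simulate modified/unmodified counterpart peptide quantities.

    ``true_occupancy[site][condition]`` is the fraction of molecules
    methylated at that site; ``loading[condition]`` a linear loading
    factor.  The unmodified counterpart intensity is proportional to
    ``loading * (1 - occupancy)`` and the modified intensity to
    ``loading * occupancy`` split across methyl states.
    """
    weights = state_weights or {"me1": 0.5, "me2": 0.5}
    wsum = sum(weights.values())
    for cond, load in loading.items():
        if load <= 0:
            raise InvalidArgumentError(f"loading for {cond!r} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for site, per_cond in true_occupancy.items():
        for cond, theta in per_cond.items():
            if not (0.0 <= theta <= 1.0):
                raise InvalidArgumentError(f"occupancy must be in [0, 1], got {theta}")
            load = loading[cond]
            noise = lognormal_noise(rng, noise_cv, 1 + len(weights))
            rows.append(
                {
                    "site": site,
                    "condition": cond,
                    "peptidoform": "unmodified",
                    "quantity": float(base_intensity * load * (1.0 - theta) * noise[0]),
                }
            )
            for j, (state, w) in enumerate(weights.items(), start=1):
                rows.append(
                    {
                        "site": site,
                        "condition": cond,
                        "peptidoform": state,
                        "quantity": float(base_intensity * load * theta * w / wsum * noise[j]),
                    }
                )
    return pd.DataFrame(rows)


def write_ground_truth(gt: pd.DataFrame, path) -> None:
    gt.to_csv(path, sep="\t", index=True)


def write_gradient_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gradient_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
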