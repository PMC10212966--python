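"""End-to-end workflow orchestration and file-format dialects.

The workflow mirrors a two-inhibitor pooled-window stability screen:
per treatment, normalize both channels, run the moderated test, adjust
by Benjamini-Hochberg, call regulated proteins, then intersect the
regulated sets across treatments (the consensus) and classify each
protein's joint stability/abundance behaviour.  Every run is
deterministic given the configuration and seed, and a machine-readable
run report records per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import QuantMatrix
from .differential_stability import REG_DOWN, REG_UP, run_differential
from .errors import ValidationError
from .set_shift_enrichment import overlap_test, preranked_enrichment, read_gmt
from .synthetic_data import (
    ExperimentDesign,
    apply_treatment_effect,
    sample_proteome_model,
    simulate_pisa_dataset,
)

logger = logging.getLogger("thermoshift")


@dataclass
class SimulationSpec:
    """Parameters for simulating the input matrices instead of reading
    them from disk.  All treatments share the proteome model and the
    substrate set; replicate noise differs per treatment."""

    n_proteins: int = 2000
    frac_stabilized: float = 0.05
    mean_delta_tm: float = 1.5
    sd_delta_tm: float = 0.5
    frac_abundance: float = 0.0
    mean_log2_abund: float = -0.5
    noise_cv: float = 0.08
    temperatures: tuple[float, ...] = (51.0, 52.0, 53.0, 54.0, 55.0, 56.0)
    n_reps_control: int = 3
    n_reps_treated: int = 3


@dataclass
class PipelineConfig:
    treatments: list[str] = field(default_factory=lambda: ["inhibitor_1", "inhibitor_2"])
    control_condition: str = "control"
    treated_condition: str = "treated"
    stability_paths: dict[str, str] = field(default_factory=dict)
    abundance_paths: dict[str, str] = field(default_factory=dict)
    simulate: SimulationSpec | None = None
    fc_threshold: float = 0.1
    p_threshold: float = 0.01
    concordance_margin: float = 0.1
    gmt_path: str | None = None
    n_perm: int = 1000
    seed: int = 0
    out_dir: str = "thermoshift_out"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.p_threshold <= 0:
            raise ValidationError("thresholds must be positive")
        if self.simulate is None and not self.stability_paths:
            raise ValidationError("config needs either input paths or a simulate block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw, simulate=SimulationSpec(**sim) if sim is not None else None)
        return cfg

    def digest(self) -> str:
        payload = json.dumps(
            {k: (v.__dict__ if isinstance(v, SimulationSpec) else v) for k, v in self.__dict__.items()},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    seed: int
    config_hash: str
    version: str
    proteins_read: dict[str, int] = field(default_factory=dict)
    complete_cases: dict[str, int] = field(default_factory=dict)
    regulated_up: dict[str, int] = field(default_factory=dict)
    regulated_down: dict[str, int] = field(default_factory=dict)
    consensus_up: int = 0
    consensus_down: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def read_quant_table(
    path,
    channel: str,
    id_column: str | None = None,
    column_map: dict[str, str] | None = None,
    log2_transform: bool = False,
) -> QuantMatrix:
    """Read a quantification TSV in the native dialect or a
    protein-group-style export.

    Native files carry ``protein_id`` plus ``<condition>_<channel>_rep<k>``
    columns.  Protein-group exports are accepted by naming the id
    column (e.g. ``Protein IDs``) and mapping each reporter column to a
    native sample name via ``column_map``.  ``log2_transform`` converts
    linear-scale intensities.
    """
    df = pd.read_csv(path, sep="\t")
    id_col = id_column or "protein_id"
    if id_col not in df.columns:
        raise ValidationError(f"{path}: missing id column {id_col!r}")
    if column_map:
        missing = [c for c in column_map if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: mapped columns not found: {missing}")
        df = df[[id_col, *column_map.keys()]].rename(columns=column_map)
    df = df.set_index(id_col)
    df.index.name = "protein_id"
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate protein ids: {dupes[:5]}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
            raise ValidationError(f"{path}: non-numeric cells in column {col!r} at lines {lines[:5]}")
        df[col] = coerced
    if log2_transform:
        if (df.to_numpy() <= 0).any():
            raise ValidationError(f"{path}: non-positive intensities cannot be log2-transformed")
        df = np.log2(df)
    return QuantMatrix(df, channel)


def _simulated_inputs(cfg: PipelineConfig):
    sim = cfg.simulate
    model = sample_proteome_model(sim.n_proteins, seed=cfg.seed)
    effect = apply_treatment_effect(
        model,
        frac_stabilized=sim.frac_stabilized,
        mean_delta_tm=sim.mean_delta_tm,
        sd_delta_tm=sim.sd_delta_tm,
        frac_abundance=sim.frac_abundance,
        mean_log2_abund=sim.mean_log2_abund,
        seed=cfg.seed + 1,
    )
    out = {}
    for i, name in enumerate(cfg.treatments):
        design = ExperimentDesign(
            temperatures=sim.temperatures,
            n_reps_control=sim.n_reps_control,
            n_reps_treated=sim.n_reps_treated,
            noise_cv=sim.noise_cv,
            seed=cfg.seed + 100 + i,
        )
        sta, abu, gt = simulate_pisa_dataset(model, effect, design)
        out[name] = (sta, abu, gt)
    return out


def run_pisa_workflow(config: PipelineConfig) -> RunReport:
    """Execute the full screen workflow; returns the run report and
    writes per-treatment differential tables, the consensus table and
    the report to ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, config_hash=config.digest(), version=__version__)
    logger.info("run start: seed=%d config=%s", config.seed, report.config_hash)

    if config.simulate is not None:
        inputs = _simulated_inputs(config)
    else:
        inputs = {}
        for name in config.treatments:
            sta = read_quant_table(config.stability_paths[name], "sta")
            abu = read_quant_table(config.abundance_paths[name], "abu")
            inputs[name] = (sta, abu, None)

    diffs: dict[str, pd.DataFrame] = {}
    up_sets: dict[str, set[str]] = {}
    down_sets: dict[str, set[str]] = {}
    universes: dict[str, set[str]] = {}
    for name, (sta, abu, gt) in inputs.items():
        if set(sta.protein_ids) != set(abu.protein_ids):
            raise ValidationError(
                f"treatment {name!r}: stability and abundance matrices disagree on proteins"
            )
        report.proteins_read[name] = int(len(sta.protein_ids))
        sta, dropped_s = sta.drop_incomplete()
        abu, dropped_a = abu.drop_incomplete()
        report.complete_cases[name] = int(len(sta.protein_ids))
        if dropped_s or dropped_a:
            logger.info("%s: dropped %d/%d incomplete rows (sta/abu)", name, dropped_s, dropped_a)
        diff = run_differential(
            sta,
            abu,
            condition_a=config.treated_condition,
            condition_b=config.control_condition,
            fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold,
            concordance_margin=config.concordance_margin,
        )
        if gt is not None:
            diff = diff.join(gt)
        diffs[name] = diff
        up_sets[name] = set(diff.index[diff["regulated_stability"] == REG_UP])
        down_sets[name] = set(diff.index[diff["regulated_stability"] == REG_DOWN])
        universes[name] = set(diff.index)
        report.regulated_up[name] = len(up_sets[name])
        report.regulated_down[name] = len(down_sets[name])
        diff.to_csv(out_dir / f"diff_{name}.tsv", sep="\t", float_format="%.6g")

    consensus_up = set.intersection(*up_sets.values()) if up_sets else set()
    consensus_down = set.intersection(*down_sets.values()) if down_sets else set()
    report.consensus_up = len(consensus_up)
    report.consensus_down = len(consensus_down)
    if not consensus_up and not consensus_down:
        msg = "consensus regulated set is empty"
        report.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)

    consensus = pd.DataFrame(
        {
            "protein_id": sorted(consensus_up) + sorted(consensus_down),
            "direction": [REG_UP] * len(consensus_up) + [REG_DOWN] * len(consensus_down),
        }
    )
    consensus.to_csv(out_dir / "consensus.tsv", sep="\t", index=False)

    if len(diffs) == 2:
        a, b = config.treatments[:2]
        universe = universes[a] & universes[b]
        for direction, sets_ in (("up", up_sets), ("down", down_sets)):
            res = overlap_test(
                population_n=len(universe),
                set_k=len(sets_[a] & universe),
                draw_n=len(sets_[b] & universe),
                overlap_k=len(sets_[a] & sets_[b] & universe),
            )
            pd.DataFrame([res.__dict__]).to_csv(
                out_dir / f"overlap_{direction}.tsv", sep="\t", index=False, float_format="%.6g"
            )

    if config.gmt_path:
        sets_ = read_gmt(config.gmt_path)
        mean_fc = pd.concat(
            [d["log2fc_stability"] for d in diffs.values()], axis=1
        ).mean(axis=1)
        enr = preranked_enrichment(
            mean_fc, sets_, n_perm=config.n_perm, seed=config.seed
        )
        enr.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    report.to_json(out_dir / "run_report.json")
    logger.info(
        "run done: consensus up=%d down=%d", report.consensus_up, report.consensus_down
    )
    return report
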