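"""Core containers shared by the simulation and analysis modules.

Quantification matrices are thin wrappers around a pandas DataFrame
(proteins x samples, log2 scale) that keep the sample annotation
(condition, replicate, channel) attached and enforce the column-name
dialect ``<condition>_<channel>_rep<k>`` used by every TSV this package
reads or writes.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ValidationError

_SAMPLE_RE = re.compile(r"^(?P<condition>.+)_(?P<channel>[A-Za-z0-9]+)_rep(?P<replicate>\d+)$")


@dataclass(frozen=True)
class MeltParams:
    """Parameters of a protein melting curve.

    tm : midpoint of the denaturable fraction, in deg C
    slope : steepness of the sigmoid transition, in 1/deg C (positive)
    plateau : non-denaturable fraction remaining soluble at high temperature
    """

    tm: float
    slope: float
    plateau: float = 0.0

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise InvalidArgumentError(f"slope must be > 0, got {self.slope}")
        if not (0.0 <= self.plateau < 1.0):
            raise InvalidArgumentError(f"plateau must be in [0, 1), got {self.plateau}")
        if not (30.0 <= self.tm <= 80.0):
            raise InvalidArgumentError(f"tm must be in [30, 80] deg C, got {self.tm}")


def sample_name(condition: str, channel: str, replicate: int) -> str:
    return f"{condition}_{channel}_rep{replicate}"


def parse_sample_name(name: str) -> tuple[str, str, int]:
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ValidationError(
            f"sample column {name!r} does not match '<condition>_<channel>_rep<k>'"
        )
    return m.group("condition"), m.group("channel"), int(m.group("replicate"))


@dataclass
class QuantMatrix:
    """Proteins x samples log2 quantification matrix for one channel.

    ``data`` is indexed by protein id; every column name follows the
    ``<condition>_<channel>_rep<k>`` dialect and must agree with
    ``channel``.
    """

    data: pd.DataFrame
    channel: str
    conditions: dict[str, str] = field(default_factory=dict)
    replicates: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dupes[:5]}")
        if not self.conditions:
            for col in self.data.columns:
                cond, channel, rep = parse_sample_name(col)
                if channel != self.channel:
                    raise ValidationError(
                        f"column {col!r} carries channel {channel!r}, expected {self.channel!r}"
                    )
                self.conditions[col] = cond
                self.replicates[col] = rep
        self.data.index.name = "protein_id"

    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    def samples_for(self, condition: str) -> list[str]:
        cols = [c for c, cond in self.conditions.items() if cond == condition]
        if not cols:
            raise InvalidArgumentError(f"no samples for condition {condition!r}")
        return cols

    def condition_names(self) -> list[str]:
        seen: list[str] = []
        for cond in self.conditions.values():
            if cond not in seen:
                seen.append(cond)
        return seen

    def is_complete(self) -> bool:
        return bool(np.isfinite(self.data.to_numpy()).all())

    def drop_incomplete(self) -> tuple["QuantMatrix", int]:
        """Complete-case filter; returns the filtered matrix and the
        number of dropped proteins."""
        keep = np.isfinite(self.data.to_numpy()).all(axis=1)
        dropped = int((~keep).sum())
        return (
            QuantMatrix(
                self.data.loc[keep].copy(),
                self.channel,
                dict(self.conditions),
                dict(self.replicates),
            ),
            dropped,
        )

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=True, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, channel: str) -> "QuantMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids in {path}: {dupes[:5]}")
        bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        if bad:
            raise ValidationError(f"non-numeric columns in {path}: {bad}")
        return cls(df, channel)


def lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise factors with unit mean and the
    requested coefficient of variation."""
    if cv < 0:
        raise InvalidArgumentError(f"noise_cv must be >= 0, got {cv}")
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)
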