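"""Sequence-context annotation of methyl sites and occupancy estimation.

Arginine methylation concentrates in glycine/arginine-rich (RGG/RG)
regions.  A methylated arginine is classified here as

* ``canonical_rg``  - the site R is immediately followed by G and sits
  in a run of repeated RG/RGG units (at least ``min_repeats`` units
  chained with inter-unit spacers of at most ``max_spacer`` residues,
  all within ``window`` residues of the site);
* ``noncanonical_rg`` - the site R is followed by G but the repeat
  condition fails (an isolated RG);
* ``non_rg`` - the next residue is not glycine (or the R is terminal).

Fractional occupancy (stoichiometry) is estimated from the depletion of
the unmodified counterpart peptide: if methylation converts a fraction
theta of molecules, the unmodified peptide signal drops by the same
fraction, so theta = 1 - (test/reference) after loading correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InvalidArgumentError

MOTIF_CANONICAL = "canonical_rg"
MOTIF_NONCANONICAL = "noncanonical_rg"
MOTIF_NON_RG = "non_rg"
MOTIF_NA = "not_applicable"


@dataclass
class MethylSiteRecord:
    protein_id: str
    position: int  # 1-based
    residue: str
    methyl_state: str
    flank: str
    motif_class: str


@dataclass
class OccupancyEstimate:
    theta: float
    method: str
    inputs: dict[str, float]


def _rg_units(sequence: str, start: int, stop: int) -> list[tuple[int, int]]:
    """0-based (start, end_inclusive) spans of RG/RGG units in a range.

    A unit is an R immediately followed by G, greedily extended by one
    further G (RGG).  Overlapping R positions each start their own unit.
    """
    units = []
    for j in range(max(start, 0), min(stop, len(sequence) - 1)):
        if sequence[j] == "R" and sequence[j + 1] == "G":
            end = j + 1
            if end + 1 < len(sequence) and sequence[end + 1] == "G":
                end += 1
            units.append((j, end))
    return units


def classify_arg_motif(
    sequence: str,
    position: int,
    max_spacer: int = 4,
    min_repeats: int = 2,
    window: int = 10,
) -> str:
    """Classify the RG context of a methyl-arginine (1-based position)."""
    if not (1 <= position <= len(sequence)):
        raise InvalidArgumentError(f"position {position} outside sequence of length {len(sequence)}")
    i = position - 1
    if sequence[i] != "R":
        raise InvalidArgumentError(f"residue at position {position} is {sequence[i]!r}, not R")
    if i + 1 >= len(sequence) or sequence[i + 1] != "G":
        return MOTIF_NON_RG

    units = _rg_units(sequence, i - window, i + window + 1)
    # keep units whose start lies within `window` residues of the site
    units = [u for u in units if abs(u[0] - i) <= window]
    units.sort()
    site_pos = next(k for k, u in enumerate(units) if u[0] == i)

    chain = 1
    # extend left
    k = site_pos
    while k > 0 and units[k][0] - units[k - 1][1] - 1 <= max_spacer:
        chain += 1
        k -= 1
    # extend right
    k = site_pos
    while k + 1 < len(units) and units[k + 1][0] - units[k][1] - 1 <= max_spacer:
        chain += 1
        k += 1
    return MOTIF_CANONICAL if chain >= min_repeats else MOTIF_NONCANONICAL


def flank_window(sequence: str, position: int, window: int = 10) -> str:
    """Residue window around a 1-based site, truncated at sequence ends."""
    i = position - 1
    return sequence[max(i - window, 0): i + window + 1]


def annotate_sites(
    sequences: dict[str, str],
    sites: pd.DataFrame,
    max_spacer: int = 4,
    min_repeats: int = 2,
    window: int = 10,
) -> pd.DataFrame:
    """Annotate a methyl-site table (protein_id, position, residue,
    methyl_state) with flank sequence and motif class.

    Lysine sites get ``not_applicable``: the RG taxonomy is specific to
    arginine.
    """
    records = []
    for row in sites.itertuples(index=False):
        seq = sequences.get(row.protein_id)
        if seq is None:
            raise InvalidArgumentError(f"no sequence for protein {row.protein_id!r}")
        pos = int(row.position)
        if not (1 <= pos <= len(seq)):
            raise InvalidArgumentError(
                f"{row.protein_id}: position {pos} outside sequence of length {len(seq)}"
            )
        if seq[pos - 1] != row.residue:
            raise InvalidArgumentError(
                f"{row.protein_id}: residue at {pos} is {seq[pos - 1]!r}, table says {row.residue!r}"
            )
        if row.residue == "R":
            motif = classify_arg_motif(seq, pos, max_spacer, min_repeats, window)
        else:
            motif = MOTIF_NA
        records.append(
            MethylSiteRecord(
                protein_id=row.protein_id,
                position=pos,
                residue=row.residue,
                methyl_state=row.methyl_state,
                flank=flank_window(seq, pos, window),
                motif_class=motif,
            )
        )
    return pd.DataFrame([r.__dict__ for r in records])


def motif_class_fractions(annotated: pd.DataFrame) -> pd.Series:
    """Fraction of Arg sites per motif class (canonical / non-canonical /
    non-RG)."""
    arg = annotated[annotated["residue"] == "R"]
    if arg.empty:
        raise InvalidArgumentError("no arginine sites to summarize")
    return arg["motif_class"].value_counts(normalize=True)


def estimate_occupancy(
    unmod_reference: float,
    unmod_test: float,
    loading_reference: float = 1.0,
    loading_test: float = 1.0,
) -> OccupancyEstimate:
    """Counterpart-decrease occupancy estimate.

    theta = 1 - (unmod_test / loading_test) / (unmod_reference /
    loading_reference), clamped to [0, 1].
    """
    vals = {
        "unmod_reference": unmod_reference,
        "unmod_test": unmod_test,
        "loading_reference": loading_reference,
        "loading_test": loading_test,
    }
    for name, v in vals.items():
        if not (v > 0):
            raise InvalidArgumentError(f"{name} must be > 0, got {v}")
    ratio = (unmod_test / loading_test) / (unmod_reference / loading_reference)
    theta = min(max(1.0 - ratio, 0.0), 1.0)
    return OccupancyEstimate(theta=theta, method="counterpart_decrease", inputs=vals)


def occupancy_from_table(
    table: pd.DataFrame,
    site: str,
    reference_condition: str,
    test_condition: str,
    loading: dict[str, float] | None = None,
) -> OccupancyEstimate:
    """Estimate occupancy for one site from a peptide-pair quantity table
    (columns: site, condition, peptidoform, quantity)."""
    loading = loading or {}
    sub = table[(table["site"] == site) & (table["peptidoform"] == "unmodified")]

    def mean_q(cond):
        q = sub.loc[sub["condition"] == cond, "quantity"]
        if q.empty:
            raise InvalidArgumentError(f"no unmodified quantities for {site!r} in {cond!r}")
        return float(q.mean())

    return estimate_occupancy(
        unmod_reference=mean_q(reference_condition),
        unmod_test=mean_q(test_condition),
        loading_reference=loading.get(reference_condition, 1.0),
        loading_test=loading.get(test_condition, 1.0),
    )
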