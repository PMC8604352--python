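"""Closed-form energy terms and trajectory-aggregation rules.

These are the pure-arithmetic pieces of the basis-set construction: the
SASA-fraction desolvation free energy, the rotamer- and coil-propensity
entropic terms, and the rules for averaging per-frame records from the
restrained sampling runs (trailing-window means, lowest-energy run selection,
all-glycine strain referencing).  Producing the per-frame records themselves
(SASA, restraint energies, rotamer placement from 3D structures) is out of
scope; they arrive as tabular input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, KT, AlphabetError, PaladinError, validate_residue


class InputError(PaladinError, ValueError):
    pass


class InsufficientDataError(PaladinError, ValueError):
    pass


#: Numeric per-frame columns of a trace, in canonical order.
TRACE_COLUMNS: tuple[str, ...] = ("vdw", "elec", "restraint", "sasa", "total")


@dataclass
class FrameEnergyTrace:
    """Per-frame record of one restrained sampling run.

    ``frames`` holds one row per frame with columns vdw, elec, restraint
    (kcal/mol), sasa (A^2) and total (total potential, kcal/mol).
    ``metadata`` typically records residue, site and rotamer index.
    """

    frames: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.frames.columns]
        if missing:
            raise InputError(f"trace missing columns: {missing}")
        if len(self.frames) < 2:
            raise InputError("trace must have at least 2 frames")
        vals = self.frames[list(TRACE_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise InputError("trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class SolvationScale:
    """Side-chain transfer free energies cyclohexane -> water, kcal/mol.

    Positive values mark hydrophobic side chains (transfer into water is
    unfavorable), so burying them yields a favorable (negative) desolvation
    energy.
    """

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = [a for a in AMINO_ACIDS if a not in self.values]
        if missing:
            raise InputError(f"solvation scale missing residues: {missing}")
        if not all(math.isfinite(v) for v in self.values.values()):
            raise InputError("solvation scale has non-finite entries")

    def __getitem__(self, res: str) -> float:
        return self.values[validate_residue(res)]


@dataclass
class PropensityScales:
    """Backbone-helical and side-chain-rotamer propensities per residue.

    ``helical`` maps residue -> helical propensity in [0, 1] (coil propensity
    is its complement).  ``rotamer`` maps residue -> (P_r, P_0): the
    probability of the lowest-energy rotamer in the beta-strand basin and the
    highest rotamer probability, with 0 < P_r <= P_0 <= 1.
    """

    helical: dict[str, float]
    rotamer: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for table, name in ((self.helical, "helical"), (self.rotamer, "rotamer")):
            missing = [a for a in AMINO_ACIDS if a not in table]
            if missing:
                raise InputError(f"{name} scale missing residues: {missing}")
        for res, h in self.helical.items():
            if not (0.0 <= h <= 1.0):
                raise InputError(f"helical propensity of {res} outside [0,1]: {h}")
        for res, (p_r, p_0) in self.rotamer.items():
            if not (0.0 < p_r <= p_0 <= 1.0):
                raise InputError(
                    f"rotamer probabilities of {res} must satisfy "
                    f"0 < P_r <= P_0 <= 1; got ({p_r}, {p_0})"
                )


def desolvation_energy(
    delta_sasa: float, sasa_total: float, dg_transfer: float
) -> float:
    """Burial-fraction-scaled transfer free energy, kcal/mol.

    E_desolv = -(delta_SASA_bind / SASA_total) * dG_chx->wat, where
    delta_sasa is the surface area buried on binding and sasa_total the total
    side-chain surface area.
    """
    if sasa_total <= 0:
        raise InputError(f"sasa_total must be > 0; got {sasa_total}")
    if not (0.0 <= delta_sasa <= sasa_total):
        raise InputError(
            f"delta_sasa must lie in [0, {sasa_total}]; got {delta_sasa}"
        )
    return -(delta_sasa / sasa_total) * dg_transfer


def sidechain_propensity_energy(p_r: float, p_0: float, kT: float = KT) -> float:
    """Entropic cost of restricting the side chain to one rotamer.

    E_r = -kT ln(P_r / P_0) with P_r the bound (lowest-energy) rotamer's
    probability and P_0 the most probable rotamer's; always >= 0.
    """
    if not (0.0 < p_r <= p_0 <= 1.0):
        raise InputError(
            f"require 0 < p_r <= p_0 <= 1; got p_r={p_r}, p_0={p_0}"
        )
    return -kT * math.log(p_r / p_0)


def backbone_propensity(window: str, scales: PropensityScales) -> float:
    """Mean coil propensity (1 - helical propensity) of a five-residue window."""
    if len(window) != 5:
        raise InputError(f"window must be exactly 5 residues; got {window!r}")
    return float(
        np.mean([1.0 - scales.helical[validate_residue(r)] for r in window])
    )


def _retained(trace: FrameEnergyTrace, discard_fraction: float) -> pd.DataFrame:
    if not (0.0 <= discard_fraction < 1.0):
        raise InputError(
            f"discard_fraction must be in [0, 1); got {discard_fraction}"
        )
    n = len(trace)
    keep = math.ceil((1.0 - discard_fraction) * n)
    if keep < 2:
        raise InsufficientDataError(
            f"fewer than 2 frames retained ({keep} of {n}); "
            "trace too short for averaging"
        )
    return trace.frames.iloc[n - keep :]


def aggregate_trace(
    trace: FrameEnergyTrace, discard_fraction: float = 2.0 / 5.0
) -> dict[str, tuple[float, float]]:
    """Trailing-window (mean, SEM) per term.

    By default the first 2/5 of frames are discarded as equilibration and the
    last 3/5 averaged; SEM is the sample standard deviation over retained
    frames divided by sqrt(n), without autocorrelation correction.
    """
    kept = _retained(trace, discard_fraction)
    out: dict[str, tuple[float, float]] = {}
    for col in TRACE_COLUMNS:
        x = kept[col].to_numpy(dtype=float)
        out[col] = (float(x.mean()), float(x.std(ddof=1) / math.sqrt(len(x))))
    return out


def select_lowest_energy_run(
    traces: list[FrameEnergyTrace], discard_fraction: float = 2.0 / 5.0
) -> int:
    """Index of the run with the lowest trailing-mean total potential energy.

    Ties resolve to the lowest index.
    """
    if not traces:
        raise InputError("need at least one trace")
    means = [aggregate_trace(t, discard_fraction)["total"][0] for t in traces]
    return int(np.argmin(means))


def strain_energy(
    trace: FrameEnergyTrace,
    glycine_reference_mean: float,
    discard_fraction: float = 2.0 / 5.0,
) -> float:
    """Backbone strain: mean restraint energy minus the all-glycine reference."""
    if not math.isfinite(glycine_reference_mean):
        raise InputError("glycine reference must be finite")
    mean, _ = aggregate_trace(trace, discard_fraction)["restraint"]
    return mean - glycine_reference_mean
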