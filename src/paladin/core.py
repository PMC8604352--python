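"""Core model containers: energy-term basis set, weights, and the combined PSSM.

The model scores a five-residue window bound across the five DnaK
substrate-binding sites (labelled -2, -1, 0, +1, +2, with site 0 the deep
central hydrophobic pocket).  Its basis set is a per-site, per-residue table
of six physical interaction terms (kcal/mol, referenced to an all-glycine
substrate); a small set of dimensionless weights combines those terms into a
working 5 x 20 position-specific scoring matrix (PSSM).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: The 20 standard amino acids, one-letter code, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Binding sites in N->C order of a forward-bound substrate.
SITES: tuple[int, ...] = (-2, -1, 0, 1, 2)
SITE_INDEX: dict[int, int] = {s: i for i, s in enumerate(SITES)}
SITE_LABELS: dict[int, str] = {-2: "-2", -1: "-1", 0: "0", 1: "+1", 2: "+2"}

#: The six per-residue physical interaction terms.
TERMS: tuple[str, ...] = (
    "vdw",
    "elec",
    "strain",
    "desolv_substrate",
    "desolv_site",
    "sc_propensity",
)
TERM_INDEX: dict[str, int] = {t: i for i, t in enumerate(TERMS)}

#: Thermal energy at ~300 K, kcal/mol; used for the orientation ambiguity
#: threshold and the rotamer-propensity formula.
KT: float = 0.6

ORIENTATIONS: tuple[str, str] = ("forward", "reverse")


class PaladinError(Exception):
    """Base class for model errors."""


class AlphabetError(PaladinError, ValueError):
    """A residue outside the 20-letter standard alphabet."""


class StructuralError(PaladinError, ValueError):
    """A container violating its structural invariants (missing cell, bad label...)."""


def validate_residue(res: str) -> str:
    res = res.upper()
    if len(res) != 1 or res not in AA_INDEX:
        raise AlphabetError(
            f"residue {res!r} is not one of the 20 standard amino acids "
            f"({AMINO_ACIDS})"
        )
    return res


def validate_site(site: int) -> int:
    if site not in SITE_INDEX:
        raise StructuralError(f"site {site!r} not in {SITES}")
    return site


@dataclass
class EnergyTermMatrix:
    """Per (site, residue, term) mean interaction energies, kcal/mol.

    Parameters
    ----------
    values : ndarray, shape (5, 20, 6)
        Mean energies indexed by (site, residue, term) following
        :data:`SITES`, :data:`AMINO_ACIDS` and :data:`TERMS` order.
    uncertainties : ndarray or None
        Standard errors of the mean, same indexing; optional.
    """

    values: np.ndarray
    uncertainties: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(SITES), len(AMINO_ACIDS), len(TERMS)):
            raise StructuralError(
                f"term matrix must have shape (5, 20, 6); got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise StructuralError("term matrix contains non-finite energies")
        if self.uncertainties is not None:
            self.uncertainties = np.asarray(self.uncertainties, dtype=float)
            if self.uncertainties.shape != self.values.shape:
                raise StructuralError("uncertainties shape mismatch")
            if not np.all(np.isfinite(self.uncertainties)) or np.any(
                self.uncertainties < 0
            ):
                raise StructuralError("uncertainties must be finite and >= 0")

    def energy(self, site: int, residue: str, term: str) -> float:
        site = validate_site(site)
        residue = validate_residue(residue)
        if term not in TERM_INDEX:
            raise StructuralError(f"unknown term {term!r}; expected one of {TERMS}")
        return float(
            self.values[SITE_INDEX[site], AA_INDEX[residue], TERM_INDEX[term]]
        )

    @classmethod
    def from_frame(cls, df) -> "EnergyTermMatrix":
        """Build from a tidy table with columns site, residue, term, value[, sem]."""
        import pandas as pd

        required = {"site", "residue", "term", "value"}
        missing = required - set(df.columns)
        if missing:
            raise StructuralError(f"term table missing columns: {sorted(missing)}")
        values = np.full((5, 20, 6), np.nan)
        sems = np.full((5, 20, 6), np.nan)
        have_sem = "sem" in df.columns and df["sem"].notna().all()
        for row in df.itertuples(index=False):
            site = validate_site(int(row.site))
            res = validate_residue(str(row.residue))
            term = str(row.term)
            if term not in TERM_INDEX:
                raise StructuralError(f"unknown term {term!r} in term table")
            idx = (SITE_INDEX[site], AA_INDEX[res], TERM_INDEX[term])
            if not np.isnan(values[idx]):
                raise StructuralError(
                    f"duplicate cell (site {site}, residue {res}, term {term})"
                )
            values[idx] = float(row.value)
            if have_sem:
                sems[idx] = float(row.sem)
        if np.isnan(values).any():
            s, r, t = np.argwhere(np.isnan(values))[0]
            raise StructuralError(
                f"missing cell (site {SITES[s]}, residue {AMINO_ACIDS[r]}, "
                f"term {TERMS[t]})"
            )
        return cls(values, sems if have_sem else None)

    def to_frame(self):
        """Tidy DataFrame with columns site, residue, term, value, sem."""
        import pandas as pd

        rows = []
        for si, site in enumerate(SITES):
            for ri, res in enumerate(AMINO_ACIDS):
                for ti, term in enumerate(TERMS):
                    rows.append(
                        {
                            "site": site,
                            "residue": res,
                            "term": term,
                            "value": self.values[si, ri, ti],
                            "sem": (
                                self.uncertainties[si, ri, ti]
                                if self.uncertainties is not None
                                else np.nan
                            ),
                        }
                    )
        return pd.DataFrame(rows)


@dataclass
class WeightSet:
    """Dimensionless weights combining the basis set into working scores.

    ``term_weights`` scale the six per-residue terms, ``site_weights`` the
    five binding sites, ``w_cp`` the whole-window backbone coil-propensity
    term, and ``e_reverse`` (kcal/mol) is a flat penalty added to
    reverse-orientation scores.
    """

    term_weights: dict[str, float]
    w_cp: float
    site_weights: dict[int, float]
    e_reverse: float

    def __post_init__(self) -> None:
        if set(self.term_weights) != set(TERMS):
            raise StructuralError(
                f"term_weights must cover exactly {TERMS}; got "
                f"{sorted(self.term_weights)}"
            )
        if set(self.site_weights) != set(SITES):
            raise StructuralError(
                f"site_weights must cover exactly {SITES}; got "
                f"{sorted(self.site_weights)}"
            )
        scalars = [self.w_cp, self.e_reverse, *self.term_weights.values(),
                   *self.site_weights.values()]
        if not all(np.isfinite(v) for v in scalars):
            raise StructuralError("weights must all be finite")

    def term_vector(self) -> np.ndarray:
        return np.array([self.term_weights[t] for t in TERMS], dtype=float)

    def site_vector(self) -> np.ndarray:
        return np.array([self.site_weights[s] for s in SITES], dtype=float)

    def copy(self) -> "WeightSet":
        return WeightSet(
            dict(self.term_weights), self.w_cp, dict(self.site_weights),
            self.e_reverse,
        )

    def to_dict(self) -> dict:
        return {
            "term_weights": dict(self.term_weights),
            "w_cp": self.w_cp,
            "site_weights": {SITE_LABELS[s]: w for s, w in self.site_weights.items()},
            "e_reverse": self.e_reverse,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "WeightSet":
        try:
            site_weights = {
                int(str(k).replace("+", "")): float(v)
                for k, v in d["site_weights"].items()
            }
            return cls(
                term_weights={k: float(v) for k, v in d["term_weights"].items()},
                w_cp=float(d["w_cp"]),
                site_weights=site_weights,
                e_reverse=float(d["e_reverse"]),
            )
        except KeyError as exc:
            raise StructuralError(f"weights mapping missing key: {exc}") from exc


def default_weights() -> WeightSet:
    """The published weight set.

    van der Waals 0.1, electrostatic 0.6, backbone strain 0, backbone
    conformational propensity 0, side-chain conformational propensity 0,
    desolvation of substrate side chain 1.0, desolvation of the binding site
    0.4; site weights 0.5/0.5/1.0/0.2/0.1 for sites -2/-1/0/+1/+2; reverse
    penalty 0 kcal/mol.
    """
    return WeightSet(
        term_weights={
            "vdw": 0.1,
            "elec": 0.6,
            "strain": 0.0,
            "desolv_substrate": 1.0,
            "desolv_site": 0.4,
            "sc_propensity": 0.0,
        },
        w_cp=0.0,
        site_weights={-2: 0.5, -1: 0.5, 0: 1.0, 1: 0.2, 2: 0.1},
        e_reverse=0.0,
    )


@dataclass
class PSSM:
    """Combined 5 x 20 position-specific scoring matrix, kcal/mol.

    Site weights are already folded in; scoring a window therefore sums one
    cell per site and never re-applies site weights.
    """

    scores: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(SITES), len(AMINO_ACIDS)):
            raise StructuralError(
                f"PSSM must have shape (5, 20); got {self.scores.shape}"
            )
        if not np.all(np.isfinite(self.scores)):
            raise StructuralError("PSSM contains non-finite scores")

    def score(self, site: int, residue: str) -> float:
        site = validate_site(site)
        residue = validate_residue(residue)
        return float(self.scores[SITE_INDEX[site], AA_INDEX[residue]])

    @classmethod
    def from_frame(cls, df, provenance: str = "") -> "PSSM":
        """Build from a DataFrame with site-label index and residue columns."""
        labels = [str(i).strip() for i in df.index]
        expected = [SITE_LABELS[s] for s in SITES]
        normalized = [lab if lab.startswith(("-", "+")) or lab == "0"
                      else f"+{lab}" for lab in labels]
        normalized = ["0" if lab in ("0", "+0") else lab for lab in normalized]
        if sorted(normalized) != sorted(expected):
            raise StructuralError(
                f"PSSM rows must be labelled {expected}; got {labels}"
            )
        cols = [str(c).strip().upper() for c in df.columns]
        missing = [a for a in AMINO_ACIDS if a not in cols]
        if missing:
            raise StructuralError(f"PSSM missing residue columns: {missing}")
        extra = [c for c in cols if c not in AA_INDEX]
        if extra:
            raise StructuralError(f"PSSM has unknown residue columns: {extra}")
        mat = np.empty((5, 20))
        for lab, (_, row) in zip(normalized, df.iterrows()):
            site = int(lab.replace("+", ""))
            for c, v in zip(cols, row):
                try:
                    mat[SITE_INDEX[site], AA_INDEX[c]] = float(v)
                except (TypeError, ValueError):
                    raise StructuralError(
                        f"non-numeric PSSM cell at site {lab}, residue {c}: {v!r}"
                    ) from None
        return cls(mat, provenance)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.scores,
            index=pd.Index([SITE_LABELS[s] for s in SITES], name="site"),
            columns=list(AMINO_ACIDS),
        )


def combine_terms(terms: EnergyTermMatrix, weights: WeightSet) -> PSSM:
    """Combine the raw basis set into the working PSSM.

    score(site, residue) = w_site * sum_term w_term * E(site, residue, term).
    The whole-window coil-propensity weight ``w_cp`` and the reverse penalty
    ``e_reverse`` are *not* folded in; they enter at scoring time.
    """
    tw = weights.term_vector()
    sw = weights.site_vector()
    scores = sw[:, None] * (terms.values @ tw)
    return PSSM(scores, provenance="combined from term matrix with weight set")
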