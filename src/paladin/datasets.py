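"""Access to packaged configuration tables and user-supplied reference data."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .core import PSSM, PaladinError
from .energetics import PropensityScales, SolvationScale
from .iodata import (
    Dataset,
    read_benchmark_table,
    read_propensity_scales,
    read_pssm,
    read_solvation_scale,
)


class MissingPublishedDataError(PaladinError, FileNotFoundError):
    """A published reference table has not been transcribed into the package."""


def _data_path(*parts: str) -> Path:
    return Path(resources.files("paladin").joinpath("data", *parts))


def default_solvation_scale() -> SolvationScale:
    """The shipped cyclohexane->water side-chain transfer free energies."""
    return read_solvation_scale(_data_path("solvation_chx_water.yaml"))


def default_propensity_scales() -> PropensityScales:
    """The shipped helical-propensity and rotamer-probability tables."""
    return read_propensity_scales(_data_path("propensity_scales.yaml"))


def published_data_dir() -> Path:
    """Directory where transcriptions of the published tables are expected."""
    return _data_path("published")


def load_published_pssm() -> PSSM:
    """Load the published combined 5x20 PSSM.

    The matrix is distributed as a spreadsheet supplement of the original
    article and is not redistributed with this package; transcribe it to
    ``data/published/pssm.tsv`` (see the README in that directory).
    """
    path = published_data_dir() / "pssm.tsv"
    if not path.exists():
        raise MissingPublishedDataError(
            f"published PSSM not found at {path}; transcribe the published "
            "5x20 score matrix supplement to TSV as documented in "
            f"{published_data_dir() / 'README.md'}"
        )
    return read_pssm(path)


def load_structure_benchmark() -> Dataset:
    """Load the structure benchmark of chaperone-bound peptides.

    Requires a user-supplied transcription at ``data/published/benchmark.tsv``
    (see the README in that directory).
    """
    path = published_data_dir() / "benchmark.tsv"
    if not path.exists():
        raise MissingPublishedDataError(
            f"structure benchmark not found at {path}; transcribe the "
            "published structure table to TSV as documented in "
            f"{published_data_dir() / 'README.md'}"
        )
    return read_benchmark_table(path)
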