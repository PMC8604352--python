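"""Synthetic inputs with planted ground truth.

Every external input the package consumes (raw term matrix, PSSM, classed
peptide array, structure benchmark, per-frame traces) can be generated here
deterministically from a seed, with the generating truth retained so tests
can check recovery.  The generators emulate the study conditions: 13-mers
tiled from client-protein sequences in four classes with proportions
strong 7% / binder 23% / neutral 21% / nonbinder 48%, sequences biased toward
the chaperone's motif (clusters of 3-5 branched hydrophobic residues flanked
by basic residues), site 0 dominant and hydrophobic in the basis set.

What these fixtures do NOT emulate: real fluorescence chemistry, correlated
array noise, or the true published energy values — passing tests on them
demonstrates the machinery (scoring, search, evaluation), not agreement with
the published matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AA_INDEX,
    AMINO_ACIDS,
    KT,
    SITES,
    TERMS,
    EnergyTermMatrix,
    PSSM,
    WeightSet,
    combine_terms,
    default_weights,
)
from .datasets import default_propensity_scales, default_solvation_scale
from .energetics import FrameEnergyTrace, sidechain_propensity_energy
from .evaluation import StructureBenchmarkRecord
from .scanner import scan_sequence, score_13mer
from .training import CLASSES, PeptideArrayRecord

#: Side-chain heavy-atom counts, used as a size proxy.
N_HEAVY = {
    "A": 1, "C": 2, "D": 4, "E": 5, "F": 7, "G": 0, "H": 6, "I": 4, "K": 5,
    "L": 4, "M": 4, "N": 4, "P": 3, "Q": 5, "R": 7, "S": 2, "T": 3, "V": 3,
    "W": 10, "Y": 8,
}
CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1}

HYDROPHOBIC = "LIVFM"
BASIC = "KR"

#: Background residue frequencies (roughly natural composition).
_BACKGROUND = {
    "A": 8.3, "C": 1.4, "D": 5.5, "E": 6.8, "F": 3.9, "G": 7.1, "H": 2.3,
    "I": 5.9, "K": 5.8, "L": 9.7, "M": 2.4, "N": 4.1, "P": 4.7, "Q": 3.9,
    "R": 5.5, "S": 6.7, "T": 5.4, "V": 6.9, "W": 1.1, "Y": 2.9,
}


@dataclass
class FixtureSpec:
    """Seeded sizes and conditions for all generators.

    Class proportions and dataset size default to the peptide-array study
    conditions (3477 13-mers from 37 proteins; 7/23/21/48% classes); noise is
    additive Gaussian on the truth score, 1 kcal/mol by default.
    """

    seed: int = 0
    n_proteins: int = 37
    n_peptides: int = 3477
    class_proportions: dict = field(
        default_factory=lambda: {
            "strong": 0.07, "binder": 0.23, "neutral": 0.21, "nonbinder": 0.48,
        }
    )
    noise_scale: float = 1.0
    n_benchmark: int = 50
    benchmark_length: tuple[int, int] = (7, 11)
    corruption_rate: float = 0.0
    n_traces: int = 5
    trace_frames: int = 300

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        # published proportions are rounded percentages summing to 0.99;
        # accept near-1 totals and renormalize
        if not math.isclose(total, 1.0, abs_tol=0.02):
            raise ValueError(f"class proportions must sum to ~1; got {total}")
        self.class_proportions = {
            c: v / total for c, v in self.class_proportions.items()
        }

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# per-site burial fraction / pocket depth / electrostatic field sign
_BURIAL = np.array([0.40, 0.60, 0.90, 0.50, 0.35])
_DEPTH = np.array([0.5, 0.7, 1.0, 0.5, 0.4])
_FIELD = np.array([-0.8, -0.5, 0.5, -1.0, -1.2])


def gen_pssm(spec: FixtureSpec) -> tuple[PSSM, EnergyTermMatrix]:
    """Deterministic synthetic basis set and its combined PSSM.

    Site 0 is the dominant hydrophobic pocket: burial fractions and van der
    Waals depth peak there, so branched hydrophobic residues are favored at
    sites -2..0 and the site-0 score spread exceeds the site +2 spread.
    """
    rng = spec.rng(1)
    solv = default_solvation_scale()
    prop = default_propensity_scales()
    values = np.zeros((5, 20, 6))
    for ri, res in enumerate(AMINO_ACIDS):
        dg = solv[res]
        nh = N_HEAVY[res]
        q = CHARGE.get(res, 0.0)
        p_r, p_0 = prop.rotamer[res]
        e_rot = sidechain_propensity_energy(p_r, p_0, KT)
        for si in range(5):
            values[si, ri, TERMS.index("vdw")] = -0.35 * nh * _DEPTH[si]
            values[si, ri, TERMS.index("elec")] = q * _FIELD[si]
            values[si, ri, TERMS.index("strain")] = 0.05 * nh * _DEPTH[si]
            values[si, ri, TERMS.index("desolv_substrate")] = -_BURIAL[si] * dg
            values[si, ri, TERMS.index("desolv_site")] = (
                -_BURIAL[si] * (nh / 10.0) * solv["N"] * 0.5
            )
            values[si, ri, TERMS.index("sc_propensity")] = e_rot
    values += rng.normal(0.0, 0.15, size=values.shape)
    sems = np.abs(rng.normal(0.0, 0.05, size=values.shape))
    terms = EnergyTermMatrix(values, sems)
    pssm = combine_terms(terms, default_weights())
    pssm.provenance = f"synthetic basis set, seed {spec.seed}"
    return pssm, terms


def _gen_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein with planted hydrophobic motifs flanked by basics."""
    aas = list(_BACKGROUND)
    probs = np.array([_BACKGROUND[a] for a in aas])
    probs = probs / probs.sum()
    seq = list(rng.choice(aas, size=length, p=probs))
    n_motifs = max(1, length // 40)
    for _ in range(n_motifs):
        k = int(rng.integers(3, 6))
        start = int(rng.integers(1, max(2, length - k - 1)))
        seq[start - 1] = str(rng.choice(list(BASIC)))
        for j in range(k):
            if start + j < length:
                seq[start + j] = str(rng.choice(list(HYDROPHOBIC)))
        if start + k < length:
            seq[start + k] = str(rng.choice(list(BASIC)))
    return "".join(seq)


def _class_counts(n: int, proportions: dict) -> dict[str, int]:
    """Largest-remainder apportionment of n records over the classes."""
    raw = {c: proportions[c] * n for c in CLASSES}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def gen_peptide_array(
    spec: FixtureSpec,
    truth_pssm: PSSM,
    truth_weights: WeightSet,
) -> tuple[list[PeptideArrayRecord], pd.DataFrame]:
    """Classed 13-mers tiled from synthetic proteins, scored by the truth model.

    Proteins are tiled into 13-mers with a 3-residue step; each 13-mer's truth
    score (forward-only window minimum) gets additive Gaussian noise and
    classes are assigned by rank so the class counts match the proportions.
    Returns the records plus a truth table (sequence, protein_id, true_score,
    noisy_score, label) for oracle tests.
    """
    rng = spec.rng(2)
    per_protein = math.ceil(spec.n_peptides / spec.n_proteins)
    length = 13 + 3 * (per_protein - 1)
    peptides: list[tuple[str, str]] = []
    for p in range(spec.n_proteins):
        protein = _gen_protein(rng, length)
        pid = f"synprot{p + 1:03d}"
        for i in range(0, len(protein) - 12, 3):
            peptides.append((pid, protein[i : i + 13]))
    peptides = peptides[: spec.n_peptides]
    true_scores = np.array(
        [score_13mer(seq, truth_pssm, truth_weights) for _, seq in peptides]
    )
    noisy = true_scores + rng.normal(0.0, spec.noise_scale, size=len(peptides))
    counts = _class_counts(len(peptides), spec.class_proportions)
    order = np.argsort(noisy, kind="stable")  # ascending: strongest binders first
    labels = np.empty(len(peptides), dtype=object)
    pos = 0
    for c in CLASSES:  # strong, binder, neutral, nonbinder: best to worst
        labels[order[pos : pos + counts[c]]] = c
        pos += counts[c]
    records = [
        PeptideArrayRecord(sequence=seq, label=labels[i], protein_id=pid)
        for i, (pid, seq) in enumerate(peptides)
    ]
    truth = pd.DataFrame(
        {
            "sequence": [seq for _, seq in peptides],
            "protein_id": [pid for pid, _ in peptides],
            "true_score": true_scores,
            "noisy_score": noisy,
            "label": labels,
        }
    )
    return records, truth


def gen_benchmark(
    spec: FixtureSpec,
    truth_pssm: PSSM,
    truth_weights: WeightSet | None = None,
) -> list[StructureBenchmarkRecord]:
    """Structure-benchmark records whose planted truth is the model argmin.

    Peptides are kept only when their orientation is unambiguous under the
    truth model (forward/reverse gap above kT), so at corruption rate 0 both
    register and orientation benchmarks are perfect by construction.  At a
    nonzero corruption rate, each record's observed (core, orientation) is
    replaced with a uniformly chosen different window with that probability.
    """
    rng = spec.rng(3)
    weights = truth_weights or default_weights()
    records: list[StructureBenchmarkRecord] = []
    lo, hi = spec.benchmark_length
    attempts = 0
    while len(records) < spec.n_benchmark and attempts < spec.n_benchmark * 200:
        attempts += 1
        length = int(rng.integers(lo, hi + 1))
        seq = _gen_protein(rng, length)
        result = scan_sequence(seq, truth_pssm, weights)
        best = result.best
        gap = abs(result.best_forward.total - result.best_reverse.total)
        if best is None or gap <= KT:
            continue
        start, orientation = best.start, best.orientation
        if rng.uniform() < spec.corruption_rate:
            options = [
                (s.start, s.orientation)
                for s in result.scores
                if (s.start, s.orientation) != (start, orientation)
            ]
            start, orientation = options[int(rng.integers(len(options)))]
        records.append(
            StructureBenchmarkRecord(
                sequence=seq,
                orientation=orientation,
                core=seq[start : start + 5],
                offset=start,
                structure_id=f"SYN{len(records) + 1:04d}",
            )
        )
    if len(records) < spec.n_benchmark:
        raise RuntimeError(
            "could not generate enough unambiguous benchmark peptides; "
            "check the truth model"
        )
    return records


def gen_traces(spec: FixtureSpec) -> list[FrameEnergyTrace]:
    """I.i.d. Gaussian per-frame traces with known means/sds in the metadata."""
    rng = spec.rng(4)
    base_means = {"vdw": -5.0, "elec": -1.0, "restraint": 2.0, "sasa": 80.0,
                  "total": -50.0}
    sds = {"vdw": 1.0, "elec": 0.5, "restraint": 0.3, "sasa": 5.0, "total": 3.0}
    traces = []
    for t in range(spec.n_traces):
        means = {
            k: v + float(rng.normal(0.0, abs(v) * 0.1 + 0.1))
            for k, v in base_means.items()
        }
        frames = pd.DataFrame(
            {
                k: rng.normal(means[k], sds[k], size=spec.trace_frames)
                for k in base_means
            }
        )
        traces.append(
            FrameEnergyTrace(
                frames,
                metadata={
                    "rotamer": t,
                    "true_means": means,
                    "true_sds": dict(sds),
                },
            )
        )
    return traces


def write_fixtures(spec: FixtureSpec, outdir) -> dict:
    """Emit every fixture file plus a manifest; returns the manifest dict."""
    from . import iodata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weights = default_weights()
    pssm, terms = gen_pssm(spec)
    records, truth = gen_peptide_array(spec, pssm, weights)
    benchmark = gen_benchmark(spec, pssm, weights)
    traces = gen_traces(spec)

    iodata.write_terms(terms, outdir / "terms.tsv")
    iodata.write_pssm(pssm, outdir / "pssm.tsv")
    iodata.write_weights(weights, outdir / "truth_weights.yaml")
    iodata.write_array_table(records, outdir / "array.tsv")
    truth.to_csv(outdir / "array_truth.tsv", sep="\t", index=False,
                 float_format="%.6f")
    iodata.write_benchmark_table(benchmark, outdir / "benchmark.tsv")
    trace_dir = outdir / "traces"
    trace_dir.mkdir(exist_ok=True)
    for i, tr in enumerate(traces):
        iodata.write_trace(tr, trace_dir / f"trace_{i:02d}.tsv")
    manifest = {
        "seed": spec.seed,
        "n_peptides": len(records),
        "n_proteins": spec.n_proteins,
        "n_benchmark": len(benchmark),
        "n_traces": len(traces),
        "noise_scale": spec.noise_scale,
        "corruption_rate": spec.corruption_rate,
        "class_proportions": spec.class_proportions,
        "truth_weights": weights.to_dict(),
        "files": [
            "terms.tsv", "pssm.tsv", "truth_weights.yaml", "array.tsv",
            "array_truth.tsv", "benchmark.tsv",
            *[f"traces/trace_{i:02d}.tsv" for i in range(len(traces))],
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
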