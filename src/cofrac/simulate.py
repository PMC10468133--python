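"""Seeded synthetic fixtures with planted ground truth for every stage.

The generators emulate the statistical structure of a co-fractionation
experiment on CSF lipoproteins: fluorescence traces as Gaussian peak
mixtures; ~28 sequential 1-ml fractions in which each protein elutes as one
(or, for scaffold apolipoproteins, several) Gaussian peaks; planted complexes
of 2–10 proteins sharing an elution profile; three replicate runs with
multiplicative lognormal intensity noise and random dropout; decoy and
contaminant rows; and block-structured protein→GO-term annotations with flip
noise.  Every generator is a pure function of its arguments including the
seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .networks import ReferenceComplexSet
from .peaks import GaussianComponent
from .proteome import ProteinGroupTable
from .enrichment import AnnotationTable
from .traces import ElutionTrace

__all__ = [
    "GroundTruth",
    "generate_trace",
    "generate_trace_suite",
    "generate_cofractionation",
    "generate_annotation",
]

# Relative detection floor: a Gaussian tail below 1e-3 of the protein's peak
# intensity is below the instrument's effective sensitivity and reads as 0.
DETECTION_FLOOR = 1e-3


@dataclass
class GroundTruth:
    """What was planted, for closed-loop recovery checks."""

    seed: int
    trace_components: tuple[GaussianComponent, ...] | None = None
    baseline: float | None = None
    noise_sd: float | None = None
    complexes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    scaffolds: tuple[str, ...] = ()
    elution: dict[str, list[dict]] = field(default_factory=dict)
    modules: dict[str, tuple[str, ...]] = field(default_factory=dict)
    module_terms: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def reference_complexes(self) -> ReferenceComplexSet:
        return ReferenceComplexSet(
            complexes={cid: frozenset(m) for cid, m in self.complexes.items()})

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "baseline": self.baseline,
            "noise_sd": self.noise_sd,
            "trace_components": None if self.trace_components is None else [
                {"amplitude": c.amplitude, "mean": c.mean, "sigma": c.sigma}
                for c in self.trace_components],
            "complexes": {k: sorted(v) for k, v in self.complexes.items()},
            "scaffolds": sorted(self.scaffolds),
            "modules": {k: sorted(v) for k, v in self.modules.items()},
            "module_terms": {k: sorted(v) for k, v in self.module_terms.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def generate_trace(components: Sequence[GaussianComponent], *,
                   baseline: float = 0.0, snr: float = np.inf,
                   grid: tuple[float, float, float] = (20.0, 60.0, 0.1),
                   seed: int = 0) -> tuple[ElutionTrace, GroundTruth]:
    """Gaussian-mixture trace plus i.i.d. noise with SD = peak max / snr."""
    if not components:
        raise InputError("need at least one component")
    if not snr > 0:
        raise InputError("snr must be positive")
    start, end, step = grid
    x = np.arange(start, end + step / 2, step)
    clean = np.full_like(x, float(baseline))
    for c in components:
        clean += c(x)
    peak = float(np.max(clean - baseline))
    rng = np.random.default_rng(seed)
    if np.isfinite(snr):
        noise_sd = peak / snr
        signal = clean + rng.normal(0.0, noise_sd, size=len(x))
    else:
        noise_sd = 0.0
        signal = clean
    truth = GroundTruth(seed=seed, trace_components=tuple(components),
                        baseline=float(baseline), noise_sd=noise_sd)
    return ElutionTrace(x, signal, label=f"synthetic(seed={seed})"), truth


def generate_trace_suite(n_traces: int, *, k_range: tuple[int, int] = (1, 6),
                         snr_range: tuple[float, float] = (30.0, 100.0),
                         amplitude_range: tuple[float, float] = (0.3, 1.0),
                         sigma_range: tuple[float, float] = (1.0, 2.5),
                         separation_factor: float = 2.0,
                         volume_range: tuple[float, float] = (25.0, 55.0),
                         grid: tuple[float, float, float] = (20.0, 60.0, 0.1),
                         seed: int = 0
                         ) -> list[tuple[ElutionTrace, GroundTruth]]:
    """Seeded batch of Gaussian-mixture traces for recovery benchmarking.

    Component count is uniform over ``k_range``; means are laid on a jittered
    grid guaranteeing pairwise separation ≥ ``separation_factor`` times the
    largest sigma; SNR is uniform over ``snr_range``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = volume_range
    out = []
    for i in range(n_traces):
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        sigmas = rng.uniform(*sigma_range, size=k)
        sep = separation_factor * float(sigmas.max())
        if (k - 1) * sep > hi - lo:
            raise InputError("volume range too small for requested separation")
        slack = (hi - lo) - (k - 1) * sep
        gaps = rng.uniform(0.0, slack / k, size=k)
        means = lo + np.cumsum(gaps) + sep * np.arange(k)
        comps = [GaussianComponent(float(rng.uniform(*amplitude_range)),
                                   float(mu), float(s))
                 for mu, s in zip(means, sigmas)]
        snr = float(rng.uniform(*snr_range))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        out.append(generate_trace(comps, snr=snr, grid=grid, seed=sub_seed))
    return out


def _gaussian_profile(fractions: np.ndarray, peaks: list[dict]) -> np.ndarray:
    prof = np.zeros(len(fractions))
    for p in peaks:
        prof += p["amplitude"] * np.exp(
            -0.5 * ((fractions - p["mean"]) / p["sigma"]) ** 2)
    return prof


def generate_cofractionation(n_proteins: int = 120,
                             fraction_range: tuple[int, int] = (23, 50),
                             n_complexes: int = 10,
                             complex_size_range: tuple[int, int] = (2, 10),
                             n_replicates: int = 3,
                             noise_cv: float = 0.05,
                             dropout: float = 0.05,
                             n_decoys: int = 8,
                             n_contaminants: int = 8,
                             scaffold_fraction: float = 0.05,
                             low_peptide_fraction: float = 0.15,
                             seed: int = 0
                             ) -> tuple[ProteinGroupTable, GroundTruth]:
    """Planted-complex co-fractionation table with replicate noise.

    Complex members share one Gaussian elution profile (means jittered by at
    most 0.2 fractions); background proteins elute independently; a few
    background proteins are scaffolds with 2–3 peaks.  Replicate intensity is
    the profile times lognormal noise with the given CV; dropout zeroes
    detected cells independently.  Low unique-peptide counts (failing the ≥3
    rule) are assigned among background proteins only — planted complexes
    emulate confidently identified proteins.
    """
    lo, hi = fraction_range
    if hi <= lo:
        raise InputError("fraction_range must be increasing")
    smin, smax = complex_size_range
    if n_proteins < n_complexes * smax:
        raise InputError(
            f"n_proteins={n_proteins} < n_complexes*max_size={n_complexes * smax}")
    rng = np.random.default_rng(seed)
    fractions = np.arange(lo, hi + 1)
    accessions = [f"P{10000 + i}" for i in range(n_proteins)]
    order = rng.permutation(n_proteins)

    sizes = rng.integers(smin, smax + 1, size=n_complexes)
    if sizes.sum() > n_proteins:
        raise InputError("complex sizes exceed the protein pool")
    complexes: dict[str, tuple[str, ...]] = {}
    elution: dict[str, list[dict]] = {}
    pos = 0
    for ci, size in enumerate(sizes):
        members = [accessions[order[pos + j]] for j in range(size)]
        pos += size
        mu = rng.uniform(lo + 2, hi - 2)
        sigma = rng.uniform(0.8, 1.6)
        complexes[f"CPX{ci + 1:03d}"] = tuple(sorted(members))
        for m in members:
            elution[m] = [{
                "amplitude": 10 ** rng.uniform(6.5, 8.5),
                "mean": mu + rng.uniform(-0.2, 0.2),
                "sigma": sigma,
            }]
    background = [accessions[order[i]] for i in range(pos, n_proteins)]
    n_scaffold = int(round(scaffold_fraction * len(background)))
    scaffolds = tuple(sorted(background[:n_scaffold]))
    for i, acc in enumerate(background):
        n_peaks = int(rng.integers(2, 4)) if i < n_scaffold else 1
        peaks = []
        for _ in range(n_peaks):
            peaks.append({
                "amplitude": 10 ** rng.uniform(6.5, 8.5) / n_peaks,
                "mean": rng.uniform(lo + 1, hi - 1),
                "sigma": rng.uniform(0.8, 2.0),
            })
        elution[acc] = peaks

    # unique peptides: low counts drawn among background (non-scaffold) rows
    peptides = pd.Series(rng.integers(3, 13, size=n_proteins), index=accessions)
    eligible = background[n_scaffold:]
    n_low = int(round(low_peptide_fraction * n_proteins))
    n_low = min(n_low, len(eligible))
    low_idx = rng.choice(len(eligible), size=n_low, replace=False)
    for i in low_idx:
        peptides[eligible[i]] = int(rng.integers(1, 3))

    # extra decoy / contaminant rows with background-like elution
    extra_rows = []
    for i in range(n_decoys):
        extra_rows.append((f"REV_Q{90000 + i}", True, False))
    for i in range(n_contaminants):
        extra_rows.append((f"CON__P{80000 + i}", False, True))
    for acc, _, _ in extra_rows:
        elution[acc] = [{
            "amplitude": 10 ** rng.uniform(6.5, 8.5),
            "mean": rng.uniform(lo + 1, hi - 1),
            "sigma": rng.uniform(0.8, 2.0),
        }]

    all_ids = accessions + [acc for acc, _, _ in extra_rows]
    profiles = np.vstack([_gaussian_profile(fractions, elution[a])
                          for a in all_ids])
    floor = DETECTION_FLOOR * profiles.max(axis=1, keepdims=True)
    profiles = np.where(profiles < floor, 0.0, profiles)

    if noise_cv > 0:
        s = np.sqrt(np.log1p(noise_cv ** 2))
        factors = rng.lognormal(-0.5 * s * s, s,
                                size=(len(all_ids), len(fractions), n_replicates))
    else:
        factors = np.ones((len(all_ids), len(fractions), n_replicates))
    reps = profiles[:, :, None] * factors
    if dropout > 0:
        drop = rng.random(reps.shape) < dropout
        reps = np.where(drop, 0.0, reps)

    meta = pd.DataFrame({
        "gene": [f"GENE{i}" for i in range(len(all_ids))],
        "unique_peptides": [int(peptides.get(a, rng.integers(3, 13)))
                            for a in all_ids],
        "is_decoy": [d for a in all_ids
                     for d in [a.startswith("REV_")]],
        "is_contaminant": [c for a in all_ids
                           for c in [a.startswith("CON__")]],
    }, index=pd.Index(all_ids, name="protein_id"))
    cols = pd.MultiIndex.from_product(
        [fractions.tolist(), range(1, n_replicates + 1)],
        names=["fraction", "replicate"])
    lfq = pd.DataFrame(
        reps.reshape(len(all_ids), -1), index=meta.index, columns=cols)
    table = ProteinGroupTable(meta=meta, lfq=lfq)
    truth = GroundTruth(seed=seed, complexes=complexes, scaffolds=scaffolds,
                        elution=elution)
    return table, truth


def generate_annotation(proteins: Sequence[str], n_modules: int = 10,
                        terms_per_module: int = 8, flip_noise: float = 0.0,
                        background_proteins: Sequence[str] = (),
                        background_rate: float = 0.01,
                        seed: int = 0) -> tuple[AnnotationTable, GroundTruth]:
    """Block-structured annotation: module proteins × module terms, flipped
    with probability ``flip_noise`` per cell.

    ``background_proteins`` (disjoint from ``proteins``) model the wider
    annotation universe an over-representation test needs: they carry each
    term independently at the low ``background_rate``.
    """
    if not 0 <= flip_noise < 0.5:
        raise InputError("flip_noise must be in [0, 0.5)")
    if set(background_proteins) & set(proteins):
        raise InputError("background proteins must be disjoint from proteins")
    proteins = list(proteins)
    if len(proteins) < n_modules:
        raise InputError("fewer proteins than modules")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(proteins))
    groups = np.array_split(order, n_modules)
    modules: dict[str, tuple[str, ...]] = {}
    module_terms: dict[str, tuple[str, ...]] = {}
    all_terms: list[str] = []
    for mi, grp in enumerate(groups):
        terms = tuple(f"GO:{7000000 + mi * terms_per_module + t:07d}"
                      for t in range(terms_per_module))
        modules[f"module_{mi + 1:02d}"] = tuple(sorted(proteins[i] for i in grp))
        module_terms[f"module_{mi + 1:02d}"] = terms
        all_terms.extend(terms)
    member = np.zeros((len(proteins), len(all_terms)), dtype=bool)
    for mi, grp in enumerate(groups):
        t0 = mi * terms_per_module
        for i in grp:
            member[i, t0:t0 + terms_per_module] = True
    if flip_noise > 0:
        flips = rng.random(member.shape) < flip_noise
        member ^= flips
    rows = [{"protein": proteins[i], "term_id": all_terms[j],
             "term_name": f"synthetic process {all_terms[j][-4:]}"}
            for i, j in zip(*np.nonzero(member))]
    if len(background_proteins):
        bg = rng.random((len(background_proteins), len(all_terms)))
        rows += [{"protein": background_proteins[i], "term_id": all_terms[j],
                  "term_name": f"synthetic process {all_terms[j][-4:]}"}
                 for i, j in zip(*np.nonzero(bg < background_rate))]
    table = AnnotationTable(df=pd.DataFrame(
        rows, columns=["protein", "term_id", "term_name"]))
    truth = GroundTruth(seed=seed, modules=modules, module_terms=module_terms)
    return table, truth
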