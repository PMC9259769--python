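"""Seeded generators for every input the pipeline consumes.

A homolog family stands in for a sequence database, a simulated peak list
for the measured proteolytic masses, and parametric curves for the kinetics
datasets. Every generator is a pure function of its spec (including the RNG
seed), so pipeline stages are testable offline against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import DigestParams, Peptide, digest, peptide_mass
from .pmf import Peak, PeakList

__all__ = [
    "FamilySpec",
    "PeakSimSpec",
    "KineticsSimSpec",
    "gen_homolog_family",
    "gen_peaklist",
    "gen_kinetics",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_NON_K = AMINO_ACIDS.replace("K", "")


@dataclass(frozen=True)
class FamilySpec:
    """A truth protein plus homologs at controlled pairwise identity.

    Homologs differ from the truth by substitutions only (uniform over the
    other 19 residues), so peptide coordinates transfer directly between
    family members. ``fragment_length_range`` controls the spacing of K
    residues in the truth, guaranteeing a digestible peptide pattern with
    bench-realistic fragment sizes.
    """

    length: int = 206
    n_homologs: int = 30
    identities: tuple[float, ...] | float = (0.65, 0.90)  # range or single value
    fragment_length_range: tuple[int, int] = (5, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 50:
            raise ValueError("length must be >= 50")
        ids = self.identities if isinstance(self.identities, tuple) else (self.identities,)
        if any(not 0.0 < x <= 1.0 for x in ids):
            raise ValueError("identities must lie in (0, 1]")


@dataclass(frozen=True)
class FamilyTruth:
    truth: str
    homologs: dict[str, str]
    realized_identity: dict[str, float]


def _random_protein(rng: np.random.Generator, length: int,
                    frag_range: tuple[int, int]) -> str:
    """Random sequence assembled as Lys-terminated fragments of random length."""
    out: list[str] = []
    while len(out) < length:
        n = int(rng.integers(frag_range[0], frag_range[1] + 1))
        out.extend(rng.choice(list(_NON_K), size=n))
        out.append("K")
    return "".join(out[:length])


def gen_homolog_family(spec: FamilySpec) -> FamilyTruth:
    """Truth sequence plus homologs whose identity to the truth is controlled.

    The number of substituted positions is round((1 - target) * L) and every
    substitution changes the residue, so the realized identity equals the
    target to within rounding (well inside +-3 points).
    """
    rng = np.random.default_rng(spec.seed)
    truth = _random_protein(rng, spec.length, spec.fragment_length_range)
    if isinstance(spec.identities, tuple) and len(spec.identities) == 2:
        targets = rng.uniform(spec.identities[0], spec.identities[1],
                              size=spec.n_homologs)
    else:
        val = spec.identities if isinstance(spec.identities, float) else spec.identities[0]
        targets = np.full(spec.n_homologs, val)
    homologs: dict[str, str] = {}
    realized: dict[str, float] = {}
    for h, target in enumerate(targets):
        n_sub = int(round((1.0 - target) * spec.length))
        if n_sub > spec.length:
            raise ValueError("unreachable identity target")
        pos = rng.choice(spec.length, size=n_sub, replace=False)
        seq = list(truth)
        for p in pos:
            choices = [a for a in AMINO_ACIDS if a != seq[p]]
            seq[p] = rng.choice(choices)
        name = f"homolog_{h:03d}"
        homologs[name] = "".join(seq)
        realized[name] = sum(a == b for a, b in zip(truth, homologs[name])) / spec.length
    return FamilyTruth(truth=truth, homologs=homologs, realized_identity=realized)


@dataclass(frozen=True)
class PeakSimSpec:
    """Measurement model for a proteolytic peak list.

    Peaks are theoretical [M+H]+ monoisotopic masses plus Gaussian error of
    ``mass_sigma_da`` (absolute Da, mirroring tenth-Da rounding of bench
    tables), thinned by ``dropout``, with uniform-random contaminant peaks
    added. ``missed_retention`` gives the probability that a peptide with a
    given missed-cleavage count shows up at all.
    """

    mass_sigma_da: float = 0.2
    dropout: float = 0.1
    contaminants: int = 0
    missed_retention: tuple[float, ...] = (1.0, 0.3)
    contaminant_mass_range: tuple[float, float] = (500.0, 3000.0)
    digest_params: DigestParams = field(default_factory=lambda: DigestParams(max_missed=1))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass_sigma_da < 0:
            raise ValueError("mass sigma must be >= 0")
        probs = (self.dropout, *self.missed_retention)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedPeaks:
    peaks: PeakList
    answer_key: dict[str, Peptide | str]  # peak_id -> true peptide or "contaminant"


def gen_peaklist(truth: str, spec: PeakSimSpec) -> SimulatedPeaks:
    """Simulate the measured peak list of a Lys-C digest of ``truth``."""
    if "K" not in truth[:-1] and not truth.endswith("K"):
        raise ValueError("truth sequence is not digestible (no K)")
    rng = np.random.default_rng(spec.seed)
    peptides = digest(truth, spec.digest_params, source_id="truth")
    peaks: list[Peak] = []
    key: dict[str, Peptide | str] = {}
    i = 0
    for pep in peptides:
        nm = pep.missed_cleavages
        keep = spec.missed_retention[nm] if nm < len(spec.missed_retention) else 0.0
        if rng.random() >= keep:
            continue
        if rng.random() < spec.dropout:
            continue
        mass = peptide_mass(pep.sequence, "monoisotopic", "MH_plus")
        mass += rng.normal(0.0, spec.mass_sigma_da) if spec.mass_sigma_da > 0 else 0.0
        pid = f"peak_{i:03d}"
        peaks.append(Peak(peak_id=pid, mass_da=float(mass)))
        key[pid] = pep
        i += 1
    for c in range(spec.contaminants):
        pid = f"contaminant_{c:03d}"
        peaks.append(Peak(peak_id=pid,
                          mass_da=float(rng.uniform(*spec.contaminant_mass_range))))
        key[pid] = "contaminant"
    return SimulatedPeaks(peaks=PeakList(tuple(peaks)), answer_key=key)


@dataclass(frozen=True)
class KineticsSimSpec:
    """Truth parameters for simulated kinetics experiments.

    Defaults are the bench-scale values characterized for the snail GST pair:
    Michaelian GSH kinetics with Km 0.22 mM, biphasic GSH kinetics with
    regime Kms 0.15/0.61 mM split at 0.5 mM, IC50 2.35 uM, activation energy
    3.75 kcal/mol and a 15-min half-life at 50 C. Noise is multiplicative
    lognormal with coefficient of variation ``noise_cv``.
    """

    km_mm: float = 0.22
    vmax_mm: float = 3.3
    km_low: float = 0.15
    km_high: float = 0.61
    vmax_low: float = 2.0
    vmax_high: float = 3.3
    breakpoint_mm: float = 0.5
    ic50_um: float = 2.35
    ea_kcal_mol: float = 3.75
    t_half_min: float = 15.0
    noise_cv: float = 0.0
    conc_grid: tuple[float, ...] = (0.025, 0.05, 0.1, 0.2, 0.35, 0.5,
                                    0.75, 1.0, 1.5, 2.5, 3.5, 5.0)
    inhibitor_grid: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0)
    temp_grid_c: tuple[float, ...] = (25.0, 30.0, 37.0, 45.0, 52.0, 60.0)
    time_grid_min: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0)
    seed: int = 0

    def __post_init__(self) -> None:
        truths = (self.km_mm, self.vmax_mm, self.km_low, self.km_high,
                  self.ic50_um, self.ea_kcal_mol, self.t_half_min)
        if any(x <= 0 for x in truths):
            raise ValueError("all truth parameters must be positive")


def _noisy(rng: np.random.Generator, y: np.ndarray, cv: float) -> np.ndarray:
    if cv <= 0:
        return y
    sigma = np.sqrt(np.log1p(cv ** 2))
    return y * rng.lognormal(-sigma ** 2 / 2.0, sigma, size=y.shape)


def gen_kinetics(spec: KineticsSimSpec, kind: str) -> pd.DataFrame:
    """Simulate one kinetics dataset; truth parameters ride in ``df.attrs``.

    kind: 'mm' | 'biphasic' | 'ic50' | 'arrhenius' | 'decay'.
    """
    rng = np.random.default_rng(spec.seed)
    if kind == "mm":
        s = np.asarray(spec.conc_grid)
        v = spec.vmax_mm * s / (spec.km_mm + s)
        df = pd.DataFrame({"concentration_mm": s,
                           "velocity": _noisy(rng, v, spec.noise_cv)})
        df.attrs["truth"] = {"km": spec.km_mm, "vmax": spec.vmax_mm}
    elif kind == "biphasic":
        s = np.asarray(spec.conc_grid)
        low = s <= spec.breakpoint_mm
        v = np.where(low,
                     spec.vmax_low * s / (spec.km_low + s),
                     spec.vmax_high * s / (spec.km_high + s))
        df = pd.DataFrame({"concentration_mm": s,
                           "velocity": _noisy(rng, v, spec.noise_cv)})
        df.attrs["truth"] = {"km_low": spec.km_low, "km_high": spec.km_high,
                             "breakpoint": spec.breakpoint_mm}
    elif kind == "ic50":
        i = np.asarray(spec.inhibitor_grid)
        act = 100.0 / (1.0 + i / spec.ic50_um)
        df = pd.DataFrame({"inhibitor_um": i,
                           "percent_activity": _noisy(rng, act, spec.noise_cv)})
        df.attrs["truth"] = {"ic50_um": spec.ic50_um}
    elif kind == "arrhenius":
        t_k = np.asarray(spec.temp_grid_c) + 273.15
        k = np.exp(10.0 - spec.ea_kcal_mol / (0.0019872 * t_k))
        df = pd.DataFrame({"temperature_k": t_k,
                           "rate": _noisy(rng, k, spec.noise_cv)})
        df.attrs["truth"] = {"ea_kcal_mol": spec.ea_kcal_mol}
    elif kind == "decay":
        t = np.asarray(spec.time_grid_min)
        act = 100.0 * np.exp(-np.log(2.0) / spec.t_half_min * t)
        df = pd.DataFrame({"time_min": t,
                           "percent_activity": _noisy(rng, act, spec.noise_cv)})
        df.attrs["truth"] = {"t_half_min": spec.t_half_min}
    else:
        raise ValueError(f"unknown kinetics kind {kind!r}")
    df.attrs["seed"] = spec.seed
    df.attrs["noise_cv"] = spec.noise_cv
    return df
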