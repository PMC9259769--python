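"""Peptide-mass-fingerprint matching.

A measured peak list is explained by querying a mass-sorted index of
theoretical protease digests of a candidate-sequence database. Candidate
peptides per peak are ranked by missed cleavages, source-homology score,
mass error and finally sequence, so results are a deterministic total order.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

from .chem import DigestParams, InvalidSequenceError, Peptide, digest, peptide_mass

__all__ = [
    "Peak",
    "PeakList",
    "MatchParams",
    "PeptideMatch",
    "TheoreticalIndex",
    "build_theoretical_index",
    "match_peaks",
    "rank_matches",
    "rank_key",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    peak_id: str
    mass_da: float
    tolerance_da: float | None = None

    def __post_init__(self) -> None:
        if self.mass_da <= 0:
            raise ValueError(f"peak {self.peak_id}: mass must be positive")


@dataclass(frozen=True)
class PeakList:
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        ids = [p.peak_id for p in self.peaks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate peak ids")

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class MatchParams:
    """Matching tolerance and the mass convention of the index.

    The default tolerance of 1.0 Da absolute suits peak lists rounded to
    tenths of a dalton; ``tolerance_ppm`` switches to relative tolerance.
    """

    tolerance_da: float = 1.0
    tolerance_ppm: float | None = None
    mass_kind: str = "monoisotopic"
    charge_form: str = "MH_plus"
    digest_params: DigestParams = field(default_factory=DigestParams)

    def __post_init__(self) -> None:
        if self.tolerance_da <= 0:
            raise ValueError("tolerance must be positive")

    def tolerance_for(self, mass_da: float) -> float:
        if self.tolerance_ppm is not None:
            return mass_da * self.tolerance_ppm * 1e-6
        return self.tolerance_da


@dataclass(frozen=True)
class PeptideMatch:
    """One candidate explanation of one peak."""

    peak_id: str
    peptide: Peptide
    theoretical_mass: float
    measured_mass: float
    source_score: float = 0.0

    @property
    def delta(self) -> float:
        return self.theoretical_mass - self.measured_mass

    @property
    def missed_cleavages(self) -> int:
        return self.peptide.missed_cleavages


class TheoreticalIndex:
    """Mass-sorted index over all digest peptides of a sequence database."""

    def __init__(self, masses: list[float], peptides: list[Peptide],
                 params: MatchParams):
        order = sorted(range(len(masses)), key=lambda i: masses[i])
        self._masses = [masses[i] for i in order]
        self._peptides = [peptides[i] for i in order]
        self.params = params

    def __len__(self) -> int:
        return len(self._masses)

    def query(self, lo: float, hi: float) -> list[tuple[float, Peptide]]:
        """All (mass, peptide) with lo <= mass <= hi."""
        i = bisect.bisect_left(self._masses, lo)
        j = bisect.bisect_right(self._masses, hi)
        return list(zip(self._masses[i:j], self._peptides[i:j]))

    def items(self):
        return zip(self._masses, self._peptides)


def build_theoretical_index(
    database: dict[str, str],
    params: MatchParams | None = None,
) -> TheoreticalIndex:
    """Digest every database sequence and index the peptides by mass.

    Invalid sequences are skipped with a logged warning rather than silently
    dropped or fatally rejected.
    """
    params = params or MatchParams()
    if not database:
        raise ValueError("empty sequence database")
    masses: list[float] = []
    peptides: list[Peptide] = []
    for source_id, seq in database.items():
        try:
            peps = digest(seq, params.digest_params, source_id=source_id)
        except InvalidSequenceError as exc:
            log.warning("skipping sequence %s: %s", source_id, exc)
            continue
        for p in peps:
            masses.append(
                peptide_mass(p.sequence, params.mass_kind, params.charge_form)
            )
            peptides.append(p)
    return TheoreticalIndex(masses, peptides, params)


def match_peaks(
    peaks: PeakList,
    index: TheoreticalIndex,
    params: MatchParams | None = None,
    source_scores: dict[str, float] | None = None,
) -> tuple[dict[str, list[PeptideMatch]], list[str]]:
    """Explain each peak by index peptides within tolerance.

    Returns (matches per peak id, ids of unexplained peaks). Every returned
    match satisfies |theoretical - measured| <= tolerance.
    """
    params = params or index.params
    source_scores = source_scores or {}
    matched: dict[str, list[PeptideMatch]] = {}
    unexplained: list[str] = []
    for peak in peaks:
        tol = peak.tolerance_da or params.tolerance_for(peak.mass_da)
        hits = [
            PeptideMatch(
                peak_id=peak.peak_id,
                peptide=pep,
                theoretical_mass=m,
                measured_mass=peak.mass_da,
                source_score=source_scores.get(pep.source_id or "", 0.0),
            )
            for m, pep in index.query(peak.mass_da - tol, peak.mass_da + tol)
        ]
        if hits:
            matched[peak.peak_id] = rank_matches(hits)
        else:
            unexplained.append(peak.peak_id)
    return matched, unexplained


def rank_key(match: PeptideMatch) -> tuple:
    """Total order: fewer missed cleavages, higher source score, smaller
    |mass error|, then lexicographic sequence for determinism."""
    return (
        match.missed_cleavages,
        -match.source_score,
        abs(match.delta),
        match.peptide.sequence,
        match.peptide.source_id or "",
        match.peptide.start or 0,
    )


def rank_matches(matches: list[PeptideMatch]) -> list[PeptideMatch]:
    """Order candidate matches for one peak (a permutation of the input)."""
    return sorted(matches, key=rank_key)
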