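"""Position-constrained scaffold assembly.

Anchored peptides are overlaid onto a 1..L coordinate system, agreeing
overlaps are merged, zero-missed-cleavage sub-peptides are absorbed into the
longer fragments that contain them, and conflicting candidates are resolved
deterministically by the same ranking used for peak matching. Unassigned
positions become the unknown symbol ``X``; maximal runs of ``X`` are the
scaffold's gap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem import (
    UNKNOWN,
    MolecularWeight,
    Peptide,
    isoelectric_point,
    molecular_weight,
)

__all__ = [
    "AnchoredPeptide",
    "Placement",
    "Scaffold",
    "ScaffoldProperties",
    "CheckResult",
    "PlacementConflictError",
    "place_peptides",
    "resolve_overlaps",
    "build_scaffold",
    "residue_check",
]


class PlacementConflictError(ValueError):
    """Two equally ranked peptides demand different residues at one position."""


@dataclass(frozen=True)
class AnchoredPeptide:
    """A peptide with an assigned scaffold interval.

    ``anchor_kind`` is 'mass_match' for fingerprint-derived fragments or
    'edman' for directly sequenced ones (which bypass mass matching).
    A printed interval may disagree with the sequence length; placement
    tolerates a C-terminal overhang of at most ``max_overhang`` residues
    (clipped) and rejects anything worse.
    """

    peptide: Peptide
    start: int
    end: int
    anchor_kind: str = "mass_match"
    label: str | None = None
    source_score: float = 0.0
    mass_delta: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad interval {self.start}-{self.end}")
        if self.anchor_kind not in ("mass_match", "edman"):
            raise ValueError(f"unknown anchor_kind {self.anchor_kind!r}")

    @property
    def name(self) -> str:
        return self.label or f"{self.peptide.sequence}@{self.start}"

    @property
    def interval_length(self) -> int:
        return self.end - self.start + 1

    @property
    def overhang(self) -> int:
        return max(0, len(self.peptide.sequence) - self.interval_length)

    def rank_sort_key(self) -> tuple:
        """Edman anchors first, then the peak-match ranking order."""
        return (
            0 if self.anchor_kind == "edman" else 1,
            self.peptide.missed_cleavages,
            -self.source_score,
            abs(self.mass_delta),
            self.peptide.sequence,
            self.start,
        )


@dataclass
class Placement:
    """Mutable overlay of peptides on a scaffold coordinate system."""

    length: int
    residues: list[str] = field(default_factory=list)
    provenance: dict[int, str] = field(default_factory=dict)
    placed: list[AnchoredPeptide] = field(default_factory=list)
    conflicts: list[dict] = field(default_factory=list)
    rejected: list[dict] = field(default_factory=list)
    absorbed: list[dict] = field(default_factory=list)
    resolved: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            self.residues = [UNKNOWN] * self.length

    def _effective_sequence(self, ap: AnchoredPeptide, max_overhang: int) -> str | None:
        if ap.end > self.length:
            self.rejected.append(
                {"peptide": ap.name, "reason": f"interval end {ap.end} beyond scaffold length {self.length}"}
            )
            return None
        if ap.overhang > max_overhang:
            self.rejected.append(
                {"peptide": ap.name,
                 "reason": f"sequence ({len(ap.peptide.sequence)} aa) exceeds interval "
                           f"{ap.start}-{ap.end} by {ap.overhang} > {max_overhang}"}
            )
            return None
        return ap.peptide.sequence[: ap.interval_length]

    def overlay(self, ap: AnchoredPeptide, max_overhang: int, strict: bool) -> bool:
        """Write one peptide left-aligned into its interval.

        Disagreements with already-written residues are recorded; in strict
        mode (used by the rank-ordered resolver) a disagreeing peptide is
        rejected wholesale instead of partially written.
        """
        seq = self._effective_sequence(ap, max_overhang)
        if seq is None:
            return False
        clashes = []
        for off, residue in enumerate(seq):
            pos = ap.start + off
            existing = self.residues[pos - 1]
            if existing != UNKNOWN and existing != residue:
                clashes.append(
                    {"position": pos, "existing": existing, "wanted": residue,
                     "existing_peptide": self.provenance.get(pos), "peptide": ap.name}
                )
        if clashes:
            self.conflicts.extend(clashes)
            if strict:
                self.rejected.append(
                    {"peptide": ap.name,
                     "reason": "residue conflict at position(s) "
                               + ",".join(str(c["position"]) for c in clashes)}
                )
                return False
        for off, residue in enumerate(seq):
            pos = ap.start + off
            if self.residues[pos - 1] == UNKNOWN:
                self.residues[pos - 1] = residue
                self.provenance[pos] = ap.name
        self.placed.append(ap)
        return True


def place_peptides(
    anchored: list[AnchoredPeptide],
    length: int,
    max_overhang: int = 1,
) -> Placement:
    """Draft placement: peptides written in input order, conflicts reported.

    Nothing is overwritten; disagreeing residues are listed in
    ``placement.conflicts`` for ``resolve_overlaps`` to arbitrate.
    """
    placement = Placement(length=length)
    for ap in anchored:
        placement.overlay(ap, max_overhang=max_overhang, strict=False)
    return placement


def resolve_overlaps(
    placement: Placement,
    max_overhang: int = 1,
) -> Placement:
    """Rank-ordered re-placement producing a conflict-free overlay.

    Peptides are replayed best-first (Edman anchors, then fewest missed
    cleavages, source score, mass error, sequence); a peptide disagreeing
    with better-ranked residues is dropped and recorded as a rejected
    alternative. A zero-missed-cleavage peptide whose interval lies inside a
    longer retained peptide is marked absorbed and its provenance transferred
    to the longer fragment. Idempotent.
    """
    resolved = Placement(length=placement.length)
    resolved.rejected = list(placement.rejected)
    for ap in sorted(placement.placed, key=AnchoredPeptide.rank_sort_key):
        resolved.overlay(ap, max_overhang=max_overhang, strict=True)

    for short in resolved.placed:
        for long in resolved.placed:
            if short is long:
                continue
            if (short.peptide.missed_cleavages == 0
                    and long.start <= short.start
                    and min(short.end, resolved.length) <= long.end
                    and len(long.peptide.sequence) > len(short.peptide.sequence)):
                resolved.absorbed.append(
                    {"peptide": short.name, "into": long.name}
                )
                for pos, owner in list(resolved.provenance.items()):
                    if owner == short.name:
                        resolved.provenance[pos] = long.name
                break
    absorbed_names = {a["peptide"] for a in resolved.absorbed}
    resolved.placed = [p for p in resolved.placed if p.name not in absorbed_names]
    resolved.resolved = True
    return resolved


@dataclass(frozen=True)
class ScaffoldProperties:
    length: int
    covered: int
    gap_count: int
    gap_intervals: tuple[tuple[int, int], ...]
    mw: MolecularWeight
    pi: float


@dataclass(frozen=True)
class Scaffold:
    """An assembled target sequence with unknown positions marked ``X``."""

    sequence: str
    provenance: dict[int, str]
    placed: tuple[AnchoredPeptide, ...]
    rejected: tuple[dict, ...]
    absorbed: tuple[dict, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gap_intervals(self) -> tuple[tuple[int, int], ...]:
        gaps, i, n = [], 0, len(self.sequence)
        while i < n:
            if self.sequence[i] == UNKNOWN:
                j = i
                while j < n and self.sequence[j] == UNKNOWN:
                    j += 1
                gaps.append((i + 1, j))
                i = j
            else:
                i += 1
        return tuple(gaps)

    def properties(self, unknown_policy: str = "fixed_mass",
                   unknown_mass: float = 110.0) -> ScaffoldProperties:
        gaps = self.gap_intervals
        covered = sum(1 for r in self.sequence if r != UNKNOWN)
        return ScaffoldProperties(
            length=self.length,
            covered=covered,
            gap_count=len(gaps),
            gap_intervals=gaps,
            mw=molecular_weight(self.sequence, unknown_policy, unknown_mass),
            pi=isoelectric_point(self.sequence),
        )


def build_scaffold(placement: Placement) -> Scaffold:
    """Freeze a consistent placement into a Scaffold."""
    if placement.conflicts and not placement.resolved:
        raise PlacementConflictError(
            f"{len(placement.conflicts)} unresolved conflict(s); run resolve_overlaps first"
        )
    return Scaffold(
        sequence="".join(placement.residues),
        provenance=dict(placement.provenance),
        placed=tuple(placement.placed),
        rejected=tuple(placement.rejected),
        absorbed=tuple(placement.absorbed),
    )


@dataclass(frozen=True)
class CheckResult:
    position: int
    expected: str
    observed: str
    status: str  # 'pass' | 'fail' | 'unknown'


def residue_check(
    scaffold: Scaffold,
    checks: list[tuple[int, str]],
) -> list[CheckResult]:
    """Compare expected residues (e.g. catalytic-site annotations) against the
    scaffold; a position inside a gap reports 'unknown', never an exception."""
    out = []
    for pos, expected in checks:
        if not 1 <= pos <= scaffold.length:
            raise ValueError(f"position {pos} outside scaffold 1-{scaffold.length}")
        observed = scaffold.sequence[pos - 1]
        if observed == UNKNOWN:
            status = "unknown"
        elif observed == expected:
            status = "pass"
        else:
            status = "fail"
        out.append(CheckResult(pos, expected, observed, status))
    return out
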