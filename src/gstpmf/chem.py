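"""Residue-level peptide chemistry.

Masses, Lys-C digestion with missed cleavages, molecular weight over
sequences containing unknown residues, Henderson-Hasselbalch net charge
and isoelectric point.

Coordinates are 1-based inclusive throughout, matching the convention of
printed peptide tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "ResidueTable",
    "Peptide",
    "DigestParams",
    "MolecularWeight",
    "InvalidSequenceError",
    "DEFAULT_TABLE",
    "WATER_MONO",
    "WATER_AVG",
    "PROTON",
    "peptide_mass",
    "digest",
    "count_missed_cleavages",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
]

WATER_MONO = 18.0105646863
WATER_AVG = 18.01528
PROTON = 1.00727646688

UNKNOWN = "X"

# Monoisotopic residue masses (Da), IUPAC 2021 atomic masses.
_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# Average residue masses (Da).
_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

# Bjellqvist pKa set (as used by the ExPASy Compute pI/MW tool).
_PKA_POSITIVE = {"nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_PKA_NEGATIVE = {"cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}

CARBAMIDOMETHYL_C = ("C", 57.02146)


class InvalidSequenceError(ValueError):
    """A sequence contains symbols outside the accepted alphabet."""


@dataclass(frozen=True)
class ResidueTable:
    """Per-residue masses, fixed-modification deltas and pKa values.

    The table covers the 20 standard residues; the unknown symbol ``X`` is
    accepted by operations that declare a policy for it but carries no
    chemistry of its own.
    """

    monoisotopic: dict[str, float] = field(default_factory=lambda: dict(_MONO))
    average: dict[str, float] = field(default_factory=lambda: dict(_AVG))
    water_mono: float = WATER_MONO
    water_avg: float = WATER_AVG
    proton: float = PROTON
    modifications: dict[str, float] = field(default_factory=dict)
    pka_positive: dict[str, float] = field(default_factory=lambda: dict(_PKA_POSITIVE))
    pka_negative: dict[str, float] = field(default_factory=lambda: dict(_PKA_NEGATIVE))

    def __post_init__(self) -> None:
        if set(self.monoisotopic) != set(_MONO) or set(self.average) != set(_MONO):
            raise ValueError("residue table must cover exactly the 20 standard residues")
        for r in self.monoisotopic:
            if not (0.0 < self.monoisotopic[r] <= self.average[r]):
                raise ValueError(f"bad mass pair for residue {r!r}")

    def with_modification(self, residue: str, delta: float) -> "ResidueTable":
        mods = dict(self.modifications)
        mods[residue] = delta
        return replace(self, modifications=mods)

    def validate(self, sequence: str, allow_unknown: bool = False) -> None:
        ok = set(self.monoisotopic)
        if allow_unknown:
            ok = ok | {UNKNOWN}
        bad = set(sequence) - ok
        if not sequence:
            raise InvalidSequenceError("empty sequence")
        if bad:
            raise InvalidSequenceError(
                f"unknown residue symbol(s) {sorted(bad)} in sequence {sequence!r}"
            )


DEFAULT_TABLE = ResidueTable()


@dataclass(frozen=True)
class Peptide:
    """A proteolytic fragment, optionally anchored on a parent coordinate system.

    ``start``/``end`` are 1-based inclusive positions on the parent sequence;
    ``missed_cleavages`` is the number of internal uncut protease sites (the
    peptide table's "NM" column).
    """

    sequence: str
    start: int | None = None
    end: int | None = None
    missed_cleavages: int = 0
    source_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidSequenceError("empty peptide sequence")
        if self.start is not None and self.end is not None:
            if self.start < 1 or self.end < self.start:
                raise ValueError(f"bad interval {self.start}-{self.end}")

    @property
    def interval_length(self) -> int | None:
        if self.start is None or self.end is None:
            return None
        return self.end - self.start + 1


@dataclass(frozen=True)
class DigestParams:
    """Protease digestion rule. Defaults describe Lys-C (cleave after K only)."""

    cleave_after: frozenset[str] = frozenset({"K"})
    max_missed: int = 2
    min_length: int = 1
    cleave_before_proline: bool = True

    def __post_init__(self) -> None:
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")


def _cut_points(sequence: str, params: DigestParams) -> list[int]:
    """0-based indices i such that a cut falls between sequence[i-1] and sequence[i]."""
    cuts = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] in params.cleave_after:
            if not params.cleave_before_proline and sequence[i] == "P":
                continue
            cuts.append(i)
    return cuts


def peptide_mass(
    sequence: str,
    mass_kind: str = "monoisotopic",
    charge_form: str = "neutral",
    mods: dict[str, float] | None = None,
    table: ResidueTable = DEFAULT_TABLE,
) -> float:
    """Mass of a peptide in Da.

    mass_kind: 'monoisotopic' or 'average'; charge_form: 'neutral' or
    'MH_plus' ([M+H]+ adds exactly one proton). ``mods`` maps residue letter
    to a fixed-modification delta applied at every occurrence.
    """
    table.validate(sequence)
    if mass_kind == "monoisotopic":
        residues, water = table.monoisotopic, table.water_mono
    elif mass_kind == "average":
        residues, water = table.average, table.water_avg
    else:
        raise ValueError(f"unknown mass_kind {mass_kind!r}")
    mods = {**table.modifications, **(mods or {})}
    m = water + sum(residues[r] + mods.get(r, 0.0) for r in sequence)
    if charge_form == "MH_plus":
        m += table.proton
    elif charge_form != "neutral":
        raise ValueError(f"unknown charge_form {charge_form!r}")
    return m


def count_missed_cleavages(
    sequence: str,
    params: DigestParams = DigestParams(),
    table: ResidueTable = DEFAULT_TABLE,
) -> int:
    """Number of internal (non C-terminal) uncut protease sites in a peptide."""
    table.validate(sequence)
    return len(_cut_points(sequence, params))


def digest(
    sequence: str,
    params: DigestParams = DigestParams(),
    source_id: str | None = None,
    table: ResidueTable = DEFAULT_TABLE,
) -> list[Peptide]:
    """All peptides obtainable with 0..max_missed retained internal sites.

    Each peptide carries its 1-based start/end on the parent and its
    missed-cleavage count; output is unique by (start, end) and sorted by
    position then length.
    """
    table.validate(sequence)
    bounds = [0] + _cut_points(sequence, params) + [len(sequence)]
    out = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + params.max_missed, len(bounds))):
            frag = sequence[bounds[a]:bounds[b]]
            if len(frag) < params.min_length:
                continue
            out.append(
                Peptide(
                    sequence=frag,
                    start=bounds[a] + 1,
                    end=bounds[b],
                    missed_cleavages=b - a - 1,
                    source_id=source_id,
                )
            )
    return out


@dataclass(frozen=True)
class MolecularWeight:
    """Average molecular weight together with the unknown-residue policy used."""

    da: float
    unknown_policy: str
    unknown_mass: float
    n_unknown: int

    @property
    def kda(self) -> float:
        return self.da / 1000.0


def molecular_weight(
    sequence: str,
    unknown_policy: str = "zero",
    unknown_mass: float = 110.0,
    table: ResidueTable = DEFAULT_TABLE,
) -> MolecularWeight:
    """Average-mass molecular weight of a sequence that may contain ``X``.

    ``X`` contributes 0 Da under the 'zero' policy or ``unknown_mass``
    (default 110.0 Da, a generic residue mass) under 'fixed_mass'.
    """
    table.validate(sequence, allow_unknown=True)
    if unknown_policy not in ("zero", "fixed_mass"):
        raise ValueError(f"unknown policy {unknown_policy!r}")
    x_mass = unknown_mass if unknown_policy == "fixed_mass" else 0.0
    n_x = sequence.count(UNKNOWN)
    m = table.water_avg + sum(
        table.average.get(r, 0.0) for r in sequence if r != UNKNOWN
    ) + n_x * x_mass
    return MolecularWeight(da=m, unknown_policy=unknown_policy,
                           unknown_mass=x_mass, n_unknown=n_x)


def net_charge(
    sequence: str,
    ph: float,
    table: ResidueTable = DEFAULT_TABLE,
) -> float:
    """Henderson-Hasselbalch net charge at a given pH.

    Termini plus ionizable side chains (D, E, C, Y, H, K, R); ``X`` and
    non-ionizable residues contribute nothing. Strictly decreasing in pH.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    table.validate(sequence, allow_unknown=True)
    charge = 1.0 / (1.0 + 10.0 ** (ph - table.pka_positive["nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (table.pka_negative["cterm"] - ph))
    for r in sequence:
        if r in table.pka_positive:
            charge += 1.0 / (1.0 + 10.0 ** (ph - table.pka_positive[r]))
        elif r in table.pka_negative:
            charge -= 1.0 / (1.0 + 10.0 ** (table.pka_negative[r] - ph))
    return charge


def isoelectric_point(
    sequence: str,
    tol: float = 0.01,
    table: ResidueTable = DEFAULT_TABLE,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge is strictly decreasing in pH and positive at pH 0, negative at
    pH 14, so the root exists and is unique. ``X`` is excluded from the charge.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol / 2.0:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, table=table) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
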