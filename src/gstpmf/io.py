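"""File formats, bundled fixture and run configuration.

FASTA (sequences and scaffolds, ``X`` preserved, uppercased on read),
tab-separated peak lists and kinetics datasets, YAML run configuration with
a write-read round-trip guarantee, and the bundled 17-row Lys-C peptide
table protected by a checksum.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, fields
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import Peptide, count_missed_cleavages
from .pmf import Peak, PeakList

__all__ = [
    "Table5Record",
    "FixtureError",
    "load_fixture",
    "read_fasta",
    "write_fasta",
    "read_peaklist",
    "write_peaklist",
    "read_kinetics_table",
    "RunConfig",
]

log = logging.getLogger(__name__)

_FIXTURE_SHA256 = "2aac41656a85f15f11c932ed39f182cc323686dfedc1e7f9ed2d4f7950de1ec2"


class FixtureError(RuntimeError):
    """The bundled fixture failed its integrity check."""


@dataclass(frozen=True)
class Table5Record:
    """One row of the bundled peptide table.

    ``flags`` preserves printed inconsistencies (interval/sequence length
    mismatches) verbatim; ``anchor_kind`` is 'edman' for the three directly
    sequenced fragments, which are position-anchored without mass matching.
    """

    peptide_no: int
    mass_da: float
    nm: int
    start: int
    end: int
    sequence: str
    source: str
    anchor_kind: str
    flags: tuple[str, ...]

    @property
    def is_edman(self) -> bool:
        return self.anchor_kind == "edman"

    def to_peptide(self) -> Peptide:
        return Peptide(
            sequence=self.sequence,
            start=self.start,
            end=self.end,
            missed_cleavages=count_missed_cleavages(self.sequence),
            source_id=self.source,
        )


def load_fixture() -> tuple[Table5Record, ...]:
    """The bundled 17-row peptide table, checksum-verified."""
    ref = resources.files("gstpmf") / "fixtures" / "table5.tsv"
    raw = ref.read_bytes()
    digest_hex = hashlib.sha256(raw).hexdigest()
    if digest_hex != _FIXTURE_SHA256:
        raise FixtureError(
            f"fixture checksum mismatch: {digest_hex} != {_FIXTURE_SHA256}"
        )
    records = []
    lines = [ln for ln in raw.decode().splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        records.append(
            Table5Record(
                peptide_no=int(row["peptide_no"]),
                mass_da=float(row["mass_da"]),
                nm=int(row["nm"]),
                start=int(row["start"]),
                end=int(row["end"]),
                sequence=row["sequence"],
                source=row["source"],
                anchor_kind=row["anchor_kind"],
                flags=tuple(f for f in row.get("flags", "").split(";") if f),
            )
        )
    if len(records) != 17:
        raise FixtureError(f"expected 17 records, found {len(records)}")
    return tuple(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into {id: uppercased sequence}; warns when empty."""
    path = Path(path)
    out: dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq)
        if seq != seq.upper():
            log.info("uppercasing mixed-case sequence %s", rec.id)
        out[rec.id] = seq.upper()
    if not out:
        log.warning("no FASTA records in %s", path)
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write sequences as 60-column-wrapped FASTA (``X`` permitted)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_peaklist(path: str | Path) -> PeakList:
    """Peak list TSV: columns peak_id, mass_da[, tolerance_da]; '#' comments."""
    df = pd.read_csv(path, sep="\t", comment="#")
    peaks = []
    for _, row in df.iterrows():
        tol = row.get("tolerance_da")
        peaks.append(
            Peak(
                peak_id=str(row["peak_id"]),
                mass_da=float(row["mass_da"]),
                tolerance_da=None if tol is None or pd.isna(tol) else float(tol),
            )
        )
    return PeakList(tuple(peaks))


def write_peaklist(peaks: PeakList, path: str | Path) -> None:
    rows = [
        {"peak_id": p.peak_id, "mass_da": p.mass_da, "tolerance_da": p.tolerance_da}
        for p in peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_kinetics_table(path: str | Path) -> pd.DataFrame:
    """Generic two-or-more-column TSV for kinetics datasets ('#' comments)."""
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run; YAML round-trip safe.

    Every threshold that shapes a result is surfaced here so output reports
    can embed the exact configuration in force.
    """

    mode: str = "reproduce"              # 'reproduce' | 'denovo'
    scaffold_length: int = 206
    tolerance_da: float = 1.0
    max_missed: int = 2
    cleave_before_proline: bool = True
    max_overhang: int = 1
    unknown_policy: str = "fixed_mass"
    unknown_mass: float = 110.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    km_ratio_threshold: float = 1.5
    vmax_drop_threshold: float = 0.15
    seed: int = 0
    database_fasta: str | None = None
    peaks_tsv: str | None = None
    output_dir: str | None = None
    extras: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
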