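"""Locate identified peptides within reference proteins.

MS/MS search engines report exact peptide sequences, so "alignment" here is
exact substring location: every occurrence of the peptide in every reference
protein, reported as 1-based inclusive coordinates on the mature chain.
Isoleucine and leucine are isobaric and indistinguishable by mass alone; an
optional I/L-equivalence mode is provided, off by default because search
output has already committed to one residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .reference_proteome import _AA_SET, ProteinRecord

logger = logging.getLogger(__name__)

BASAL_TIME_MIN = -15

#: Column-map keys recognised by :func:`read_peptide_table`.
TABLE_FIELDS = ("sequence", "intensity", "substrate", "time_min", "animal_id")


class ConfigError(ValueError):
    """Raised for invalid configuration (missing columns, bad options)."""


class UnmappedPeptideError(ValueError):
    """Raised when unmapped peptides are present and the policy forbids them."""


@dataclass(frozen=True)
class PeptideObservation:
    """One identified peptide in one sample, optionally located in a protein.

    ``start``/``end`` are 1-based inclusive mature coordinates, ``None`` until
    mapped.  ``intensity_imputed`` flags observations whose table row carried
    no intensity (given weight 1.0 so count-only tables flow through the same
    pipeline).  ``ambiguous`` flags copies of an observation whose sequence
    occurs at more than one locus.
    """

    sequence: str
    intensity: float = 1.0
    substrate: str = ""
    time_min: int = 0
    animal_id: str = ""
    protein_id: str | None = None
    start: int | None = None
    end: int | None = None
    ambiguous: bool = False
    intensity_imputed: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError(f"peptide {self.sequence!r}: length must be >= 2")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(f"peptide {self.sequence!r}: illegal residue(s) {sorted(bad)!r}")
        if not (self.intensity >= 0):
            raise ValueError(f"peptide {self.sequence!r}: intensity must be >= 0")
        if (self.start is None) != (self.end is None):
            raise ValueError("start and end must be set together")
        if self.start is not None and self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"peptide {self.sequence!r}: span {self.start}..{self.end} "
                f"inconsistent with length {len(self.sequence)}"
            )

    @property
    def mapped(self) -> bool:
        return self.start is not None


@dataclass(frozen=True)
class MappingPolicy:
    """How to resolve peptide-to-protein matches.

    equate_ile_leu:
        Treat I and L as the same residue during matching.
    multi_match_rule:
        ``report_all`` expands a peptide matching k loci into k copies flagged
        ambiguous; ``unique_only`` drops ambiguous peptides.
    on_unmapped:
        ``drop_with_log`` drops peptides absent from every protein (counted
        in the report); ``error`` raises listing them.
    """

    equate_ile_leu: bool = False
    multi_match_rule: Literal["report_all", "unique_only"] = "report_all"
    on_unmapped: Literal["drop_with_log", "error"] = "drop_with_log"

    def __post_init__(self) -> None:
        if self.multi_match_rule not in ("report_all", "unique_only"):
            raise ConfigError(f"unknown multi_match_rule {self.multi_match_rule!r}")
        if self.on_unmapped not in ("drop_with_log", "error"):
            raise ConfigError(f"unknown on_unmapped {self.on_unmapped!r}")


@dataclass
class MappingReport:
    """Record accounting for one :func:`map_observations` run.

    ``n_input == n_mapped_unique + n_ambiguous + n_unmapped`` always holds
    (ambiguous counts input observations, not expanded copies).
    """

    n_input: int = 0
    n_mapped_unique: int = 0
    n_ambiguous: int = 0
    n_unmapped: int = 0
    unmapped_sequences: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_mapped_unique": self.n_mapped_unique,
            "n_ambiguous": self.n_ambiguous,
            "n_unmapped": self.n_unmapped,
            "unmapped_sequences": sorted(set(self.unmapped_sequences)),
        }


def read_peptide_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> list[PeptideObservation]:
    """Parse a delimited peptide-identification table into observations.

    ``column_map`` maps the field names ``sequence``, ``intensity``,
    ``substrate``, ``time_min``, ``animal_id`` to the table's column headers
    (identity by default).  ``sequence`` is mandatory; other fields fall back
    to defaults (intensity 1.0, flagged imputed).  A ``time_min`` value of
    ``basal`` (case-insensitive) is encoded as -15 min.  Rows failing
    validation are dropped with a log entry; coordinates are left unset.
    """
    column_map = dict(column_map or {})
    unknown = set(column_map) - set(TABLE_FIELDS)
    if unknown:
        raise ConfigError(f"unknown column_map keys: {sorted(unknown)}")
    colof = {f: column_map.get(f, f) for f in TABLE_FIELDS}

    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str)

    if colof["sequence"] not in frame.columns:
        raise ConfigError(
            f"{path}: mandatory sequence column {colof['sequence']!r} not found "
            f"(have {list(frame.columns)})"
        )

    observations: list[PeptideObservation] = []
    n_dropped = 0
    for idx, row in frame.iterrows():
        try:
            raw_intensity = row.get(colof["intensity"])
            imputed = raw_intensity is None or pd.isna(raw_intensity)
            raw_time = row.get(colof["time_min"], 0)
            if isinstance(raw_time, str) and raw_time.strip().lower() == "basal":
                time_min = BASAL_TIME_MIN
            else:
                time_min = int(float(raw_time)) if not pd.isna(raw_time) else 0
            observations.append(
                PeptideObservation(
                    sequence=str(row[colof["sequence"]]).strip().upper(),
                    intensity=1.0 if imputed else float(raw_intensity),
                    substrate=str(row.get(colof["substrate"], "") or ""),
                    time_min=time_min,
                    animal_id=str(row.get(colof["animal_id"], "") or ""),
                    intensity_imputed=imputed,
                )
            )
        except (ValueError, TypeError) as exc:
            n_dropped += 1
            logger.warning("%s: row %d dropped: %s", path, idx, exc)
    if n_dropped:
        logger.warning("%s: dropped %d invalid row(s)", path, n_dropped)
    return observations


def observations_to_frame(observations: Iterable[PeptideObservation]) -> pd.DataFrame:
    """Tabulate observations (mapped or not) as a DataFrame."""
    rows = [
        {
            "sequence": o.sequence,
            "intensity": o.intensity,
            "substrate": o.substrate,
            "time_min": o.time_min,
            "animal_id": o.animal_id,
            "protein_id": o.protein_id,
            "start": o.start,
            "end": o.end,
            "ambiguous": o.ambiguous,
        }
        for o in observations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sequence", "intensity", "substrate", "time_min", "animal_id",
            "protein_id", "start", "end", "ambiguous",
        ],
    )


def _canonical(seq: str, equate_ile_leu: bool) -> str:
    return seq.replace("I", "L") if equate_ile_leu else seq


def map_peptide(
    sequence: str,
    proteins: Sequence[ProteinRecord],
    policy: MappingPolicy | None = None,
) -> list[tuple[str, int, int]]:
    """All exact occurrences of ``sequence`` in ``proteins``.

    Returns ``(protein_id, start, end)`` triples in deterministic order:
    protein input order, then ascending start.  1-based inclusive mature
    coordinates.  An empty list means no match.
    """
    policy = policy or MappingPolicy()
    query = _canonical(sequence.upper(), policy.equate_ile_leu)
    hits: list[tuple[str, int, int]] = []
    for protein in proteins:
        subject = _canonical(protein.sequence, policy.equate_ile_leu)
        pos = subject.find(query)
        while pos != -1:
            hits.append((protein.protein_id, pos + 1, pos + len(query)))
            pos = subject.find(query, pos + 1)
    return hits


def map_observations(
    observations: Iterable[PeptideObservation],
    proteins: Sequence[ProteinRecord],
    policy: MappingPolicy | None = None,
) -> tuple[list[PeptideObservation], MappingReport]:
    """Map each observation onto the reference proteins.

    Under ``report_all`` an observation matching k > 1 loci is expanded into
    k mapped copies flagged ambiguous; under ``unique_only`` ambiguous
    observations are dropped.  Unmapped observations are dropped (or raise,
    per policy).  Previously assigned coordinates are overwritten, so the
    operation is idempotent.
    """
    policy = policy or MappingPolicy()
    report = MappingReport()
    mapped: list[PeptideObservation] = []
    for obs in observations:
        report.n_input += 1
        loci = map_peptide(obs.sequence, proteins, policy)
        if not loci:
            report.n_unmapped += 1
            report.unmapped_sequences.append(obs.sequence)
            continue
        if len(loci) == 1:
            report.n_mapped_unique += 1
            pid, start, end = loci[0]
            mapped.append(
                replace(obs, protein_id=pid, start=start, end=end, ambiguous=False)
            )
        else:
            report.n_ambiguous += 1
            if policy.multi_match_rule == "report_all":
                for pid, start, end in loci:
                    mapped.append(
                        replace(obs, protein_id=pid, start=start, end=end, ambiguous=True)
                    )
    if report.n_unmapped and policy.on_unmapped == "error":
        raise UnmappedPeptideError(
            f"{report.n_unmapped} peptide(s) not found in any reference protein: "
            f"{sorted(set(report.unmapped_sequences))}"
        )
    if report.n_unmapped:
        logger.info(
            "dropped %d unmapped peptide(s): %s",
            report.n_unmapped,
            sorted(set(report.unmapped_sequences))[:10],
        )
    return mapped, report
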