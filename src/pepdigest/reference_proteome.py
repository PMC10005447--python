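"""Reference protein sequences in mature-protein numbering.

Peptidomic coordinates throughout this package are 1-based positions on the
*mature* chain, i.e. the precursor with its signal peptide removed.  This is
the convention used for casein-derived bioactive peptides in the dairy
literature (beta-casomorphin-7 is beta-casein 60-66, the plasmin-resistant
C-terminal domain of beta-casein is 193-209, and so on).

The package ships mature sequences of the four major bovine caseins
(beta, alpha-s1, alpha-s2, kappa), one canonical genetic variant each, as a
small FASTA fixture.  Header metadata records the length of the removed
signal peptide and the source accession so the precursor coordinate of any
mature position p is simply ``signal_length + p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class FastaError(ValueError):
    """Raised when a FASTA file cannot be parsed or validated."""


@dataclass(frozen=True)
class ProteinRecord:
    """A mature reference protein with 1-based residue numbering.

    Attributes
    ----------
    protein_id:
        Short token identifying the protein (e.g. ``CASB_BOVIN``).
    sequence:
        Uppercase amino-acid string of the mature chain (signal peptide
        removed); mature position 1 corresponds to precursor position
        ``signal_length + 1``.
    display_name:
        Free-text human-readable name.
    signal_length:
        Number of precursor residues removed to obtain the mature chain.
    source_accession:
        Provenance note (e.g. a UniProt accession of the precursor entry).
    """

    protein_id: str
    sequence: str
    display_name: str = ""
    signal_length: int = 0
    source_accession: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: sequence must be non-empty")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"{self.protein_id}: illegal residue character(s) "
                f"{sorted(bad)!r}; allowed alphabet is {AMINO_ACIDS}"
            )
        if self.signal_length < 0:
            raise ValueError(f"{self.protein_id}: signal_length must be >= 0")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Residues ``start..end`` in 1-based inclusive mature numbering."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise IndexError(
                f"{self.protein_id}: positions {start}..{end} outside 1..{len(self.sequence)}"
            )
        return self.sequence[start - 1 : end]


def _parse_header(description: str) -> tuple[str, dict[str, str]]:
    tokens = description.split()
    protein_id = tokens[0]
    meta: dict[str, str] = {}
    for tok in tokens[1:]:
        if "=" in tok:
            key, _, value = tok.partition("=")
            meta[key] = value
    return protein_id, meta


def load_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The header dialect is ``>id key=value ...`` with optional keys
    ``signal_length``, ``source_accession`` and ``name`` (underscores in the
    name are rendered as spaces).  Sequences are uppercased; an absent
    ``signal_length`` defaults to 0.

    Raises
    ------
    FastaError
        If the file is not FASTA-formatted or a sequence contains characters
        outside the 20-letter amino-acid alphabet.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with open(path) as handle:
        first = handle.read(1)
        if first != ">":
            raise FastaError(f"{path}: line 1: expected FASTA header starting with '>'")
    for entry in SeqIO.parse(str(path), "fasta"):
        protein_id, meta = _parse_header(entry.description)
        try:
            signal_length = int(meta.get("signal_length", "0"))
        except ValueError as exc:
            raise FastaError(f"{path}: record {protein_id}: bad signal_length") from exc
        try:
            records.append(
                ProteinRecord(
                    protein_id=protein_id,
                    sequence=str(entry.seq).upper(),
                    display_name=meta.get("name", "").replace("_", " "),
                    signal_length=signal_length,
                    source_accession=meta.get("source_accession", ""),
                )
            )
        except ValueError as exc:
            raise FastaError(f"{path}: record {protein_id}: {exc}") from exc
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records in the ``>id key=value ...`` header dialect (lossless)."""
    seq_records = []
    for rec in records:
        parts = [rec.protein_id, f"signal_length={rec.signal_length}"]
        if rec.source_accession:
            parts.append(f"source_accession={rec.source_accession}")
        if rec.display_name:
            parts.append(f"name={rec.display_name.replace(' ', '_')}")
        seq_records.append(
            SeqRecord(Seq(rec.sequence), id=rec.protein_id, description=" ".join(parts[1:]))
        )
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def bundled_caseins() -> list[ProteinRecord]:
    """The four bundled mature bovine caseins (beta, alpha-s1, alpha-s2, kappa).

    One canonical genetic variant per casein, signal peptide removed:
    beta-casein 209 residues, alpha-s1 199, alpha-s2 207, kappa 169.
    """
    with resources.as_file(
        resources.files("pepdigest.data").joinpath("caseins.fasta")
    ) as fixture:
        return load_fasta(fixture)
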