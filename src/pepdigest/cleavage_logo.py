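"""Terminal-residue composition of a peptide set (sequence-logo content).

The first and last three residues of identified digestion peptides summarise
the apparent cleavage preference of the proteases that produced them.  The
product here is the 20 x 6 column-stochastic probability matrix behind a
terminal sequence logo — positions N1, N2, N3 and C-3, C-2, C-1 — not the
rendered letter graphic.

Peptides shorter than five residues are excluded by default (the usual MS
identification floor for this kind of data).  For a length-5 peptide the
terminal windows overlap: its middle residue is position 3 from both ends
and contributes to both the N3 and the C-3 column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .peptide_mapping import ConfigError
from .reference_proteome import AMINO_ACIDS

POSITION_LABELS = ("N1", "N2", "N3", "C-3", "C-2", "C-1")


@dataclass
class TerminalLogoMatrix:
    """Amino-acid probabilities at the three terminal positions of each end."""

    probs: pd.DataFrame  # 20 amino-acid rows x 6 position columns
    n_peptides: int
    n_excluded_short: int

    def column(self, label: str) -> pd.Series:
        return self.probs[label]


def terminal_logo(peptides: Iterable[str], min_length: int = 5) -> TerminalLogoMatrix:
    """Tally terminal residues of ``peptides`` into a probability matrix.

    Residues 1..3 of each included peptide contribute to N1..N3 and residues
    -3..-1 to C-3..C-1 (overlapping windows for length-5 peptides).  Each
    column is the frequency over included peptides, so columns sum to 1.
    Peptides shorter than ``min_length`` are excluded and counted.

    Raises
    ------
    ValueError
        If no peptide passes the length filter.
    """
    if min_length < 5:
        raise ConfigError("min_length must be >= 5 so both terminal windows exist")
    counts = np.zeros((len(AMINO_ACIDS), len(POSITION_LABELS)))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    n_included = 0
    n_short = 0
    for pep in peptides:
        if len(pep) < min_length:
            n_short += 1
            continue
        n_included += 1
        for j, residue in enumerate(pep[:3]):
            counts[aa_index[residue], j] += 1
        for j, residue in enumerate(pep[-3:]):
            counts[aa_index[residue], 3 + j] += 1
    if n_included == 0:
        raise ValueError(
            "no peptide passed the length filter; lower min_length or check the input"
        )
    probs = pd.DataFrame(
        counts / n_included, index=list(AMINO_ACIDS), columns=list(POSITION_LABELS)
    )
    return TerminalLogoMatrix(probs=probs, n_peptides=n_included, n_excluded_short=n_short)


def top_terminal_kmer(
    peptides: Iterable[str],
    end: str = "C",
    k: int = 3,
) -> list[tuple[str, int]]:
    """Ranked k-mer counts at one peptide end.

    ``end='N'`` tallies the first k residues, ``end='C'`` the last k, of
    every peptide with length >= k.  Ranked by descending count, ties broken
    lexicographically.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    if end not in ("N", "C"):
        raise ConfigError(f"end must be 'N' or 'C', got {end!r}")
    tally: dict[str, int] = {}
    for pep in peptides:
        if len(pep) < k:
            continue
        kmer = pep[:k] if end == "N" else pep[-k:]
        tally[kmer] = tally.get(kmer, 0) + 1
    return sorted(tally.items(), key=lambda item: (-item[1], item[0]))
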