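"""Descriptive peptidomics: residue coverage profiles, size distributions,
and per-time-point peptide count summaries.

Two per-residue profile modes are supported along a parent protein:

* ``intensity_sum`` — at each mature position, the sum of MS intensities of
  all identified peptides overlapping that position (the numeric content of
  substrate-vs-time area plots);
* ``occurrence_count`` — the number of overlapping peptides, ignoring
  intensity (the appearance-frequency heatmap content).

Count summaries follow identification-level bookkeeping: a "unique peptide"
is a distinct sequence string within one (substrate, time) sample, a
"common" peptide is one seen in every animal, and column totals are plain
sums of the per-time counts (not deduplicated unions across time).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .peptide_mapping import ConfigError, PeptideObservation
from .reference_proteome import ProteinRecord

#: Length bins matching the spoken size categories of duodenal peptidomes:
#: very short (2-5), the MS sweet spot (6-9), long (10-14), very long (>=15).
DEFAULT_LENGTH_BINS: tuple[tuple[int, int | None], ...] = (
    (2, 5),
    (6, 9),
    (10, 14),
    (15, None),
)

ProfileMode = Literal["intensity_sum", "occurrence_count"]


@dataclass
class ResidueProfile:
    """Per-residue aggregate along one protein for one sample group."""

    protein_id: str
    mode: ProfileMode
    values: np.ndarray
    sample_key: Hashable = "pooled"

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class SizeDistribution:
    """Counts of unique peptide sequences per length bin for one group."""

    group_key: Hashable
    bin_edges: tuple[tuple[int, int | None], ...]
    counts: np.ndarray
    percentages: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def bin_labels(self) -> list[str]:
        return [f"{lo}-{hi}" if hi is not None else f">={lo}" for lo, hi in self.bin_edges]


@dataclass
class CountSummary:
    """Per-time unique and common (all-animal) peptide counts with totals."""

    per_time: dict[int, tuple[int, int]]
    n_animals: int

    @property
    def column_totals(self) -> tuple[int, int]:
        totals = np.array(list(self.per_time.values()), dtype=int)
        if totals.size == 0:
            return (0, 0)
        return int(totals[:, 0].sum()), int(totals[:, 1].sum())

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"time_min": t, "total_unique": tot, "common": com}
            for t, (tot, com) in sorted(self.per_time.items())
        ]
        frame = pd.DataFrame(rows, columns=["time_min", "total_unique", "common"])
        tot, com = self.column_totals
        frame.loc[len(frame)] = {"time_min": "Total", "total_unique": tot, "common": com}
        return frame


def _require_mapped(observations: Iterable[PeptideObservation]) -> list[PeptideObservation]:
    obs = list(observations)
    unmapped = [o.sequence for o in obs if not o.mapped]
    if unmapped:
        raise ValueError(f"unmapped observation(s): {sorted(set(unmapped))[:5]}")
    return obs


def residue_profile(
    observations: Iterable[PeptideObservation],
    protein: ProteinRecord,
    mode: ProfileMode = "intensity_sum",
    sample_key: Hashable = "pooled",
) -> ResidueProfile:
    """Aggregate peptide coverage of one protein into a per-residue vector.

    ``values[p-1]`` is the sum over observations with ``start <= p <= end``
    of the intensity (``intensity_sum``) or of 1 (``occurrence_count``).
    Observations mapped to other proteins are ignored; spans outside the
    protein raise.
    """
    if mode not in ("intensity_sum", "occurrence_count"):
        raise ConfigError(f"unknown profile mode {mode!r}")
    length = len(protein)
    values = np.zeros(length)
    for obs in _require_mapped(observations):
        if obs.protein_id != protein.protein_id:
            continue
        if not (1 <= obs.start <= obs.end <= length):
            raise ValueError(
                f"{obs.sequence}: span {obs.start}..{obs.end} outside "
                f"{protein.protein_id} (length {length})"
            )
        weight = obs.intensity if mode == "intensity_sum" else 1.0
        values[obs.start - 1 : obs.end] += weight
    return ResidueProfile(protein.protein_id, mode, values, sample_key)


def profile_matrix(
    observations: Iterable[PeptideObservation],
    protein: ProteinRecord,
    mode: ProfileMode = "intensity_sum",
    normalize_rows: bool = False,
) -> pd.DataFrame:
    """Residue profiles of every (substrate, time) sample, as a matrix.

    Rows are (substrate, time_min) pairs in substrate order then ascending
    time; columns are mature residue positions labelled ``protein:pos``.
    Intensities are summed over animals.  With ``normalize_rows`` each row is
    divided by its total (rows with zero total are left as zeros).
    """
    obs = _require_mapped(observations)
    keys = sorted({(o.substrate, o.time_min) for o in obs})
    rows = []
    for key in keys:
        subset = [o for o in obs if (o.substrate, o.time_min) == key]
        rows.append(residue_profile(subset, protein, mode, sample_key=key).values)
    matrix = np.array(rows) if rows else np.zeros((0, len(protein)))
    if normalize_rows and matrix.size:
        totals = matrix.sum(axis=1, keepdims=True)
        matrix = np.divide(matrix, totals, out=np.zeros_like(matrix), where=totals > 0)
    columns = [f"{protein.protein_id}:{p}" for p in range(1, len(protein) + 1)]
    index = pd.MultiIndex.from_tuples(keys, names=["substrate", "time_min"])
    return pd.DataFrame(matrix, index=index, columns=columns)


def _validate_bins(bin_edges: Sequence[tuple[int, int | None]]) -> None:
    prev_hi = -np.inf
    for i, (lo, hi) in enumerate(bin_edges):
        if hi is not None and hi < lo:
            raise ConfigError(f"bin {lo}-{hi}: upper edge below lower")
        if lo <= prev_hi:
            raise ConfigError("length bins must be ordered and non-overlapping")
        if hi is None and i != len(bin_edges) - 1:
            raise ConfigError("open-ended bin must be last")
        prev_hi = hi if hi is not None else np.inf


def size_distribution(
    observations: Iterable[PeptideObservation],
    bin_edges: Sequence[tuple[int, int | None]] = DEFAULT_LENGTH_BINS,
    group_by: Sequence[str] = ("substrate",),
) -> list[SizeDistribution]:
    """Unique-sequence length histograms per group.

    Each group (by default, one per substrate; optionally also per time
    point) counts distinct peptide sequences whose length falls in each bin;
    a bin ``(lo, None)`` is open-ended.  Percentages are on the group total
    and 0 for empty groups.
    """
    _validate_bins(bin_edges)
    for g in group_by:
        if g not in ("substrate", "time_min"):
            raise ConfigError(f"cannot group by {g!r}")
    groups: dict[Hashable, set[str]] = {}
    for obs in observations:
        key = tuple(getattr(obs, g) for g in group_by)
        groups.setdefault(key if len(key) > 1 else key[0], set()).add(obs.sequence)
    out = []
    for key in sorted(groups):
        lengths = np.array([len(s) for s in groups[key]])
        counts = np.array(
            [
                int(((lengths >= lo) & (lengths <= (hi if hi is not None else np.inf))).sum())
                for lo, hi in bin_edges
            ]
        )
        total = counts.sum()
        pct = 100.0 * counts / total if total else np.zeros(len(counts))
        out.append(SizeDistribution(key, tuple(bin_edges), counts, pct))
    return out


def fraction_longer_than(observations: Iterable[PeptideObservation], length: int = 10) -> float:
    """Fraction of unique peptide sequences strictly longer than ``length``."""
    seqs = {o.sequence for o in observations}
    if not seqs:
        return 0.0
    return sum(len(s) > length for s in seqs) / len(seqs)


def count_summary(
    observations: Iterable[PeptideObservation],
    n_animals: int,
) -> CountSummary:
    """Per-time-point unique and common peptide counts.

    For each time point: the number of distinct sequences identified in at
    least one animal, and the number identified in all ``n_animals`` animals
    ("common").  Column totals are arithmetic sums over time points; a
    sequence seen at several times is counted at each.  Observations should
    come from a single substrate (mixing substrates pools their peptidomes).
    """
    if n_animals < 1:
        raise ConfigError("n_animals must be >= 1")
    presence: dict[int, dict[str, set[str]]] = {}
    for obs in observations:
        presence.setdefault(obs.time_min, {}).setdefault(obs.sequence, set()).add(obs.animal_id)
    per_time: dict[int, tuple[int, int]] = {}
    for time, seq_animals in sorted(presence.items()):
        total = len(seq_animals)
        common = sum(len(animals) >= n_animals for animals in seq_animals.values())
        per_time[time] = (total, common)
    return CountSummary(per_time, n_animals)


def dedup_union_count(observations: Iterable[PeptideObservation]) -> int:
    """Number of distinct sequences across all time points (deduplicated).

    Complementary to :func:`count_summary`, whose totals deliberately sum
    per-time counts without deduplication.
    """
    return len({o.sequence for o in observations})
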