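"""In-silico digestion and plasma generators for pipeline testing.

No raw MS data accompany the study design this package analyses, so every
stage is exercised against synthetic inputs with the statistical structure
the analysis assumes:

* a stochastic protein digestion model producing per-(animal, time) peptide
  tables of realistic size (a few hundred unique casein peptides per time
  point), with substrate-dependent fragment-size distributions controlled by
  a hydrolysis extent, pepsin-like P1 cleavage preferences (aromatic and
  large hydrophobic residues favoured, bonds flanking proline suppressed),
  and optionally protected regions (e.g. the digestion-resistant C-terminal
  domain of beta-casein, 193-209);
* a plasma amino-acid generator with substrate-specific mean time courses,
  per-animal offsets and Gaussian noise, emulating the faster and higher
  early amino-acid appearance after a hydrolysate meal.

Both generators record their ground truth (generating loci, mean curves) and
are byte-reproducible from a seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plasma_stats import PLASMA_COLUMNS, PLASMA_TIME_GRID
from .reference_proteome import AMINO_ACIDS, ProteinRecord, bundled_caseins

logger = logging.getLogger(__name__)

#: P1 cleavage propensities (relative weight of cutting the bond after each
#: residue).  Pepsin-like: strong after F/L/W/Y, moderate after E/M, a small
#: background everywhere else.  Bonds with proline on either side are
#: additionally suppressed (classic pepsin behaviour).
DEFAULT_CLEAVAGE_WEIGHTS: dict[str, float] = {
    **{aa: 0.05 for aa in AMINO_ACIDS},
    "F": 1.0,
    "L": 1.0,
    "W": 0.9,
    "Y": 0.9,
    "E": 0.5,
    "M": 0.3,
}

PROLINE_SUPPRESSION = 0.02

#: Duodenal collection grid (minutes post-intake); the basal (-15 min)
#: sample contains no meal-derived peptides and is not simulated.
DIGEST_TIME_GRID = (5, 10, 15, 20, 30, 45, 60, 90, 120, 150)

#: Digestion-resistant C-terminal domain of beta-casein.
BETA_CN_CTERM_REGION = ("CASB_BOVIN", 193, 209)


@dataclass(frozen=True)
class DigestionConfig:
    """Parameters of the stochastic digestion model for one substrate.

    Each protein molecule is digested independently: peptide bond i (after
    residue i) is cut with probability proportional to
    ``cleavage_weights[residue i]`` times the proline suppression and any
    protection factor, rescaled so the mean cut probability over all bonds
    equals ``hydrolysis_extent`` (probabilities are capped at 1 and the
    remainder redistributed).  Fragments between consecutive cuts are
    observed if their length lies in ``[min_len, max_len]`` — the lower edge
    mimics the MS identification floor of five residues.
    """

    substrate: str = "casein"
    proteins: tuple[ProteinRecord, ...] | None = None  # None -> bundled caseins
    cleavage_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLEAVAGE_WEIGHTS)
    )
    hydrolysis_extent: float = 0.30
    protected_regions: tuple[tuple[str, int, int, float], ...] = ()
    min_len: int = 5
    max_len: int = 40
    intensity_logmean: float = 6.0
    intensity_logsd: float = 0.4
    n_animals: int = 6
    time_points: tuple[int, ...] = DIGEST_TIME_GRID
    molecules_per_protein: int = 20
    peptides_per_sample_target: int = 180
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.hydrolysis_extent <= 1):
            raise ValueError("hydrolysis_extent must be in (0, 1]")
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if any(w < 0 for w in self.cleavage_weights.values()):
            raise ValueError("cleavage weights must be >= 0")

    def resolved_proteins(self) -> list[ProteinRecord]:
        return list(self.proteins) if self.proteins is not None else bundled_caseins()


@dataclass
class SyntheticTruth:
    """Ground truth of one digestion run: generating loci per emitted row."""

    loci: pd.DataFrame  # one row per table row: protein_id, start, end
    cut_probabilities: dict[str, np.ndarray]
    config: DigestionConfig
    empty_samples: list[tuple[str, int]] = field(default_factory=list)


def _bond_probabilities(protein: ProteinRecord, config: DigestionConfig) -> np.ndarray:
    """Per-bond cut probabilities with mean equal to hydrolysis_extent."""
    seq = protein.sequence
    n_bonds = len(seq) - 1
    weights = np.array([config.cleavage_weights.get(seq[i], 0.0) for i in range(n_bonds)])
    for i in range(n_bonds):
        if seq[i] == "P" or seq[i + 1] == "P":
            weights[i] *= PROLINE_SUPPRESSION
    for pid, start, end, factor in config.protected_regions:
        if pid == protein.protein_id:
            lo = max(1, start - 1)  # bond entering the region
            hi = min(n_bonds, end - 1)  # last internal bond
            weights[lo - 1 : hi] *= factor
    if weights.sum() == 0:
        return np.zeros(n_bonds)
    # scale to the target mean, redistributing mass clipped at p=1
    target_total = config.hydrolysis_extent * n_bonds
    probs = np.zeros(n_bonds)
    free = weights > 0
    for _ in range(50):
        remaining = target_total - probs[~free].sum()
        if remaining <= 0 or not free.any():
            break
        scale = remaining / weights[free].sum()
        probs[free] = np.minimum(weights[free] * scale, 1.0)
        newly_capped = free & (probs >= 1.0)
        if not newly_capped.any():
            break
        free = free & ~newly_capped
    return np.clip(probs, 0.0, 1.0)


def simulate_digest(config: DigestionConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a peptide identification table for one substrate.

    For every (animal, time point), ``molecules_per_protein`` independent
    digestion realisations of each protein are pooled; fragments inside the
    observable length window receive log-normal intensities (repeated
    identifications of a peptide in a sample have their intensities summed).
    Samples exceeding ``peptides_per_sample_target`` unique peptides are
    subsampled to the target.  Fully deterministic given the seed.

    Returns the public peptide table (sequence, intensity, substrate,
    time_min, animal_id) and a :class:`SyntheticTruth` carrying the
    generating locus of every emitted row.
    """
    rng = np.random.default_rng(config.seed)
    proteins = config.resolved_proteins()
    probs = {p.protein_id: _bond_probabilities(p, config) for p in proteins}

    rows: list[dict] = []
    loci: list[dict] = []
    empty_samples: list[tuple[str, int]] = []
    for animal_index in range(config.n_animals):
        animal_id = f"pig{animal_index + 1}"
        for time_min in config.time_points:
            sample: dict[tuple[str, int, int], float] = {}
            for protein in proteins:
                p = probs[protein.protein_id]
                length = len(protein)
                for _ in range(config.molecules_per_protein):
                    cuts = np.flatnonzero(rng.random(len(p)) < p) + 1  # cut after residue i
                    bounds = np.concatenate(([0], cuts, [length]))
                    for lo, hi in zip(bounds[:-1], bounds[1:]):
                        frag_len = hi - lo
                        if not (config.min_len <= frag_len <= config.max_len):
                            continue
                        intensity = 10.0 ** rng.normal(
                            config.intensity_logmean, config.intensity_logsd
                        )
                        key = (protein.protein_id, int(lo) + 1, int(hi))
                        sample[key] = sample.get(key, 0.0) + intensity
            if not sample:
                warnings.warn(
                    f"empty synthetic sample ({animal_id}, t={time_min} min): "
                    "hydrolysis_extent may be too high for the length window",
                    stacklevel=2,
                )
                empty_samples.append((animal_id, time_min))
                continue
            keys = sorted(sample)
            if len(keys) > config.peptides_per_sample_target:
                # keep the most intense peptides, as data-dependent MS
                # acquisition does; ties broken by locus for determinism
                keys = sorted(sample, key=lambda k: (-sample[k], k))
                keys = sorted(keys[: config.peptides_per_sample_target])
            protein_by_id = {p.protein_id: p for p in proteins}
            for pid, start, end in keys:
                rows.append(
                    {
                        "sequence": protein_by_id[pid].slice(start, end),
                        "intensity": sample[(pid, start, end)],
                        "substrate": config.substrate,
                        "time_min": time_min,
                        "animal_id": animal_id,
                    }
                )
                loci.append({"protein_id": pid, "start": start, "end": end})

    table = pd.DataFrame(rows, columns=["sequence", "intensity", "substrate", "time_min", "animal_id"])
    truth = SyntheticTruth(
        loci=pd.DataFrame(loci, columns=["protein_id", "start", "end"]),
        cut_probabilities=probs,
        config=config,
        empty_samples=empty_samples,
    )
    return table, truth


def default_study_configs(seed: int = 0) -> tuple[DigestionConfig, DigestionConfig]:
    """The two-substrate study conditions.

    Casein: moderate hydrolysis on duodenal arrival (extent 0.30) with the
    C-terminal domain of beta-casein (193-209) protected (factor 0.1),
    reflecting its documented resistance to gastric digestion.  Hydrolysate:
    extensive pre-hydrolysis (extent 0.50), no protected region, and a
    slightly smaller per-sample identification cap (shorter peptides fall
    below the MS floor).  Defaults reproduce the magnitudes of real duodenal
    peptidomes: a few hundred unique peptides per time point, with roughly a
    quarter of casein peptides longer than 10 residues against under a tenth
    for the hydrolysate.  Seeds are offset so the two substrates use
    independent random streams.
    """
    casein = DigestionConfig(
        substrate="casein",
        hydrolysis_extent=0.30,
        protected_regions=((*BETA_CN_CTERM_REGION, 0.1),),
        seed=seed,
    )
    hydrolysate = DigestionConfig(
        substrate="hydrolysate",
        hydrolysis_extent=0.50,
        protected_regions=(),
        peptides_per_sample_target=150,
        seed=seed + 104729,  # distinct stream for the second substrate
    )
    return casein, hydrolysate


def simulate_study(seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth, SyntheticTruth]:
    """Digest both default substrates and concatenate their peptide tables."""
    casein_cfg, hydrolysate_cfg = default_study_configs(seed)
    casein_table, casein_truth = simulate_digest(casein_cfg)
    hydro_table, hydro_truth = simulate_digest(hydrolysate_cfg)
    table = pd.concat([casein_table, hydro_table], ignore_index=True)
    return table, casein_truth, hydro_truth


# ---------------------------------------------------------------------------
# plasma generator


@dataclass(frozen=True)
class PlasmaEffectSpec:
    """Substrate-specific mean concentration curves for the analytes.

    ``curves[analyte][substrate]`` maps each time point of the sampling grid
    to a mean concentration (umol/L).  ``animal_sd`` is the SD of a per-
    animal additive offset (shared across times within one substrate
    series); ``noise_sd`` is the SD of independent Gaussian measurement
    noise.
    """

    curves: Mapping[str, Mapping[str, Mapping[int, float]]]
    noise_sd: float = 4.0
    animal_sd: float = 2.0
    n_animals: int = 6
    times: tuple[int, ...] = PLASMA_TIME_GRID


def default_plasma_spec(n_animals: int = 6) -> PlasmaEffectSpec:
    """Mean curves emulating postprandial plasma amino-acid kinetics.

    The hydrolysate curves rise faster and peak higher before 200 min
    (indispensable amino acids peaking around 45 min) and converge with the
    casein curves by 360 min.
    """
    grid = PLASMA_TIME_GRID

    def curve(points: Sequence[float]) -> dict[int, float]:
        return dict(zip(grid, points))

    curves = {
        "methionine": {
            "casein": curve([28, 30, 33, 37, 39, 41, 39, 36, 32]),
            "hydrolysate": curve([28, 35, 46, 56, 53, 45, 40, 36, 32]),
        },
        "lysine": {
            "casein": curve([160, 168, 180, 196, 205, 212, 205, 196, 178]),
            "hydrolysate": curve([160, 185, 225, 262, 250, 228, 210, 196, 178]),
        },
        "valine": {
            "casein": curve([210, 215, 224, 238, 248, 262, 258, 248, 228]),
            "hydrolysate": curve([210, 228, 258, 292, 290, 276, 258, 245, 228]),
        },
        "glycine": {  # a null analyte: no substrate effect
            "casein": curve([520, 520, 518, 515, 512, 510, 512, 515, 518]),
            "hydrolysate": curve([520, 520, 518, 515, 512, 510, 512, 515, 518]),
        },
    }
    return PlasmaEffectSpec(curves=curves, noise_sd=6.0, animal_sd=3.0, n_animals=n_animals)


def null_plasma_spec(
    analyte: str = "glycine",
    level: float = 250.0,
    noise_sd: float = 6.0,
    n_animals: int = 6,
) -> PlasmaEffectSpec:
    """Identical flat curves for both substrates (type-I-error calibration)."""
    flat = {t: level for t in PLASMA_TIME_GRID}
    return PlasmaEffectSpec(
        curves={analyte: {"casein": dict(flat), "hydrolysate": dict(flat)}},
        noise_sd=noise_sd,
        animal_sd=0.0,
        n_animals=n_animals,
    )


def shifted_plasma_spec(
    analyte: str = "methionine",
    level: float = 40.0,
    shift: float = 12.0,
    shift_times: Sequence[int] = (5, 20, 45, 60),
    noise_sd: float = 4.0,
    n_animals: int = 6,
) -> PlasmaEffectSpec:
    """Flat casein curve with a planted hydrolysate shift at early times."""
    casein = {t: level for t in PLASMA_TIME_GRID}
    hydrolysate = {
        t: level + (shift if t in set(shift_times) else 0.0) for t in PLASMA_TIME_GRID
    }
    return PlasmaEffectSpec(
        curves={analyte: {"casein": casein, "hydrolysate": hydrolysate}},
        noise_sd=noise_sd,
        animal_sd=0.0,
        n_animals=n_animals,
    )


def simulate_plasma(spec: PlasmaEffectSpec, seed: int = 0) -> pd.DataFrame:
    """Draw a long-format plasma concentration table from an effect spec.

    concentration = mean curve + animal offset + Gaussian noise, truncated
    at 0 (with a warning).  Deterministic given the seed; analytes,
    substrates, animals and times are iterated in a fixed order.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_truncated = 0
    for analyte in sorted(spec.curves):
        by_substrate = spec.curves[analyte]
        for substrate in sorted(by_substrate):
            curve = by_substrate[substrate]
            for animal_index in range(spec.n_animals):
                offset = rng.normal(0.0, spec.animal_sd) if spec.animal_sd > 0 else 0.0
                for time_min in spec.times:
                    value = curve[time_min] + offset + rng.normal(0.0, spec.noise_sd)
                    if value < 0:
                        n_truncated += 1
                        value = 0.0
                    rows.append(
                        {
                            "analyte": analyte,
                            "animal_id": f"pig{animal_index + 1}",
                            "substrate": substrate,
                            "time_min": time_min,
                            "concentration": value,
                        }
                    )
    if n_truncated:
        warnings.warn(f"{n_truncated} negative concentration(s) truncated at 0", stacklevel=2)
    return pd.DataFrame(rows, columns=list(PLASMA_COLUMNS))
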