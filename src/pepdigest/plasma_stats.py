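"""Plasma amino-acid time-course comparison between two substrates.

For each analyte, a balanced fixed-effects two-way ANOVA (substrate x time)
is computed from cell means, followed by per-time-point substrate contrasts
using t statistics on the pooled error term with Bonferroni adjustment over
the time points tested.  The blood-sampling design grid is the basal draw at
-15 min plus eight post-intake draws out to 6 h.

The animals in a crossover design receive both substrates, which this plain
fixed-effects ANOVA deliberately does not model (no animal factor, no
repeated-measures correlation); see the package methods note for the caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .peptide_mapping import ConfigError

#: Blood sampling grid (minutes): basal, then 5, 20, 45 min, 1, 2, 3, 4, 6 h.
PLASMA_TIME_GRID = (-15, 5, 20, 45, 60, 120, 180, 240, 360)

PLASMA_COLUMNS = ("analyte", "animal_id", "substrate", "time_min", "concentration")


@dataclass
class PlasmaSeries:
    """Long-format concentration records (umol/L) for one analyte."""

    analyte: str
    records: pd.DataFrame  # columns: animal_id, substrate, time_min, concentration

    def __post_init__(self) -> None:
        missing = {"animal_id", "substrate", "time_min", "concentration"} - set(
            self.records.columns
        )
        if missing:
            raise ConfigError(f"{self.analyte}: records missing column(s) {sorted(missing)}")
        if (self.records["concentration"] < 0).any():
            raise ValueError(f"{self.analyte}: negative concentration")


@dataclass
class AnovaReport:
    """Two-way ANOVA with per-time Bonferroni-adjusted substrate contrasts."""

    analyte: str
    f_substrate: float
    p_substrate: float
    f_time: float
    p_time: float
    f_interaction: float
    p_interaction: float
    per_time: pd.DataFrame  # time_min, mean_diff, t, p_raw, p_bonferroni, stars
    ss: dict = field(default_factory=dict)
    df: dict = field(default_factory=dict)

    def significant_times(self, alpha: float = 0.05) -> list[int]:
        mask = self.per_time["p_bonferroni"] < alpha
        return [int(t) for t in self.per_time.loc[mask, "time_min"]]


def split_series(table: pd.DataFrame) -> list[PlasmaSeries]:
    """Split a long-format plasma table (one row per measurement) by analyte."""
    missing = set(PLASMA_COLUMNS) - set(table.columns)
    if missing:
        raise ConfigError(f"plasma table missing column(s) {sorted(missing)}")
    return [
        PlasmaSeries(analyte=str(analyte), records=group.drop(columns="analyte").reset_index(drop=True))
        for analyte, group in table.groupby("analyte", sort=True)
    ]


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def two_way_anova(series: PlasmaSeries) -> AnovaReport:
    """Balanced two-way fixed-effects ANOVA (substrate x time) for one analyte.

    Sums of squares are computed from cell means on a balanced design (equal
    replicates per substrate-time cell); per-time substrate differences use
    t statistics on the pooled mean-square error, with Bonferroni adjustment
    over the number of time points tested.

    Raises on empty cells or unbalanced designs (general unbalanced SS
    decompositions are out of scope).
    """
    rec = series.records
    substrates = sorted(rec["substrate"].unique())
    times = sorted(rec["time_min"].unique())
    if len(substrates) < 2:
        raise ConfigError(f"{series.analyte}: need >= 2 substrates, got {substrates}")
    if len(times) < 2:
        raise ConfigError(f"{series.analyte}: need >= 2 time points")
    a, b = len(substrates), len(times)

    sizes = rec.groupby(["substrate", "time_min"])["concentration"].size()
    for s in substrates:
        for t in times:
            if (s, t) not in sizes.index:
                raise ValueError(f"{series.analyte}: empty cell (substrate={s}, time={t})")
    if sizes.nunique() != 1:
        raise ValueError(
            f"{series.analyte}: unbalanced design (cell sizes {sorted(sizes.unique())}); "
            "only balanced designs are supported"
        )
    n = int(sizes.iloc[0])
    if n < 2:
        raise ValueError(f"{series.analyte}: need >= 2 replicates per cell")

    y = rec["concentration"].to_numpy(dtype=float)
    grand = y.mean()
    cell_means = rec.groupby(["substrate", "time_min"])["concentration"].mean()
    means_s = rec.groupby("substrate")["concentration"].mean()
    means_t = rec.groupby("time_min")["concentration"].mean()

    ss_substrate = b * n * float(((means_s - grand) ** 2).sum())
    ss_time = a * n * float(((means_t - grand) ** 2).sum())
    ss_cells = n * float(((cell_means - grand) ** 2).sum())
    ss_interaction = ss_cells - ss_substrate - ss_time
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = ss_total - ss_cells

    df_s, df_t = a - 1, b - 1
    df_int = df_s * df_t
    df_err = a * b * (n - 1)
    ms_error = ss_error / df_err

    def f_and_p(ss: float, df_num: int) -> tuple[float, float]:
        if ms_error == 0:
            return (0.0, 1.0) if ss <= 1e-300 else (np.inf, 0.0)
        f = (ss / df_num) / ms_error
        return f, float(stats.f.sf(f, df_num, df_err))

    f_s, p_s = f_and_p(ss_substrate, df_s)
    f_t, p_t = f_and_p(ss_time, df_t)
    f_i, p_i = f_and_p(ss_interaction, df_int)

    # per-time contrasts between the two first substrates on the pooled error
    s0, s1 = substrates[0], substrates[1]
    rows = []
    n_family = len(times)
    for t in times:
        diff = float(cell_means[(s0, t)] - cell_means[(s1, t)])
        if ms_error == 0:
            t_stat = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p_raw = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(ms_error * 2.0 / n)
            t_stat = diff / se
            p_raw = float(2 * stats.t.sf(abs(t_stat), df_err))
        p_adj = min(1.0, p_raw * n_family)
        rows.append(
            {
                "time_min": t,
                "mean_diff": diff,
                "t": t_stat,
                "p_raw": p_raw,
                "p_bonferroni": p_adj,
                "stars": _stars(p_adj),
            }
        )
    per_time = pd.DataFrame(rows)

    return AnovaReport(
        analyte=series.analyte,
        f_substrate=f_s, p_substrate=p_s,
        f_time=f_t, p_time=p_t,
        f_interaction=f_i, p_interaction=p_i,
        per_time=per_time,
        ss={
            "substrate": ss_substrate, "time": ss_time,
            "interaction": ss_interaction, "error": ss_error, "total": ss_total,
        },
        df={"substrate": df_s, "time": df_t, "interaction": df_int, "error": df_err},
    )


def summarize_series(series: PlasmaSeries) -> pd.DataFrame:
    """Per (substrate, time) mean and standard error of the mean.

    Cells with a single record get SE 0 and ``se_defined=False``.
    """
    grouped = series.records.groupby(["substrate", "time_min"])["concentration"]
    out = grouped.agg(mean="mean", n="size", sd=lambda v: v.std(ddof=1)).reset_index()
    out["se_defined"] = out["n"] > 1
    out["se"] = np.where(out["se_defined"], out["sd"].fillna(0.0) / np.sqrt(out["n"]), 0.0)
    out["analyte"] = series.analyte
    return out[["analyte", "substrate", "time_min", "n", "mean", "se", "se_defined"]]


def anova_table(reports: Iterable[AnovaReport]) -> pd.DataFrame:
    """Flatten per-analyte reports into one long per-time table."""
    frames = []
    for rep in reports:
        frame = rep.per_time.copy()
        frame.insert(0, "analyte", rep.analyte)
        frame["p_substrate"] = rep.p_substrate
        frame["p_time"] = rep.p_time
        frame["p_interaction"] = rep.p_interaction
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
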