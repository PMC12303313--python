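"""Growth-curve statistics on chlorophyll-a fluorescence (RFU) time series.

Two analyses, per species: a fixed-effects two-way ANOVA with replication on
culture condition (mono vs co) x sampling day, reported spreadsheet-style
(SS, df, MS, F, P-value, F crit); and per-day Welch t-tests (two-tailed,
unequal variance) comparing mono- against co-culture RFU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .tables_io import GrowthSeries

ANOVA_SOURCES = ("sample", "days", "interaction", "within")


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_diff: float


def growth_long_frame(series: Iterable[GrowthSeries]) -> pd.DataFrame:
    """Long layout: one row per (culture, day, replicate) observation."""
    rows = []
    for s in series:
        for day, rfu in sorted(s.observations.items()):
            rows.append(
                {"species": s.species, "culture": s.culture,
                 "replicate": s.replicate, "day": day, "rfu": rfu}
            )
    return pd.DataFrame(rows)


def two_way_anova(
    series: Iterable[GrowthSeries],
    alpha: float = 0.05,
    interaction: bool = True,
) -> pd.DataFrame:
    """Two-factor (culture x day) fixed-effects ANOVA with replication.

    Requires a balanced design: every (culture, day) cell must hold the same
    replicate count r >= 2.  Returns a table indexed by source of variation
    (sample = culture condition, days, interaction, within) with columns
    SS, df, MS, F, p, F_crit.  ``interaction=False`` fits the additive model,
    pooling the interaction into the residual.
    """
    data = growth_long_frame(series)
    if data.empty:
        raise DegenerateDataError("no growth observations")
    counts = data.groupby(["culture", "day"]).size()
    cultures = sorted(data["culture"].unique())
    days = sorted(data["day"].unique())
    if len(cultures) < 2 or len(days) < 2:
        raise ValidationError("need both culture levels and >= 2 days")
    expected = {(c, d) for c in cultures for d in days}
    if set(counts.index) != expected or counts.nunique() != 1:
        off = sorted(expected - set(counts.index)) or [counts.idxmin()]
        raise ValidationError(f"unbalanced design at cell {off[0]}")
    r = int(counts.iloc[0])
    if r < 2:
        raise ValidationError("need >= 2 replicates per cell for within-cell variance")
    if data["rfu"].nunique() == 1:
        raise DegenerateDataError("all observations identical; no variance to partition")

    y = data["rfu"].to_numpy(dtype=float)
    grand = y.mean()
    a, b = len(cultures), len(days)
    cell = data.groupby(["culture", "day"])["rfu"].mean()
    row = data.groupby("culture")["rfu"].mean()
    col = data.groupby("day")["rfu"].mean()

    ss_a = float(b * r * ((row - grand) ** 2).sum())
    ss_b = float(a * r * ((col - grand) ** 2).sum())
    inter = cell.copy()
    for (c, d), m in cell.items():
        inter[(c, d)] = m - row[c] - col[d] + grand
    ss_ab = float(r * (inter ** 2).sum())
    cell_map = cell.to_dict()
    resid = y - np.array([cell_map[(c, d)] for c, d in zip(data["culture"], data["day"])])
    ss_w = float((resid ** 2).sum())

    rows = {}
    if interaction:
        df_w = a * b * (r - 1)
        ms_w = ss_w / df_w
        sources = [("sample", ss_a, a - 1), ("days", ss_b, b - 1),
                   ("interaction", ss_ab, (a - 1) * (b - 1))]
    else:
        df_w = a * b * r - a - b + 1
        ss_w = ss_w + ss_ab
        ms_w = ss_w / df_w
        sources = [("sample", ss_a, a - 1), ("days", ss_b, b - 1)]
    if ms_w == 0.0:
        raise DegenerateDataError("zero within-cell variance; F undefined")
    for name, ss, df in sources:
        f = (ss / df) / ms_w
        rows[name] = {
            "SS": ss, "df": df, "MS": ss / df, "F": f,
            "p": float(stats.f.sf(f, df, df_w)),
            "F_crit": float(stats.f.ppf(1 - alpha, df, df_w)),
        }
    rows["within"] = {"SS": ss_w, "df": df_w, "MS": ms_w,
                      "F": np.nan, "p": np.nan, "F_crit": np.nan}
    out = pd.DataFrame(rows).T.loc[[s for s in ANOVA_SOURCES if s in rows]]
    out.index.name = "source"
    return out


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's two-tailed t-test (unequal variances).

    Convention: if both groups have zero variance and equal means the result
    is t = 0, p = 1 (no evidence of a difference, rather than NaN).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError(f"each group needs >= 2 values (got {x.size} and {y.size})")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite value in input")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    mean_diff = float(x.mean() - y.mean())
    if vx == 0.0 and vy == 0.0:
        if mean_diff == 0.0:
            return WelchResult(t=0.0, df=float(x.size + y.size - 2), p=1.0, mean_diff=0.0)
        return WelchResult(t=np.inf if mean_diff > 0 else -np.inf,
                           df=float(x.size + y.size - 2), p=0.0, mean_diff=mean_diff)
    se2x, se2y = vx / x.size, vy / y.size
    df = (se2x + se2y) ** 2 / (
        se2x ** 2 / (x.size - 1) + se2y ** 2 / (y.size - 1)
    )
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(df),
                       p=float(res.pvalue), mean_diff=mean_diff)


def per_day_welch(
    series: Iterable[GrowthSeries],
    mono_replicates: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Welch t-test mono vs co for every sampling day.

    ``mono_replicates`` restricts the mono-culture group (e.g. replicates 1-4
    to match the 4 co-culture replicates); None uses all.
    """
    data = growth_long_frame(series)
    out = []
    for day in sorted(data["day"].unique()):
        sub = data[data["day"] == day]
        mono = sub[sub["culture"] == "mono"]
        if mono_replicates is not None:
            mono = mono[mono["replicate"].isin(mono_replicates)]
        co = sub[sub["culture"] == "co"]
        res = welch_t_test(mono["rfu"].to_numpy(), co["rfu"].to_numpy())
        out.append({"day": day, "t": res.t, "df": res.df, "p": res.p,
                    "mean_diff": res.mean_diff})
    return pd.DataFrame(out).set_index("day")


def growth_statistics(
    series: Iterable[GrowthSeries],
    alpha: float = 0.05,
    mono_replicates: Sequence[int] = (1, 2, 3, 4),
) -> dict[str, pd.DataFrame]:
    """Per-species ANOVA (4 mono + 4 co replicates by default) and per-day Welch tests.

    Returns ``{"anova_<species>": AnovaTable, "welch_<species>": per-day table}``.
    The choice of which mono replicates enter the balanced ANOVA is exposed; a
    sensitivity note across the complementary choice is included when 8 mono
    replicates exist.
    """
    all_series = list(series)
    out: dict[str, pd.DataFrame] = {}
    for sp in sorted({s.species for s in all_series}):
        sp_series = [s for s in all_series if s.species == sp]
        subset = [
            s for s in sp_series
            if s.culture == "co" or s.replicate in set(mono_replicates)
        ]
        out[f"anova_{sp}"] = two_way_anova(subset, alpha=alpha)
        out[f"welch_{sp}"] = per_day_welch(sp_series, mono_replicates=mono_replicates)
    return out
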