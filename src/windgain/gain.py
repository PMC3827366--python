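"""Population-scale daily foraging mass gain and its descriptive tests.

Individual birds rarely yield an accurate mass in both the morning and the
evening of the same day, so gain is computed on the population scale: for
each day, the mean mass of adults returning in the evening minus the mean
mass of adults leaving in the morning. The pooled (both-sex) gain pools
*individuals* before averaging — it is a difference of pooled window means,
not an average of the per-sex gains, because the two sexes contribute
different numbers of birds to each window.

Days lacking either window for a group have an undefined (missing) gain,
never zero. Days where either window has fewer than ``min_n`` accepted birds
are flagged ``low_n`` but retained; dropping them is the caller's choice.
"""

from __future__ import annotations

import pandas as pd

from .stats import (
    CorrelationResult,
    PairedTResult,
    TwoSampleTResult,
    paired_t,
    pearson,
    two_sample_t,
)

__all__ = [
    "daily_gain",
    "paired_t_morning_evening",
    "sex_comparison",
    "SexComparison",
    "gain_summary",
]

#: Default low-sample flag threshold: accepted birds per window.
DEFAULT_MIN_N = 15

_DAILY_COLUMNS = [
    "date",
    "season",
    "stage",
    "sex",
    "n_morning",
    "n_evening",
    "mean_morning_g",
    "mean_evening_g",
    "gain_g",
    "low_n",
]


def daily_gain(clean: pd.DataFrame, min_n: int = DEFAULT_MIN_N) -> pd.DataFrame:
    """Per-day gain statistics for females, males and the pooled population.

    Parameters
    ----------
    clean
        Deduplicated clean-mass table (columns ``pit_id, date, window,
        mass_g, sex, season, stage``), as produced by
        :func:`windgain.qc.run_qc`.
    min_n
        Flag threshold: a day×group row is marked ``low_n`` when either
        window has fewer than this many birds.

    Returns
    -------
    DataFrame
        One row per (date, sex) with sex ∈ {"F", "M", "pooled"}:
        window sample sizes and means, ``gain_g = mean_evening −
        mean_morning`` (NaN when either window is empty), and the ``low_n``
        flag. Each day's row is independent of every other day.
    """
    if clean.empty:
        return pd.DataFrame(columns=_DAILY_COLUMNS)
    df = clean.copy()
    df["date"] = df["date"].astype(str)
    rows = []
    for date, day in df.groupby("date", sort=True):
        season = day["season"].iloc[0]
        stage = day["stage"].iloc[0]
        for sex in ("F", "M", "pooled"):
            sub = day if sex == "pooled" else day[day["sex"] == sex]
            morning = sub.loc[sub["window"] == "morning", "mass_g"]
            evening = sub.loc[sub["window"] == "evening", "mass_g"]
            n_m, n_e = len(morning), len(evening)
            mean_m = morning.mean() if n_m else float("nan")
            mean_e = evening.mean() if n_e else float("nan")
            gain = mean_e - mean_m if (n_m and n_e) else float("nan")
            rows.append(
                {
                    "date": date,
                    "season": season,
                    "stage": stage,
                    "sex": sex,
                    "n_morning": n_m,
                    "n_evening": n_e,
                    "mean_morning_g": mean_m,
                    "mean_evening_g": mean_e,
                    "gain_g": gain,
                    "low_n": min(n_m, n_e) < min_n,
                }
            )
    return pd.DataFrame(rows, columns=_DAILY_COLUMNS)


def paired_t_morning_evening(
    daily: pd.DataFrame, sexes: tuple[str, ...] = ("F", "M")
) -> PairedTResult:
    """Paired t-test of mean evening vs mean morning mass.

    The paired unit is one day×group mean (one row of ``daily`` for each sex
    in ``sexes``, across all seasons and stages); pass ``sexes=("pooled",)``
    to pair on the pooled day means instead. Rows missing either window mean
    are excluded.
    """
    sub = daily[daily["sex"].isin(sexes)].dropna(
        subset=["mean_morning_g", "mean_evening_g"]
    )
    if len(sub) < 2:
        raise ValueError("need at least 2 day×group pairs")
    return paired_t(sub["mean_morning_g"].to_numpy(), sub["mean_evening_g"].to_numpy())


class SexComparison:
    """Crèche-stage male/female comparison: gain difference and concordance."""

    def __init__(self, ttest: TwoSampleTResult, correlation: CorrelationResult, n_days: int):
        self.ttest = ttest
        self.correlation = correlation
        self.n_days = n_days

    def __repr__(self):
        t, c = self.ttest, self.correlation
        return (
            f"SexComparison(t_{t.df:g} = {t.statistic:.3f}, p = {t.pvalue:.3f}; "
            f"r = {c.r:.2f}, p = {c.pvalue:.3g}, n = {c.n} days)"
        )


def sex_comparison(
    daily: pd.DataFrame, stage: str = "creche", equal_var: bool = True
) -> SexComparison:
    """Compare daily gains between the sexes during one chick-rearing stage.

    Two results: an independent t-test (Student equal-variance by default,
    Welch via ``equal_var=False``) on the per-sex daily gains, and a Pearson
    correlation of day-matched (male, female) gain pairs — the concordance
    that indicates both sexes experience the same daily foraging conditions.
    With fewer than 3 matched days the correlation is reported undefined.
    """
    sub = daily[daily["stage"] == stage]
    f = sub[(sub["sex"] == "F")].dropna(subset=["gain_g"])
    m = sub[(sub["sex"] == "M")].dropna(subset=["gain_g"])
    ttest = two_sample_t(f["gain_g"].to_numpy(), m["gain_g"].to_numpy(), equal_var=equal_var)
    merged = pd.merge(
        f[["date", "gain_g"]], m[["date", "gain_g"]], on="date", suffixes=("_f", "_m")
    )
    corr = pearson(merged["gain_g_m"].to_numpy(), merged["gain_g_f"].to_numpy())
    return SexComparison(ttest, corr, n_days=len(merged))


def gain_summary(daily: pd.DataFrame) -> pd.DataFrame:
    """Per (season × stage × sex) summary of daily gains: mean ± SD and range."""
    sub = daily.dropna(subset=["gain_g"])
    out = (
        sub.groupby(["season", "stage", "sex"])["gain_g"]
        .agg(n_days="count", mean_g="mean", sd_g="std", min_g="min", max_g="max")
        .reset_index()
    )
    return out
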