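"""Independent brute-force re-implementations used as test oracles.

These deliberately re-derive the QC filter rules with plain vectorised
pandas, in a different style from the pipeline's per-crossing cascade, so
that agreement between the two is informative.
"""

import numpy as np
import pandas as pd


def brute_force_qc(crossings: pd.DataFrame, registry: pd.DataFrame, calendar: pd.DataFrame):
    """Classify every crossing by the first failing rule ('' = accepted).

    Returns a DataFrame aligned with ``crossings`` carrying ``rule``,
    ``mass_g`` and ``date`` columns. Deduplication is excluded (it is a
    seeded random choice, not a deterministic rule).
    """
    df = crossings.copy().reset_index(drop=True)
    ts = pd.to_datetime(df["timestamp"])
    df["date"] = ts.dt.date.astype(str)
    minute = ts.dt.hour * 60 + ts.dt.minute
    in_morning = (minute >= 80) & (minute <= 599)
    in_evening = (minute >= 600) & (minute <= 1420)

    reg = registry.astype(str).set_index("pit_id")["sex"]
    df["sex"] = df["pit_id"].astype(str).map(reg)
    cal = calendar.copy()
    cal["date"] = cal["date"].astype(str)
    df = df.merge(cal[["date", "stage"]], on="date", how="left")

    mass_cols = [c for c in df.columns if c.startswith("mass_")]
    masses = df[mass_cols].astype(float)
    n_rec = masses.notna().sum(axis=1)
    spread = masses.max(axis=1) - masses.min(axis=1)
    mean = masses.mean(axis=1)

    female = df["sex"] == "F"
    lo = np.where(female, 1700.0, 2000.0)
    hi = np.where(female, 3500.0, 3900.0)

    rule = np.select(
        [
            df["sex"].isna(),
            df["stage"].isna(),
            ~(in_morning | in_evening),
            (df["sex"] == "M") & (df["stage"] == "guard"),
            n_rec < 2,
            spread >= 200.0,
            (mean < lo) | (mean > hi),
        ],
        [
            "unknown-pit",
            "unknown-date",
            "outside-window",
            "male-during-guard",
            "too-few-recordings",
            "spread",
            "out-of-bounds",
        ],
        default="",
    )
    out = df[["pit_id", "timestamp", "date"]].copy()
    out["rule"] = rule
    out["mass_g"] = mean
    out["window"] = np.select([in_morning, in_evening], ["morning", "evening"], "outside")
    return out


def textbook_paired_t(x, y):
    """Closed-form paired t: mean(d) / (sd(d)/sqrt(n)), d = y − x."""
    d = np.asarray(y, float) - np.asarray(x, float)
    n = d.size
    return d.mean() / (d.std(ddof=1) / np.sqrt(n)), n - 1


def textbook_student_t(a, b):
    """Closed-form equal-variance two-sample t."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2)), n1 + n2 - 2


def textbook_pearson_r(x, y):
    """Closed-form Pearson r from the covariance formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
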