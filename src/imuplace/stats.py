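"""Significance screening of IMU channels across surfaces and locations.

Each trial's 400-sample window is reduced to one scalar per channel (RMS by
default — amplitude-sensitive and robust to sign conventions; mean and SD
selectable).  Welch's heteroscedastic one-way ANOVA then tests, per channel
output, (i) the seven surfaces within one body location and (ii) the six
locations within one surface, followed by Bonferroni-corrected pairwise
Welch t tests labelled Significant/Insignificant at p < 0.001.

The ANOVA statistic is hand-authored (variance-weighted group means,
Welch-Satterthwaite denominator degrees of freedom); it is independently
cross-checked against an established implementation in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import (
    AXES,
    SENSORS,
    BodyLocation,
    ComparisonDescriptor,
    IMUTrial,
    SurfaceClass,
    WINDOW_SAMPLES,
    all_channels,
    comparison_schedule,
)

__all__ = [
    "TrialSummary",
    "summarize_trials",
    "WelchAnovaResult",
    "welch_anova",
    "SignificanceResult",
    "pairwise_posthoc",
    "SignificanceMatrix",
    "significance_screen",
    "ALPHA",
]

#: the screening significance threshold on the adjusted p-value
ALPHA = 0.001

Statistic = Literal["rms", "mean", "sd"]


@dataclass(frozen=True)
class TrialSummary:
    participant_id: int
    surface: SurfaceClass
    trial_index: int
    location: BodyLocation
    sensor: str
    axis: str
    value: float


def _reduce(window: np.ndarray, statistic: Statistic) -> np.ndarray:
    if window.size == 0:
        raise ValueError("empty window")
    if statistic == "rms":
        return np.sqrt(np.mean(window**2, axis=-1))
    if statistic == "mean":
        return np.mean(window, axis=-1)
    if statistic == "sd":
        return np.std(window, axis=-1, ddof=1)
    raise ValueError(f"unknown summary statistic: {statistic!r}")


def summarize_trials(
    trials: Sequence[IMUTrial],
    statistic: Statistic = "rms",
    window_start: int = 0,
    window_len: int = WINDOW_SAMPLES,
) -> pd.DataFrame:
    """One scalar per (trial, channel) over the analysis window.

    Returns a long-format frame with columns participant_id, surface,
    trial_index, location, sensor, axis, value (36 rows per trial).
    """
    if window_len <= 0:
        raise ValueError("empty window")
    channels = all_channels()
    rows = []
    for trial in trials:
        end = window_start + window_len
        if trial.n_samples < end:
            raise ValueError(
                f"trial has {trial.n_samples} samples, window needs {end}"
            )
        values = _reduce(trial.samples[:, window_start:end], statistic)
        for ch, v in zip(channels, values):
            rows.append(
                (
                    trial.participant_id,
                    trial.surface.value,
                    trial.trial_index,
                    ch.location.value,
                    ch.sensor,
                    ch.axis,
                    float(v),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "surface",
            "trial_index",
            "location",
            "sensor",
            "axis",
            "value",
        ],
    )


class WelchAnovaResult(NamedTuple):
    F: float
    df1: float
    df2: float
    p_value: float


def welch_anova(groups: Sequence[Sequence[float]]) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA.

    With group sizes n_i, means m_i and variances s_i^2, the weights are
    w_i = n_i / s_i^2, the weighted grand mean is mw = sum(w_i m_i)/sum(w_i),
    and

        F = [sum w_i (m_i - mw)^2 / (k-1)]
            / [1 + 2(k-2)/(k^2-1) * sum (1 - w_i/sum(w))^2 / (n_i-1)]

    with df1 = k-1 and Welch-Satterthwaite
    df2 = (k^2-1) / (3 sum (1 - w_i/sum(w))^2 / (n_i-1)); the p-value is
    the upper tail of F(df1, df2).
    """
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need at least two groups")
    n = np.array([a.size for a in arrs], dtype=np.float64)
    if np.any(n < 2):
        raise ValueError("each group needs at least two values")
    m = np.array([a.mean() for a in arrs])
    s2 = np.array([a.var(ddof=1) for a in arrs])
    if np.any(s2 <= 0):
        raise ValueError("a group has zero variance; Welch weights are undefined")
    w = n / s2
    sw = w.sum()
    mw = (w * m).sum() / sw
    between = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = ((1.0 - w / sw) ** 2 / (n - 1.0)).sum()
    F = between / (1.0 + 2.0 * (k - 2.0) / (k**2 - 1.0) * lam)
    df1 = float(k - 1)
    df2 = (k**2 - 1.0) / (3.0 * lam)
    p = float(sstats.f.sf(F, df1, df2))
    return WelchAnovaResult(float(F), df1, float(df2), p)


@dataclass(frozen=True)
class SignificanceResult:
    """One pairwise comparison, labelled at the p < 0.001 threshold."""

    comparison: ComparisonDescriptor
    statistic: float
    df1: float
    df2: float
    p_value: float
    p_adjusted: float
    adjusted_alpha: float
    significant: bool

    @property
    def label(self) -> str:
        return "Significant" if self.significant else "Insignificant"


def _welch_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t (statistic, df, two-sided p)."""
    if a.var(ddof=1) <= 0 and b.var(ddof=1) <= 0:
        raise ValueError("both groups have zero variance")
    res = sstats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pairwise_posthoc(
    groups: dict,
    family_size: int | None = None,
    alpha: float = ALPHA,
    descriptor_factory=None,
) -> list[SignificanceResult]:
    """Bonferroni-corrected Welch t tests for every unordered group pair.

    ``groups`` maps a group key to its values.  The adjusted p is
    min(1, p * family_size) (family defaults to the number of pairs), and
    a pair is Significant iff the adjusted p falls below ``alpha``.
    """
    keys = list(groups)
    pairs = list(itertools.combinations(keys, 2))
    family = family_size if family_size is not None else len(pairs)
    out = []
    for ka, kb in pairs:
        a = np.asarray(groups[ka], dtype=np.float64)
        b = np.asarray(groups[kb], dtype=np.float64)
        t, df, p = _welch_pair(a, b)
        p_adj = min(1.0, p * family)
        desc = descriptor_factory(ka, kb) if descriptor_factory else (ka, kb)
        out.append(
            SignificanceResult(
                comparison=desc,
                statistic=t,
                df1=1.0,
                df2=df,
                p_value=p,
                p_adjusted=p_adj,
                adjusted_alpha=alpha,
                significant=p_adj < alpha,
            )
        )
    return out


@dataclass
class SignificanceMatrix:
    """All pairwise results of one screening mode, plus the omnibus tests."""

    mode: str
    entries: dict
    omnibus: dict

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for desc, res in self.entries.items():
            rows.append(
                {
                    "mode": desc.mode,
                    "context": desc.context.value,
                    "sensor": desc.sensor,
                    "axis": desc.axis,
                    "group_a": desc.pair[0].value,
                    "group_b": desc.pair[1].value,
                    "t": res.statistic,
                    "df": res.df2,
                    "p_raw": res.p_value,
                    "p_adj": res.p_adjusted,
                    "label": res.label,
                }
            )
        return pd.DataFrame(rows)

    def significant_counts(self) -> pd.DataFrame:
        """Counts of Significant labels per context (location or surface)."""
        df = self.to_frame()
        return (
            df.assign(significant=df["label"].eq("Significant"))
            .groupby("context", sort=False)["significant"]
            .sum()
            .reset_index(name="n_significant")
        )


def significance_screen(
    summaries: pd.DataFrame,
    mode: str,
    alpha: float = ALPHA,
    family: Literal["per_anova", "global"] = "per_anova",
) -> SignificanceMatrix:
    """Run the full screening schedule for one mode.

    ``across_surfaces``: per (location, sensor output) a Welch ANOVA over
    the seven surfaces, then the 21 Bonferroni-corrected surface pairs —
    756 pairwise entries.  ``across_locations``: per (surface, output) over
    the six locations, then 15 pairs — 630 entries.
    """
    schedule = comparison_schedule(mode)
    if mode == "across_surfaces":
        group_enum, context_enum = SurfaceClass, BodyLocation
        group_col, context_col = "surface", "location"
    else:
        group_enum, context_enum = BodyLocation, SurfaceClass
        group_col, context_col = "location", "surface"
    n_pairs = len(list(itertools.combinations(list(group_enum), 2)))
    family_size = len(schedule) if family == "global" else n_pairs

    entries: dict = {}
    omnibus: dict = {}
    for context in context_enum:
        for sensor in SENSORS:
            for axis in AXES:
                cell = summaries[
                    (summaries[context_col] == context.value)
                    & (summaries["sensor"] == sensor)
                    & (summaries["axis"] == axis)
                ]
                groups = {}
                for g in group_enum:
                    vals = cell.loc[cell[group_col] == g.value, "value"].to_numpy()
                    if vals.size == 0:
                        raise ValueError(
                            f"no summaries for ({context.value}, {sensor}, "
                            f"{axis}, {g.value})"
                        )
                    groups[g] = vals
                omnibus[(context, sensor, axis)] = welch_anova(list(groups.values()))
                results = pairwise_posthoc(
                    groups,
                    family_size=family_size,
                    alpha=alpha,
                    descriptor_factory=lambda a, b, _c=context, _s=sensor, _x=axis: ComparisonDescriptor(
                        mode, (a, b), _s, _x, _c
                    ),
                )
                for res in results:
                    entries[res.comparison] = res

    expected = len(schedule)
    if len(entries) != expected:
        raise AssertionError(
            f"schedule mismatch: {len(entries)} entries vs {expected} expected"
        )
    return SignificanceMatrix(mode=mode, entries=entries, omnibus=omnibus)
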