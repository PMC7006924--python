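"""Behavioral and physiological statistics for coral stress assays.

Covers the choice-flume preference readout (fraction of time a larva
spends in the cue-bearing channel, side-swap controlled), dark-adapted
photosystem II maximum quantum yield (Fv/Fm), and the factorial tests
used on treatment x time response data: balanced two-way ANOVA with
Tukey's HSD, the Scheirer-Ray-Hare rank-based two-way ANOVA with
Mann-Whitney/Bonferroni follow-ups, two-sample Kolmogorov-Smirnov
comparisons, and the arcsine square-root transform for percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "FlumePeriod",
    "FlumeTrial",
    "PhenotypeObservation",
    "KSResult",
    "fvfm",
    "cue_time_proportion",
    "ks_two_sample",
    "two_way_anova",
    "tukey_hsd",
    "scheirer_ray_hare",
    "mann_whitney_bonferroni",
    "arcsine_sqrt",
    "phenotypes_to_frame",
]

OBS_PER_PERIOD = 24  # 2 min at 5-s intervals
SIDES = ("left", "right")


@dataclass(frozen=True)
class FlumePeriod:
    """One 2-min observation period with the cue on a fixed side."""

    cue_side: str
    observations: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.cue_side not in SIDES:
            raise ValueError(f"invalid cue side {self.cue_side!r}")
        if len(self.observations) != OBS_PER_PERIOD:
            raise ValueError(
                f"expected {OBS_PER_PERIOD} observations, got {len(self.observations)}"
            )
        bad = set(self.observations) - set(SIDES)
        if bad:
            raise ValueError(f"invalid side observations: {sorted(bad)}")


@dataclass(frozen=True)
class FlumeTrial:
    """Two periods per larva with the cue side swapped between them."""

    larva_id: str
    cue: str
    periods: tuple[FlumePeriod, FlumePeriod]

    def __post_init__(self) -> None:
        if len(self.periods) != 2:
            raise ValueError("a trial has exactly two periods")
        if self.periods[0].cue_side == self.periods[1].cue_side:
            raise ValueError(
                f"trial {self.larva_id!r}: cue side must swap between periods"
            )


@dataclass(frozen=True)
class PhenotypeObservation:
    """One treatment x time response (Fv/Fm, settlement or survival)."""

    unit_id: str
    life_stage: str
    treatment: str
    time_h: int
    response: float

    def __post_init__(self) -> None:
        if self.life_stage not in ("larva", "adult"):
            raise ValueError(f"invalid life stage {self.life_stage!r}")


class KSResult(NamedTuple):
    statistic: float
    pvalue: float
    pvalue_exact: float | None
    pvalue_asymptotic: float


def fvfm(F0: float, Fm: float) -> float:
    """Maximum quantum yield of PSII: (Fm - F0)/Fm, in [0, 1].

    F0 is minimal and Fm maximal fluorescence of dark-adapted tissue.
    """
    if Fm <= 0:
        raise ValueError("Fm must be positive")
    if F0 < 0 or F0 > Fm:
        raise ValueError("require 0 <= F0 <= Fm")
    return (Fm - F0) / Fm


def cue_time_proportion(trial: FlumeTrial) -> float:
    """Percent of the 48 pooled observations spent on the cue side.

    Pooling the two side-swapped periods cancels any fixed side bias: a
    larva that sticks to one physical side scores exactly 50%.
    """
    hits = sum(
        obs == period.cue_side
        for period in trial.periods
        for obs in period.observations
    )
    return 100.0 * hits / (2 * OBS_PER_PERIOD)


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 5
) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs. The
    p-value uses exact enumeration when min(n, m) <= ``exact_max_n``
    and the asymptotic formula otherwise; for small samples both are
    reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    small = min(len(x), len(y)) <= exact_max_n
    asymp = stats.ks_2samp(x, y, method="asymp")
    if small:
        exact = stats.ks_2samp(x, y, method="exact")
        return KSResult(float(exact.statistic), float(exact.pvalue),
                        float(exact.pvalue), float(asymp.pvalue))
    return KSResult(float(asymp.statistic), float(asymp.pvalue),
                    None, float(asymp.pvalue))


def _as_factorial_frame(
    data: Iterable[PhenotypeObservation] | pd.DataFrame,
    response: str = "response",
    factor_a: str = "treatment",
    factor_b: str = "time_h",
) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data.copy()
    else:
        df = phenotypes_to_frame(data)
    for col in (response, factor_a, factor_b):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    return df


def _balanced_cells(df, factor_a, factor_b, response, require_reps=2):
    levels_a = sorted(df[factor_a].unique())
    levels_b = sorted(df[factor_b].unique())
    cells = {}
    missing = []
    for a, b in product(levels_a, levels_b):
        vals = df.loc[(df[factor_a] == a) & (df[factor_b] == b), response].to_numpy(
            dtype=float
        )
        if len(vals) == 0:
            missing.append((a, b))
        cells[(a, b)] = vals
    if missing:
        raise ValueError(f"empty cells: {missing}")
    sizes = {len(v) for v in cells.values()}
    if len(sizes) != 1:
        raise ValueError("unbalanced design: unequal cell sizes")
    n = sizes.pop()
    if len(levels_a) > 1 and len(levels_b) > 1 and n < require_reps:
        raise ValueError(
            f"interaction requires >= {require_reps} replicates per cell"
        )
    return levels_a, levels_b, cells, n


def _factorial_ss(values: np.ndarray, levels_a, levels_b, cells, n):
    """Sums of squares for a balanced two-factor layout (Type I; with
    balance these equal Type II/III)."""
    grand = values.mean()
    la, lb = len(levels_a), len(levels_b)
    mean_a = {a: np.mean([cells[(a, b)].mean() for b in levels_b]) for a in levels_a}
    mean_b = {b: np.mean([cells[(a, b)].mean() for a in levels_a]) for b in levels_b}
    ss_a = n * lb * sum((mean_a[a] - grand) ** 2 for a in levels_a)
    ss_b = n * la * sum((mean_b[b] - grand) ** 2 for b in levels_b)
    ss_cells = n * sum(
        (cells[(a, b)].mean() - grand) ** 2 for a in levels_a for b in levels_b
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = float(((values - grand) ** 2).sum())
    ss_resid = ss_total - ss_cells
    return ss_a, ss_b, max(ss_ab, 0.0), max(ss_resid, 0.0), ss_total


def two_way_anova(
    data: Iterable[PhenotypeObservation] | pd.DataFrame,
    response: str = "response",
    factor_a: str = "treatment",
    factor_b: str = "time_h",
    transform=None,
) -> pd.DataFrame:
    """Balanced fixed-effects two-way ANOVA.

    Returns a table with rows for each factor (only factors with >= 2
    levels), their interaction, and the residual; columns ``ss``, ``df``,
    ``F`` and ``p``. A constant response yields F = 0 across effects
    (the 0/0 ratio is defined as no evidence of effect). ``transform``
    (e.g. :func:`arcsine_sqrt` composed with /100) is applied to the
    response first.
    """
    df = _as_factorial_frame(data, response, factor_a, factor_b)
    if transform is not None:
        df = df.assign(**{response: df[response].map(transform)})
    levels_a, levels_b, cells, n = _balanced_cells(df, factor_a, factor_b, response)
    values = df[response].to_numpy(dtype=float)
    N = len(values)
    ss_a, ss_b, ss_ab, ss_resid, _ = _factorial_ss(values, levels_a, levels_b, cells, n)
    la, lb = len(levels_a), len(levels_b)
    rows = []
    df_resid = N - la * lb
    ms_resid = ss_resid / df_resid if df_resid > 0 else 0.0

    def f_row(name, ss, dfree):
        if dfree == 0:
            return None
        ms = ss / dfree
        if ms_resid == 0:
            f = 0.0 if np.isclose(ss, 0) else math.inf
        else:
            f = ms / ms_resid
        p = 1.0 if f == 0 else float(stats.f.sf(f, dfree, df_resid))
        return {"effect": name, "ss": ss, "df": dfree, "F": f, "p": p}

    for name, ss, dfree in (
        (factor_a, ss_a, la - 1),
        (factor_b, ss_b, lb - 1),
        (f"{factor_a}:{factor_b}", ss_ab, (la - 1) * (lb - 1)),
    ):
        row = f_row(name, ss, dfree)
        if row:
            rows.append(row)
    rows.append(
        {"effect": "residual", "ss": ss_resid, "df": df_resid, "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows).set_index("effect")


def tukey_hsd(
    data: Iterable[PhenotypeObservation] | pd.DataFrame,
    factor: str = "treatment",
    response: str = "response",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey's HSD pairwise comparisons on one factor (studentized-range
    adjusted p-values, via statsmodels)."""
    df = _as_factorial_frame(data, response, factor, factor)
    if df[factor].nunique() < 2:
        raise ValueError("Tukey HSD requires at least 2 groups")
    res = pairwise_tukeyhsd(
        df[response].to_numpy(dtype=float), df[factor].astype(str).to_numpy(), alpha
    )
    table = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    return table.rename(columns={"p-adj": "p_adj"})


def scheirer_ray_hare(
    data: Iterable[PhenotypeObservation] | pd.DataFrame,
    response: str = "response",
    factor_a: str = "treatment",
    factor_b: str = "time_h",
) -> pd.DataFrame:
    """Scheirer-Ray-Hare rank-based two-way ANOVA.

    Responses are replaced by mid-ranks (ties averaged); the balanced
    two-way sums of squares are computed on ranks, and each effect's
    H = SS_effect / MS_total is referred to chi-square with the effect's
    df, where MS_total = SS_total/(N-1). Computing MS_total from the
    actual rank variance applies the tie correction. With a single-level
    second factor this reduces exactly to tie-corrected Kruskal-Wallis.
    """
    df = _as_factorial_frame(data, response, factor_a, factor_b)
    df = df.assign(_rank=stats.rankdata(df[response].to_numpy(dtype=float)))
    levels_a, levels_b, cells, n = _balanced_cells(df, factor_a, factor_b, "_rank")
    ranks = df["_rank"].to_numpy(dtype=float)
    N = len(ranks)
    ss_a, ss_b, ss_ab, _resid, ss_total = _factorial_ss(
        ranks, levels_a, levels_b, cells, n
    )
    if ss_total == 0:  # all responses tied: no evidence for any effect
        ms_total = np.nan
    else:
        ms_total = ss_total / (N - 1)
    la, lb = len(levels_a), len(levels_b)
    rows = []
    for name, ss, dfree in (
        (factor_a, ss_a, la - 1),
        (factor_b, ss_b, lb - 1),
        (f"{factor_a}:{factor_b}", ss_ab, (la - 1) * (lb - 1)),
    ):
        if dfree == 0:
            continue
        h = 0.0 if np.isnan(ms_total) else ss / ms_total
        rows.append(
            {
                "effect": name,
                "H": h,
                "df": dfree,
                "p": 1.0 if h == 0 else float(stats.chi2.sf(h, dfree)),
            }
        )
    return pd.DataFrame(rows).set_index("effect")


def mann_whitney_bonferroni(
    groups: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]] | None = None,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per pair with Bonferroni adjustment.

    Exact null distribution for groups up to ``exact_max_n`` (without
    ties), normal approximation with continuity correction otherwise.
    Adjusted p = min(1, raw p x number of comparisons).
    """
    if comparisons is None:
        keys = sorted(groups)
        comparisons = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1 :]]
    m = len(comparisons)
    rows = []
    for a, b in comparisons:
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"empty group in comparison ({a!r}, {b!r})")
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        if max(len(x), len(y)) <= exact_max_n and not has_ties:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        else:
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "U": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_adj": min(1.0, float(res.pvalue) * m),
            }
        )
    return pd.DataFrame(rows)


def arcsine_sqrt(p: float) -> float:
    """Variance-stabilizing arcsin(sqrt(p)) transform for proportions."""
    if not 0 <= p <= 1:
        raise ValueError(f"proportion {p} outside [0, 1]")
    return math.asin(math.sqrt(p))


def phenotypes_to_frame(obs: Iterable[PhenotypeObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit_id": o.unit_id,
                "life_stage": o.life_stage,
                "treatment": o.treatment,
                "time_h": o.time_h,
                "response": o.response,
            }
            for o in obs
        ]
    )
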