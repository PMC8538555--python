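"""Factorial comparison of CoV scores: balanced three-way ANOVA,
Tukey HSD contrasts, and the usual assumption checks.

The design is the 2 x 2 x 2 grid of the phantom experiments: motility
pattern (slower / faster CPPW) x media viscosity (LOVIS / HIVIS) x media
volume (150 / 200 mL), with equal replicates per cell.  The fixed-effects
sum-of-squares decomposition is computed directly from marginal means
(balanced, hence order-independent); F and Tukey p-values use scipy's F
and studentized-range distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FACTORS",
    "make_cov_table",
    "validate_cov_table",
    "three_way_anova",
    "tukey_hsd",
    "factor_mean_difference",
    "assumption_checks",
    "AssumptionChecks",
    "round_half_away",
]

FACTORS = ("pattern", "viscosity", "volume_ml")
RESPONSE = "cov_percent"


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (report-parity rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    # pre-quantize at 9 decimals so float representation noise (e.g.
    # 6.112499999999997 for the exact 6.1125) cannot flip a true half
    d = Decimal(repr(float(x))).quantize(Decimal(1).scaleb(-9), rounding=ROUND_HALF_UP)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def make_cov_table(rows) -> pd.DataFrame:
    """Build a CoV table from (pattern, viscosity, volume_ml, replicate, cov) rows."""
    df = pd.DataFrame(rows, columns=[*FACTORS, "replicate", RESPONSE])
    validate_cov_table(df, require_replicates=False)
    return df


def validate_cov_table(df: pd.DataFrame, require_replicates: bool = True) -> None:
    """Check the expected columns and (optionally) a balanced design."""
    missing = [c for c in (*FACTORS, RESPONSE) if c not in df.columns]
    if missing:
        raise ValueError(f"CoV table missing columns: {missing}")
    counts = df.groupby(list(FACTORS), observed=True).size()
    if require_replicates:
        if counts.nunique() != 1:
            raise ValueError(
                "unbalanced design: unequal cell counts "
                f"{dict(counts)}; a general linear model is out of scope"
            )
        if counts.iloc[0] < 2:
            raise ValueError("need at least 2 replicates per cell for ANOVA")
        for f in FACTORS:
            if df[f].nunique() != 2:
                raise ValueError(f"factor {f!r} must have exactly 2 levels")


@dataclass
class AnovaFit:
    """Effects table plus the residual quantities needed for post-hoc tests."""

    effects: pd.DataFrame
    ms_resid: float
    df_resid: int
    n_per_cell: int

    @property
    def total_ss(self) -> float:
        return float(self.effects["sum_sq"].sum())


def three_way_anova(df: pd.DataFrame) -> AnovaFit:
    """Balanced fixed-effects three-way ANOVA with all interactions.

    With two levels per factor every term is a single orthogonal +/-1
    contrast: coding each factor's levels as c = +/-1, the estimate of a
    term over factor subset S is L = mean(y * prod_{f in S} c_f) and its
    sum of squares is N * L^2 (1 df each).  Under balance this equals the
    marginal-mean decomposition and is order-independent.
    """
    validate_cov_table(df)
    y = df[RESPONSE].to_numpy(dtype=float)
    N = len(y)

    codes = {}
    for f in FACTORS:
        levels = sorted(pd.unique(df[f]), key=repr)
        codes[f] = np.where(df[f].to_numpy() == levels[0], 1.0, -1.0)

    rows = []
    for size in (1, 2, 3):
        for subset in combinations(FACTORS, size):
            c = np.prod([codes[f] for f in subset], axis=0)
            L = float(np.mean(y * c))
            rows.append({"effect": ":".join(subset), "sum_sq": N * L**2, "df": 1})

    cell_means = df.groupby(list(FACTORS), observed=True)[RESPONSE].transform("mean")
    ss_resid = float(((y - cell_means.to_numpy()) ** 2).sum())
    df_resid = N - df.groupby(list(FACTORS), observed=True).ngroups
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    for r in rows:
        ms = r["sum_sq"] / r["df"]
        if df_resid > 0 and ms_resid > 0:
            r["F"] = ms / ms_resid
            r["p"] = float(sps.f.sf(r["F"], r["df"], df_resid))
        elif df_resid > 0 and ms_resid == 0:
            r["F"] = np.inf if r["sum_sq"] > 0 else 0.0
            r["p"] = 0.0 if r["sum_sq"] > 0 else 1.0
        else:
            r["F"] = np.nan
            r["p"] = np.nan
    rows.append({"effect": "residual", "sum_sq": ss_resid, "df": df_resid,
                 "F": np.nan, "p": np.nan})
    effects = pd.DataFrame(rows)
    n_per_cell = N // df.groupby(list(FACTORS), observed=True).ngroups
    return AnovaFit(effects=effects, ms_resid=ms_resid, df_resid=df_resid,
                    n_per_cell=n_per_cell)


def factor_mean_difference(df: pd.DataFrame, factor: str,
                           level_a, level_b) -> float:
    """Signed difference of factor-level means, mean(A) - mean(B).

    Works on replicate tables and on cell-mean tables alike (each cell
    weighted equally under balance).
    """
    if factor not in df.columns:
        raise ValueError(f"factor {factor!r} not in table")
    ga = df.loc[df[factor] == level_a, RESPONSE]
    gb = df.loc[df[factor] == level_b, RESPONSE]
    if ga.empty or gb.empty:
        raise ValueError(f"levels {level_a!r}/{level_b!r} not found for {factor!r}")
    return float(ga.mean() - gb.mean())


def tukey_hsd(df: pd.DataFrame, factor: str,
              fit: AnovaFit | None = None) -> pd.DataFrame:
    """Tukey HSD pairwise contrasts for one factor of the balanced design.

    Returns one row per level pair with the signed mean difference
    (level_a - level_b), its absolute value, and the studentized-range
    adjusted p-value computed against the ANOVA residual mean square.
    """
    if factor not in FACTORS:
        raise ValueError(f"factor must be one of {FACTORS}, got {factor!r}")
    if fit is None:
        fit = three_way_anova(df)
    levels = list(pd.unique(df[factor]))
    k = len(levels)
    n_per_level = len(df) // k
    rows = []
    for a, b in combinations(levels, 2):
        diff = factor_mean_difference(df, factor, a, b)
        if fit.ms_resid > 0:
            se = np.sqrt(fit.ms_resid / n_per_level)
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, fit.df_resid))
        else:
            p = 0.0 if diff != 0 else 1.0
        rows.append({
            "factor": factor, "level_a": a, "level_b": b,
            "mean_difference": diff, "abs_difference": abs(diff),
            "p_adj": p,
        })
    return pd.DataFrame(rows)


@dataclass
class AssumptionChecks:
    shapiro_w: float | None
    shapiro_p: float | None
    levene_f: float
    levene_p: float


def assumption_checks(df: pd.DataFrame) -> AssumptionChecks:
    """Shapiro–Wilk normality of pooled cell residuals + Levene's test.

    Levene uses the classic mean-centred variant across the 8 cells.  The
    Shapiro–Wilk check is skipped (None) with a warning when any cell has
    fewer than 3 replicates.
    """
    validate_cov_table(df, require_replicates=False)
    groups = [g[RESPONSE].to_numpy(dtype=float)
              for _, g in df.groupby(list(FACTORS), observed=True)]
    resid = np.concatenate([g - g.mean() for g in groups])
    if min(len(g) for g in groups) < 3:
        warnings.warn("fewer than 3 replicates per cell; skipping Shapiro–Wilk")
        sw, sp_ = None, None
    else:
        sw, sp_ = sps.shapiro(resid)
        sw, sp_ = float(sw), float(sp_)
    if all(np.ptp(g) == 0 for g in groups):  # degenerate: no spread anywhere
        lf, lp = 0.0, 1.0
    else:
        lf, lp = sps.levene(*groups, center="mean")
    return AssumptionChecks(shapiro_w=sw, shapiro_p=sp_,
                            levene_f=float(lf), levene_p=float(lp))
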