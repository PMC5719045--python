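"""Frequency and association statistics for gait phase analyses.

Core pieces: the two-proportion z ("Binomial Proportion") test on
irregular-step counts with the UNPOOLED standard error

    z = (p2 - p1) / sqrt(p1 (1 - p1) / n1 + p2 (1 - p2) / n2),

two-sample Kolmogorov-Smirnov comparisons of cumulative phase
distributions, Spearman phase-vs-gait-parameter correlations with part
correlations controlling for speed (Bonferroni-adjusted), speed-category
contingency of irregular steps around the 90 cm/s walk-trot / gallop-bound
boundary, and ordinary-least-squares 95% prediction bands for control
gait-index-vs-speed relations.

The unpooled SE is deliberate: it reproduces the printed z statistics of
the reference comparisons (e.g. 3/84 vs 15/84 -> z = 3.08), whereas the
pooled-SE variant gives 2.99 there; the pooled variant remains available
behind a flag.  Standard group-level tests (paired/independent t, Levene,
repeated-measures and mixed ANOVA, Tukey HSD) are exposed as thin audited
delegations to scipy/pingouin/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProportionTestResult",
    "CorrelationResult",
    "PredictionBand",
    "two_proportion_z",
    "ks_compare",
    "phase_speed_association",
    "speed_category_counts",
    "prediction_band",
    "delegated_tests",
]


@dataclass(frozen=True)
class ProportionTestResult:
    x1: int
    n1: int
    x2: int
    n2: int
    p1: float
    p2: float
    z: float
    p_two_sided: float
    pooled: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    covariate: str
    rs: float
    r2_pct: float
    p: float
    p_bonferroni: float
    n: int
    part_r: float | None = None
    part_p: float | None = None
    adjustment: str = "bonferroni"


@dataclass
class PredictionBand:
    """OLS line with out-of-sample prediction intervals (statsmodels)."""

    slope: float
    intercept: float
    sigma2: float            # residual variance
    n: int
    alpha: float = 0.05
    _results: object = field(default=None, repr=False, compare=False)

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def interval(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper prediction bounds for new observations at x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        exog = np.column_stack([np.ones_like(x), x])
        frame = self._results.get_prediction(exog).summary_frame(
            alpha=self.alpha)
        return (frame["obs_ci_lower"].to_numpy(),
                frame["obs_ci_upper"].to_numpy())

    def coverage(self, x, y) -> float:
        """Fraction of (x, y) points inside the prediction band."""
        lo, hi = self.interval(x)
        y = np.asarray(y, dtype=float)
        return float(np.mean((y >= lo) & (y <= hi)))


def two_proportion_z(x1: int, n1: int, x2: int, n2: int,
                     pooled: bool = False) -> ProportionTestResult:
    """Two-proportion z test; unpooled SE by default, no continuity correction.

    z follows the sign of p2 - p1; two-sided p from the normal distribution.
    Degenerate inputs with zero standard error (both proportions 0, or both
    1) raise, since z is undefined there.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n, n >= 1")
    p1, p2 = x1 / n1, x2 / n2
    if pooled:
        p = (x1 + x2) / (n1 + n2)
        var = p * (1 - p) * (1 / n1 + 1 / n2)
    else:
        var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if var == 0:
        raise ValueError("standard error is zero; z undefined "
                         "(both proportions at a boundary)")
    z = (p2 - p1) / np.sqrt(var)
    p_two = 2 * stats.norm.sf(abs(z))
    return ProportionTestResult(x1=x1, n1=n1, x2=x2, n2=n2, p1=p1, p2=p2,
                                z=float(z), p_two_sided=float(p_two),
                                pooled=pooled)


def ks_compare(values1, values2) -> tuple[float, float]:
    """Two-sample KS test on cumulative distributions; returns (D, p)."""
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if len(v1) == 0 or len(v2) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(v1, v2)
    return float(res.statistic), float(res.pvalue)


_GAIT_COVARIATES = ("instantaneous_speed_cm_s", "step_frequency_hz",
                    "stride_length_cm", "stride_time_s", "stance_s", "swing_s")


def phase_speed_association(steps: pd.DataFrame,
                            phase_col: str = "phase_transformed",
                            covariates: tuple[str, ...] = _GAIT_COVARIATES,
                            speed_col: str = "instantaneous_speed_cm_s",
                            animal_averaged_part: bool = True) -> list[CorrelationResult]:
    """Spearman correlations of transformed phase against gait parameters.

    Step-level Spearman rs (with R^2% = 100*rs^2) per covariate, Bonferroni-
    adjusted across the covariate family; part correlations controlling for
    speed are computed on animal-averaged data (pingouin), skipped for the
    speed covariate itself.  Constant covariates are reported as absent
    (omitted from the result list).
    """
    import pingouin as pg

    present = [c for c in covariates if c in steps.columns]
    df = steps[steps[phase_col].notna()]
    k = len(present)
    results = []
    for cov_name in present:
        sub = df[[phase_col, cov_name]].dropna()
        if sub[cov_name].nunique() < 2 or len(sub) < 3:
            continue
        rs, p = stats.spearmanr(sub[phase_col], sub[cov_name])
        part_r = part_p = None
        if cov_name != speed_col and speed_col in df.columns:
            data = df[["animal_id", phase_col, cov_name, speed_col]].dropna()
            if animal_averaged_part:
                data = data.groupby("animal_id").mean().reset_index()
            if len(data) >= 4 and data[cov_name].nunique() > 1 \
                    and data[speed_col].nunique() > 1:
                pc = pg.partial_corr(data=data, x=cov_name, y=phase_col,
                                     x_covar=speed_col)
                pcol = "p_val" if "p_val" in pc.columns else "p-val"
                part_r = float(pc["r"].iloc[0])
                part_p = float(pc[pcol].iloc[0])
        results.append(CorrelationResult(
            covariate=cov_name, rs=float(rs), r2_pct=float(100 * rs**2),
            p=float(p), p_bonferroni=float(min(1.0, p * k)), n=len(sub),
            part_r=part_r, part_p=part_p))
    return results


def speed_category_counts(steps: pd.DataFrame, irregular_col: str = "irregular",
                          speed_col: str = "instantaneous_speed_cm_s",
                          cutoff: float = 90.0) -> pd.DataFrame:
    """Contingency of step irregularity by speed class (<=cutoff vs >cutoff).

    Also reports the fraction of irregular steps occurring at or below the
    cutoff (NaN when no irregular steps exist).
    """
    df = steps.dropna(subset=[speed_col, irregular_col]).copy()
    df["speed_class"] = np.where(df[speed_col] <= cutoff, "low", "high")
    table = (df.groupby(["speed_class", irregular_col]).size()
             .unstack(fill_value=0).reindex(["low", "high"], fill_value=0))
    n_irr = int(df[irregular_col].sum())
    frac_low = (float(df.loc[df[irregular_col], speed_col].le(cutoff).mean())
                if n_irr else np.nan)
    table.attrs["fraction_irregular_at_or_below_cutoff"] = frac_low
    table.attrs["cutoff_cm_s"] = cutoff
    return table


def prediction_band(x, y, alpha: float = 0.05) -> PredictionBand:
    """OLS fit of y on x with a standard 95% prediction interval."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant x; regression undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return PredictionBand(slope=float(res.params[1]),
                          intercept=float(res.params[0]),
                          sigma2=float(res.mse_resid), n=len(x),
                          alpha=alpha, _results=res)


def delegated_tests(kind: str, *args, **kwargs) -> dict:
    """Thin audited pass-throughs to standard group-level tests.

    kinds: "paired_t", "independent_t", "levene", "rm_anova", "mixed_anova",
    "tukey".  Results are returned with their inputs' shapes for audit; the
    factor structure (group x timepoint) is the caller's responsibility.
    """
    if kind == "paired_t":
        a, b = (np.asarray(v, float) for v in args)
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        res = stats.ttest_rel(a, b)
        return {"kind": kind, "t": float(res.statistic),
                "p": float(res.pvalue), "n": len(a)}
    if kind == "independent_t":
        a, b = (np.asarray(v, float) for v in args)
        res = stats.ttest_ind(a, b, equal_var=kwargs.get("equal_var", True))
        return {"kind": kind, "t": float(res.statistic),
                "p": float(res.pvalue), "n1": len(a), "n2": len(b)}
    if kind == "levene":
        res = stats.levene(*[np.asarray(v, float) for v in args],
                           center=kwargs.get("center", "mean"))
        return {"kind": kind, "W": float(res.statistic),
                "p": float(res.pvalue), "k": len(args)}
    if kind in ("rm_anova", "mixed_anova"):
        import pingouin as pg
        data = args[0]
        fn = pg.rm_anova if kind == "rm_anova" else pg.mixed_anova
        table = fn(data=data, **kwargs)
        return {"kind": kind, "table": table}
    if kind == "tukey":
        import pingouin as pg
        table = pg.pairwise_tukey(data=args[0], **kwargs)
        return {"kind": kind, "table": table}
    raise ValueError(f"unknown test kind {kind!r}")
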