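"""Meta-regression procedures over the clustered study table.

Implements the inference pipeline around the random-intercept logistic model:
the null model (intercept + class-imbalance correction only), a univariable
scan adding one study factor at a time, backward elimination by AIC with the
imbalance covariate forced into every model, an explained-variation
decomposition of the random-intercept variance, leave-one-study-out
(jackknife) stability of the selected factor set, and descriptive
cross-tabulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import glmm_core
from .glmm_core import GlmmFit, TestResult, lr_test, wald_test
from .study_table import (
    CATEGORICAL_LEVELS,
    STUDY_FACTORS,
    FactorSet,
    StudyRecord,
    encode_design,
    outcomes_array,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EliminationStep",
    "EliminationTrace",
    "VarianceDecomposition",
    "JackknifeResult",
    "fit_factor_model",
    "fit_null_model",
    "univariable_scan",
    "backward_eliminate",
    "explained_variation",
    "jackknife_stability",
    "crosstab_summary",
]

_AIC_TIE_TOL = 1e-6


@dataclass
class EliminationStep:
    factors: FactorSet                 # factor set *before* this step's deletion
    current_aic: float
    candidates: pd.DataFrame           # columns: factor, df, aic, p_value
    dropped: str | None


@dataclass
class EliminationTrace:
    steps: list[EliminationStep]
    final_set: FactorSet
    final_fit: GlmmFit

    def to_frame(self) -> pd.DataFrame:
        """Long-format trace: one row per (step, candidate factor)."""
        frames = []
        for i, step in enumerate(self.steps, start=1):
            df = step.candidates.copy()
            df.insert(0, "step", i)
            df["current_aic"] = step.current_aic
            df["dropped"] = df["factor"] == step.dropped
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass
class VarianceDecomposition:
    sigma2_null: float
    sigma2_full: float
    sigma2_minus: dict[str, float]
    total_explained: float
    relative: dict[str, float]
    denominator_mode: str

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": "sigma2_null", "value": self.sigma2_null},
            {"component": "sigma2_full", "value": self.sigma2_full},
            {"component": "total_explained", "value": self.total_explained},
        ]
        for k in self.sigma2_minus:
            rows.append({"component": f"sigma2_minus[{k}]", "value": self.sigma2_minus[k]})
        for k in self.relative:
            rows.append({"component": f"relative[{k}]", "value": self.relative[k]})
        return pd.DataFrame(rows)


@dataclass
class JackknifeResult:
    per_leaveout: dict[str, frozenset[str] | None]  # None marks a failed run
    modal_set: frozenset[str]
    agreement: float
    reference_set: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, fs in self.per_leaveout.items():
            rows.append({
                "left_out_study": sid,
                "final_factors": "|".join(sorted(fs)) if fs is not None else "FAILED",
                "matches_full_data": (fs == self.reference_set) if fs is not None else False,
            })
        return pd.DataFrame(rows)


def _factor_df(records: Sequence[StudyRecord], factor: str) -> int:
    """Model degrees of freedom a factor contributes (levels-1 or 1)."""
    if factor in CATEGORICAL_LEVELS:
        observed = {getattr(r, factor) for r in records}
        return max(len(observed) - 1, 0)
    return 1


def fit_factor_model(
    records: Sequence[StudyRecord],
    factors: FactorSet,
    include_forced: bool = True,
    **fit_kwargs,
) -> GlmmFit:
    """Fit the random-intercept model with the given factor set (+ forced covariate)."""
    design = encode_design(records, factors, include_forced=include_forced,
                           **{k: fit_kwargs.pop(k) for k in ("reference_levels", "log10_numeric")
                              if k in fit_kwargs})
    return glmm_core.fit_glmm(design, outcomes_array(records), **fit_kwargs)


def fit_null_model(records: Sequence[StudyRecord], **fit_kwargs) -> GlmmFit:
    """Null model: random intercept with only the class-imbalance correction."""
    return fit_factor_model(records, FactorSet.empty(), **fit_kwargs)


def _factor_test(
    fit_with: GlmmFit, fit_without: GlmmFit, factor: str, method: str
) -> TestResult:
    if method == "wald":
        return wald_test(fit_with, fit_with.column_map[factor])
    return lr_test(fit_with, fit_without)


def univariable_scan(
    records: Sequence[StudyRecord],
    factors: Sequence[str] = STUDY_FACTORS,
    pvalue_method: str = "lrt",
    **fit_kwargs,
) -> pd.DataFrame:
    """One-factor-at-a-time scan against the null model.

    Each row reports the AIC of (null + factor) and the test of the factor's
    coefficients.  The forced covariate's own row is the null model itself,
    tested against the intercept-only random-intercept model.
    """
    se = fit_kwargs.pop("se_method", "hessian" if pvalue_method == "wald" else "none")
    null_fit = fit_factor_model(records, FactorSet.empty(), se_method=se, **fit_kwargs)
    intercept_only = fit_factor_model(
        records, FactorSet.empty(), include_forced=False, se_method="none", **fit_kwargs
    )
    forced = FactorSet.empty().forced
    rows = [{
        "factor": forced,
        "df": 1,
        "aic": null_fit.aic,
        "p_value": _factor_test(null_fit, intercept_only, forced, pvalue_method).p_value,
    }]
    for factor in factors:
        fit = fit_factor_model(
            records, FactorSet((factor,)), se_method=se, **fit_kwargs
        )
        test = _factor_test(fit, null_fit, factor, pvalue_method)
        rows.append({
            "factor": factor,
            "df": _factor_df(records, factor),
            "aic": fit.aic,
            "p_value": test.p_value,
        })
    return pd.DataFrame(rows)


def backward_eliminate(
    records: Sequence[StudyRecord],
    start: FactorSet | None = None,
    pvalue_method: str = "lrt",
    final_se: bool = True,
    **fit_kwargs,
) -> EliminationTrace:
    """AIC backward elimination with the forced covariate exempt.

    At each step every removable factor is refitted out of the model; the
    factor whose deletion gives the lowest AIC is dropped if that AIC beats
    the current model's, otherwise elimination stops.  Ties (within 1e-6)
    break toward the smaller-df factor, then input order.
    """
    current = start if start is not None else FactorSet.full()
    se = fit_kwargs.pop("se_method", "hessian" if pvalue_method == "wald" else "none")
    steps: list[EliminationStep] = []
    current_fit = fit_factor_model(records, current, se_method=se, **fit_kwargs)
    while current.included_factors:
        cand_rows = []
        for factor in current.included_factors:
            try:
                reduced_fit = fit_factor_model(
                    records, current.without(factor), se_method="none", **fit_kwargs
                )
            except Exception as exc:  # candidate excluded, step continues
                logger.warning("deletion fit for %r failed: %s", factor, exc)
                cand_rows.append({
                    "factor": factor, "df": _factor_df(records, factor),
                    "aic": np.nan, "p_value": np.nan,
                })
                continue
            test = _factor_test(current_fit, reduced_fit, factor, pvalue_method)
            cand_rows.append({
                "factor": factor,
                "df": _factor_df(records, factor),
                "aic": reduced_fit.aic,
                "p_value": test.p_value,
                "_fit": reduced_fit,
            })
        cand = pd.DataFrame(cand_rows)
        valid = cand.dropna(subset=["aic"])
        if valid.empty:
            steps.append(EliminationStep(current, current_fit.aic,
                                         cand.drop(columns="_fit", errors="ignore"), None))
            break
        best_aic = valid["aic"].min()
        tied = valid[valid["aic"] <= best_aic + _AIC_TIE_TOL]
        # tie-break: smaller df, then input order (stable sort preserves it)
        chosen = tied.sort_values("df", kind="stable").iloc[0]
        if chosen["aic"] < current_fit.aic:
            steps.append(EliminationStep(
                current, current_fit.aic,
                cand.drop(columns="_fit", errors="ignore"), str(chosen["factor"]),
            ))
            current = current.without(str(chosen["factor"]))
            current_fit = chosen["_fit"]
        else:
            steps.append(EliminationStep(
                current, current_fit.aic,
                cand.drop(columns="_fit", errors="ignore"), None,
            ))
            break
    if final_se and current_fit.cov_beta is None:
        # refit the final model once with standard errors for reporting
        current_fit = fit_factor_model(records, current, se_method="hessian", **fit_kwargs)
    return EliminationTrace(steps=steps, final_set=current, final_fit=current_fit)


def explained_variation(
    records: Sequence[StudyRecord],
    full_factors: FactorSet | None = None,
    denominator_mode: str = "null",
    **fit_kwargs,
) -> VarianceDecomposition:
    """Explained-variation decomposition of the random-intercept variance.

    On the log-odds scale: the total explained variation is
    (sigma2_null - sigma2_full) / sigma2_null, and factor k's relative
    contribution is (sigma2_{-k} - sigma2_full) / denominator, where
    sigma2_{-k} comes from the model with every factor but k.  The
    denominator is sigma2_null (default) or (sigma2_null - sigma2_full)
    ("explained" mode).
    """
    if denominator_mode not in ("null", "explained"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    full_factors = full_factors if full_factors is not None else FactorSet.full()
    kw = dict(fit_kwargs, se_method="none")
    null_fit = fit_factor_model(records, FactorSet.empty(), **kw)
    full_fit = fit_factor_model(records, full_factors, **kw)
    s2_null, s2_full = null_fit.sigma2, full_fit.sigma2
    if s2_null <= 0:
        raise ValueError("sigma2_null is zero: explained variation undefined")
    total = (s2_null - s2_full) / s2_null
    s2_minus: dict[str, float] = {}
    for factor in full_factors.included_factors:
        fit_mk = fit_factor_model(records, full_factors.without(factor), **kw)
        s2_minus[factor] = fit_mk.sigma2
    denom = s2_null if denominator_mode == "null" else (s2_null - s2_full)
    if denom == 0:
        raise ValueError("zero denominator in explained-variation decomposition")
    relative = {k: (v - s2_full) / denom for k, v in s2_minus.items()}
    return VarianceDecomposition(
        sigma2_null=s2_null,
        sigma2_full=s2_full,
        sigma2_minus=s2_minus,
        total_explained=total,
        relative=relative,
        denominator_mode=denominator_mode,
    )


def jackknife_stability(
    records: Sequence[StudyRecord],
    start: FactorSet | None = None,
    **fit_kwargs,
) -> JackknifeResult:
    """Leave-one-study-out replication of the backward-elimination selection.

    Each study (cluster) is removed in turn, elimination reruns from the full
    factor set, and agreement is the fraction of leave-out runs selecting
    exactly the full-data factor set.  Failed runs are excluded from the
    agreement denominator and marked in the per-study map.
    """
    studies = list(dict.fromkeys(r.study_id for r in records))
    if len(studies) < 3:
        raise ValueError("jackknife needs >= 3 studies")
    fit_kwargs.setdefault("final_se", False)
    reference = frozenset(
        backward_eliminate(records, start=start, **fit_kwargs).final_set.included_factors
    )
    per: dict[str, frozenset[str] | None] = {}
    for sid in studies:
        subset = [r for r in records if r.study_id != sid]
        try:
            trace = backward_eliminate(subset, start=start, **fit_kwargs)
            per[sid] = frozenset(trace.final_set.included_factors)
        except Exception as exc:
            logger.warning("jackknife run without study %r failed: %s", sid, exc)
            per[sid] = None
    ok = [fs for fs in per.values() if fs is not None]
    if not ok:
        raise RuntimeError("all jackknife runs failed")
    counts: dict[frozenset[str], int] = {}
    for fs in ok:
        counts[fs] = counts.get(fs, 0) + 1
    modal = max(counts, key=lambda fs: (counts[fs], -len(fs)))
    agreement = sum(fs == reference for fs in ok) / len(ok)
    return JackknifeResult(
        per_leaveout=per, modal_set=modal, agreement=agreement, reference_set=reference
    )


def crosstab_summary(
    records: Sequence[StudyRecord], row_factor: str, col_factor: str
) -> pd.DataFrame:
    """Cell counts and mean accuracies for two categorical factors.

    Returns a tidy frame with one row per (row level, column level) cell;
    counts are model rows, means are unweighted means of row accuracies
    rounded to 2 decimals.  Empty cells have count 0 and NaN mean.
    """
    for f in (row_factor, col_factor):
        if f not in CATEGORICAL_LEVELS:
            raise ValueError(f"{f!r} is not a categorical factor")
    rows = []
    for rl in CATEGORICAL_LEVELS[row_factor]:
        for cl in CATEGORICAL_LEVELS[col_factor]:
            accs = [r.accuracy for r in records
                    if getattr(r, row_factor) == rl and getattr(r, col_factor) == cl]
            rows.append({
                row_factor: rl,
                col_factor: cl,
                "count": len(accs),
                "mean_accuracy": round(float(np.mean(accs)), 2) if accs else np.nan,
            })
    df = pd.DataFrame(rows)
    observed_r = {getattr(r, row_factor) for r in records}
    observed_c = {getattr(r, col_factor) for r in records}
    return df[df[row_factor].isin(observed_r) & df[col_factor].isin(observed_c)].reset_index(drop=True)
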