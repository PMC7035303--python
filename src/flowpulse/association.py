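"""Multivariable association analysis between arterial pulsatility and
small-vessel-disease outcomes.

Three outcomes are modeled with generalized linear models: WMH load
(%ICV) with a gamma distribution and log link (right-skewed, positive),
and total brain volume (%ICV) and the aggregate cognitive Z-score with a
Gaussian distribution and identity link.  Every model adjusts for age,
sex (female = 1), mean arterial pressure, hypertension, and total
cerebral blood flow; one pulsatility term (ICA or M1; PI or FVP) is
entered at a time.  Extended variants additionally adjust for
antihypertensive drug classes (WMH, TBV) or for WMH + TBV (cognition),
and the basic models are re-run within the SVD subgroup for WMH and TBV
only.  Distal M3 pulsatility is excluded from multivariable modeling.

Fitting is iteratively reweighted least squares (via statsmodels) with
Wald 95% confidence intervals and Pearson-based dispersion; rows with any
missing model variable are dropped (complete-case).  Also provides
ICC(2,1) — intraclass correlation, two-way random effects, single rater,
absolute agreement — for interrater reliability of visual ratings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .errors import DomainError, SingularDesignError, ValidationError

__all__ = [
    "OUTCOMES",
    "PULSATILITY_TERMS",
    "BASE_COVARIATES",
    "ANTIHYPERTENSIVE_COLUMNS",
    "ModelSpec",
    "FitResult",
    "fit_glm",
    "run_model_battery",
    "icc_2_1",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("wmh_pct_icv", "tbv_pct_icv", "cognition")
PULSATILITY_TERMS = ("ICA_PI", "M1_PI", "ICA_FVP", "M1_FVP")
BASE_COVARIATES = ("age", "female", "map", "hypertension", "tcbf")
ANTIHYPERTENSIVE_COLUMNS = (
    "antihtn_beta_blocker",
    "antihtn_raas",
    "antihtn_ccb",
    "antihtn_diuretic",
)

_OUTCOME_COLUMNS = {
    "wmh_pct_icv": "wmh_pct_icv",
    "tbv_pct_icv": "tbv_pct_icv",
    "cognition": "aggregate_z",
}
_OUTCOME_FAMILY = {
    "wmh_pct_icv": "gamma_log",
    "tbv_pct_icv": "gaussian_identity",
    "cognition": "gaussian_identity",
}
_TERM_COLUMNS = {
    "ICA_PI": "ica_pi",
    "M1_PI": "m1_pi",
    "ICA_FVP": "ica_fvp",
    "M1_FVP": "m1_fvp",
}

_Z_975 = scipy.stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ModelSpec:
    """One GLM: outcome, family/link, covariates, pulsatility term, subgroup."""

    outcome: str
    pulsatility_term: Optional[str] = None
    extra_adjustments: frozenset = frozenset()
    subgroup: str = "all"
    base_covariates: Tuple[str, ...] = BASE_COVARIATES

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"outcome must be one of {OUTCOMES}")
        if self.pulsatility_term is not None:
            if self.pulsatility_term.upper().startswith("M3"):
                raise ValidationError(
                    "M3 pulsatility is excluded from multivariable analysis"
                )
            if self.pulsatility_term not in PULSATILITY_TERMS:
                raise ValidationError(
                    f"pulsatility_term must be one of {PULSATILITY_TERMS} or None"
                )
        object.__setattr__(self, "extra_adjustments", frozenset(self.extra_adjustments))
        unknown = self.extra_adjustments - {"antihypertensives", "wmh_tbv"}
        if unknown:
            raise ValidationError(f"unknown extra adjustments: {sorted(unknown)}")
        if "wmh_tbv" in self.extra_adjustments and self.outcome != "cognition":
            raise ValidationError("wmh_tbv adjustment applies to the cognition model")
        if self.subgroup not in ("all", "svd_only"):
            raise ValidationError("subgroup must be 'all' or 'svd_only'")
        if self.subgroup == "svd_only" and self.outcome == "cognition":
            raise ValidationError(
                "cognition is not modeled in the SVD subgroup (too few follow-ups)"
            )

    @property
    def family_link(self) -> str:
        return _OUTCOME_FAMILY[self.outcome]

    def design_columns(self) -> list:
        cols = list(self.base_covariates)
        if "antihypertensives" in self.extra_adjustments:
            cols += list(ANTIHYPERTENSIVE_COLUMNS)
        if "wmh_tbv" in self.extra_adjustments:
            cols += ["wmh_pct_icv", "tbv_pct_icv"]
        if self.pulsatility_term is not None:
            cols.append(_TERM_COLUMNS[self.pulsatility_term])
        return cols


@dataclass(frozen=True)
class FitResult:
    """Fitted GLM: named coefficients with Wald 95% CIs and p-values."""

    spec: ModelSpec
    names: Tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    dispersion: float
    n_used: int
    converged: bool
    iterations: int

    def _index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no coefficient named {name!r}; have {self.names}") from None

    def coef(self, name: str) -> float:
        return float(self.coefficients[self._index(name)])

    def ci(self, name: str) -> Tuple[float, float]:
        i = self._index(name)
        return float(self.ci_lower[i]), float(self.ci_upper[i])

    def p_value(self, name: str) -> float:
        return float(self.p_values[self._index(name)])

    @property
    def pulsatility_column(self) -> Optional[str]:
        term = self.spec.pulsatility_term
        return _TERM_COLUMNS[term] if term else None

    def tidy(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.names,
                "estimate": self.coefficients,
                "se": self.standard_errors,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p_value": self.p_values,
            }
        )


def _check_rank(X: np.ndarray, names: Sequence[str]):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR: the trailing pivots index the dependent columns
        _, _, pivot = scipy.linalg.qr(X, pivoting=True, mode="economic")
        collinear = [names[i] for i in sorted(pivot[rank:])]
        raise SingularDesignError(collinear)


def fit_glm(spec: ModelSpec, cohort: pd.DataFrame) -> FitResult:
    """Fit one GLM by IRLS with complete-case deletion.

    Gamma/log models require a strictly positive outcome.  Rank-deficient
    designs raise :class:`SingularDesignError` naming the collinear
    columns; non-convergence within 100 iterations is returned as a
    flagged result, not an exception.
    """
    outcome_col = _OUTCOME_COLUMNS[spec.outcome]
    design_cols = spec.design_columns()
    needed = [outcome_col] + design_cols + (["svd"] if spec.subgroup == "svd_only" else [])
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise ValidationError(f"cohort table lacks columns: {missing_cols}")

    data = cohort[needed].copy()
    if spec.subgroup == "svd_only":
        data = data[data["svd"].astype(bool)]
        data = data.drop(columns="svd")
    data = data.dropna()
    n_used = len(data)
    if n_used < 10:
        raise ValidationError(
            f"only {n_used} complete cases; at least 10 required"
        )

    y = data[outcome_col].to_numpy(float)
    if spec.family_link == "gamma_log" and np.any(y <= 0):
        raise ValidationError("gamma/log outcome must be strictly positive")

    X = np.column_stack([np.ones(n_used)] + [data[c].to_numpy(float) for c in design_cols])
    names = ("intercept",) + tuple(design_cols)
    _check_rank(X, names)

    family = (
        sm.families.Gamma(link=sm.families.links.Log())
        if spec.family_link == "gamma_log"
        else sm.families.Gaussian()
    )
    model = sm.GLM(y, X, family=family)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-convergence is reported via the flag
        res = model.fit(maxiter=100, tol=1e-8, scale="X2")

    params = np.asarray(res.params)
    se = np.asarray(res.bse)
    return FitResult(
        spec=spec,
        names=names,
        coefficients=params,
        standard_errors=se,
        ci_lower=params - _Z_975 * se,
        ci_upper=params + _Z_975 * se,
        p_values=np.asarray(res.pvalues),
        dispersion=float(res.scale),
        n_used=n_used,
        converged=bool(getattr(res, "converged", True)),
        iterations=int(len(res.fit_history.get("deviance", [0])) - 1),
    )


def run_model_battery(
    cohort: pd.DataFrame,
    terms: Sequence[str] = PULSATILITY_TERMS,
    include_extended: bool = True,
    include_subgroup: bool = True,
) -> pd.DataFrame:
    """Run the full model battery and return a tidy results table.

    Basic models: each pulsatility term × each of the three outcomes.
    Extended: WMH and TBV additionally adjusted for antihypertensive
    classes; cognition additionally adjusted for WMH + TBV.  Subgroup:
    basic WMH and TBV models restricted to SVD-positive subjects
    (cognition excluded there).  Variants that cannot be fit (fewer than
    10 complete cases, or no subgroup members) are skipped with a logged
    warning.  One row per fitted model, reporting the pulsatility term's
    coefficient.
    """
    specs = []
    for term in terms:
        for outcome in OUTCOMES:
            specs.append(("basic", ModelSpec(outcome, term)))
        if include_extended:
            specs.append(
                ("extended", ModelSpec("wmh_pct_icv", term, {"antihypertensives"}))
            )
            specs.append(
                ("extended", ModelSpec("tbv_pct_icv", term, {"antihypertensives"}))
            )
            specs.append(("extended", ModelSpec("cognition", term, {"wmh_tbv"})))
        if include_subgroup:
            specs.append(("svd_subgroup", ModelSpec("wmh_pct_icv", term, subgroup="svd_only")))
            specs.append(("svd_subgroup", ModelSpec("tbv_pct_icv", term, subgroup="svd_only")))

    rows = []
    for variant, spec in specs:
        try:
            fit = fit_glm(spec, cohort)
        except (ValidationError, SingularDesignError) as exc:
            logger.warning(
                "skipping %s %s ~ %s: %s", variant, spec.outcome, spec.pulsatility_term, exc
            )
            continue
        col = fit.pulsatility_column
        lo, hi = fit.ci(col)
        rows.append(
            {
                "outcome": spec.outcome,
                "pulsatility_term": spec.pulsatility_term,
                "variant": variant,
                "family_link": spec.family_link,
                "estimate": fit.coef(col),
                "ci_lower": lo,
                "ci_upper": hi,
                "p_value": fit.p_value(col),
                "dispersion": fit.dispersion,
                "n": fit.n_used,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def icc_2_1(ratings_a: Sequence[float], ratings_b: Sequence[float]) -> float:
    """ICC(2,1): two-way random effects, single rater, absolute agreement.

    From the two-way ANOVA mean squares with k = 2 raters and n subjects:
    ``(MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE))`` where MSR, MSC
    and MSE are the between-subject, between-rater and residual mean
    squares.
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("ratings must be 1-D vectors of equal length")
    n = a.size
    if n < 3:
        raise ValidationError("at least 3 rated subjects are required")
    x = np.column_stack([a, b])
    k = 2
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    sst = ssr + ssc + sse
    if sst <= 0:
        raise DomainError("ICC undefined: ratings have zero total variance")
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    return float((msr - mse) / denom)
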