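"""Synthetic stroke/TIA cohort with the covariate and outcome structure
assumed by the association models.

The generator emulates, at the level of numbers rather than images, a
cohort of elderly patients with acute ischemic stroke or TIA:

* covariates — age, sex, blood pressures (MAP = DBP + pulse pressure / 3),
  hypertension, antihypertensive classes, diagnosis, NIHSS, total cerebral
  blood flow;
* per-segment arterial pulsatility (ICA, M1, M3; left/right), correlated
  with age, with configurable per-side missingness and the contralateral
  fallback applied downstream;
* outcomes with known generative truth — white-matter-hyperintensity load
  (% of intracranial volume) drawn from a gamma distribution whose log
  mean is linear in the covariates and one pulsatility term; total brain
  volume (%ICV) and an aggregate cognitive Z-score drawn Gaussian with
  identity-link linear predictors;
* derived clinical quantities — ICV/TBV arithmetic, Fazekas grades tied
  to WMH load, the small-vessel-disease composite, and the cognitive
  battery scores that reproduce the target aggregate exactly under the
  shipped battery norms.

Every stochastic step is driven by a single seed; the generative
coefficients are returned as a "truth" mapping for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import MissingDataError, ValidationError
from .waveform import PulsatilityMetrics

__all__ = [
    "COGNITIVE_TESTS",
    "TIMED_TESTS",
    "BATTERY_NORMS",
    "CohortParams",
    "SubjectRecord",
    "generate_cohort_frame",
    "generate_cohort",
    "compute_volume_fractions",
    "classify_svd",
    "svd_composite",
    "aggregate_cognition",
    "simulate_rater_pair",
]

#: the eight neuropsychological subtests of the battery
COGNITIVE_TESTS = (
    "two_choice_reaction",
    "stroop_congruent",
    "stroop_incongruent",
    "ten_word_list",
    "delayed_recall",
    "delayed_recognition",
    "trail_making_a",
    "trail_making_b",
)

#: timed subtests: lower is better, so their Z-scores flip sign
TIMED_TESTS = frozenset(
    {
        "two_choice_reaction",
        "stroop_congruent",
        "stroop_incongruent",
        "trail_making_a",
        "trail_making_b",
    }
)

#: default battery norms: test -> (mean, SD, orientation)
BATTERY_NORMS: Dict[str, Tuple[float, float, int]] = {
    "two_choice_reaction": (430.0, 60.0, -1),  # ms
    "stroop_congruent": (680.0, 110.0, -1),  # ms
    "stroop_incongruent": (1120.0, 230.0, -1),  # ms
    "ten_word_list": (7.0, 1.5, +1),  # words
    "delayed_recall": (6.0, 2.0, +1),  # words
    "delayed_recognition": (9.0, 1.2, +1),  # words
    "trail_making_a": (40.0, 12.0, -1),  # s
    "trail_making_b": (90.0, 35.0, -1),  # s
}

#: generative pulsatility distributions (R-R standardized values):
#: segment -> (PI mean, PI SD, FVP mean [ml], FVP SD)
PULSATILITY_DISTRIBUTIONS = {
    "ica": (1.26, 0.37, 0.47, 0.15),
    "m1": (1.28, 0.37, 0.28, 0.11),
    "m3": (1.40, 0.51, 0.06, 0.02),
}


def _default_wmh_coefs():
    # log-link linear predictor for WMH %ICV; tCBF in ml/s
    return {
        "intercept": -2.5,
        "age": 0.06,
        "female": 0.0,
        "map": 0.0,
        "hypertension": 0.83,
        "tcbf": -0.36,
        "pulsatility": 1.67,
    }


def _default_tbv_coefs():
    return {
        "intercept": 67.0,
        "age": -0.34,
        "female": 4.17,
        "map": 0.09,
        "hypertension": 0.0,
        "tcbf": 1.2,
        "pulsatility": 0.0,
    }


def _default_cog_coefs():
    return {
        "intercept": 40.7,
        "age": -0.33,
        "female": 3.84,
        "map": -0.13,
        "hypertension": 0.0,
        "tcbf": 0.0,
        "pulsatility": -4.4,
    }


@dataclass
class CohortParams:
    """Generative parameters of the synthetic cohort.

    Covariate distributions default to the demographics of an elderly
    stroke/TIA population (mean age ~70, ~30% women, high hypertension
    prevalence); outcome coefficient defaults carry effect magnitudes of
    the size reported for such cohorts (e.g. a log-WMH slope of 1.67 per
    ml of ICA flow-volume pulsatility).
    """

    n_subjects: int = 500
    seed: int = 0

    # covariates
    age_mean: float = 70.2
    age_sd: float = 8.9
    age_min: float = 50.0
    age_max: float = 85.0
    female_prevalence: float = 0.30
    dbp_mean: float = 78.4
    dbp_sd: float = 10.2
    pulse_pressure_mean: float = 69.0
    pulse_pressure_sd: float = 15.0
    hypertension_prevalence: float = 0.865
    antihypertensive_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "beta_blocker": 0.39,
            "raas": 0.64,
            "ccb": 0.36,
            "diuretic": 0.33,
        }
    )
    stroke_prevalence: float = 0.719
    nihss_rate: float = 1.0
    tcbf_mean: float = 10.8  # ml/s
    tcbf_sd: float = 1.7
    rr_mean: float = 0.9  # s
    rr_sd: float = 0.1

    # pulsatility structure
    age_pulsatility_corr: float = 0.4
    side_sd_fraction: float = 0.15
    missingness_rate: float = 0.05  # per side, per paired artery

    # outcome models
    wmh_coefs: Mapping[str, float] = field(default_factory=_default_wmh_coefs)
    wmh_pulsatility_term: str = "ica_fvp"
    gamma_shape: float = 1.2
    wmh_floor: float = 1e-4  # %ICV, keeps the gamma support positive
    tbv_coefs: Mapping[str, float] = field(default_factory=_default_tbv_coefs)
    tbv_pulsatility_term: str = "ica_fvp"
    tbv_sd: float = 5.0
    cog_coefs: Mapping[str, float] = field(default_factory=_default_cog_coefs)
    cog_pulsatility_term: str = "m1_pi"
    cog_sd: float = 4.0
    followup_rate: float = 0.539

    # volumes
    icv_mean: float = 1450.0  # ml
    icv_sd: float = 130.0

    # Fazekas latent model (tied to log WMH load)
    fazekas_intercept_pv: float = 1.75
    fazekas_intercept_dwm: float = 1.55
    fazekas_slope: float = 0.55
    fazekas_noise_sd: float = 0.5

    # other SVD features
    microbleed_rate: float = 0.5
    lacune_prevalence: float = 0.15
    infarct_prevalence: float = 0.17

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be at least 1")
        if self.gamma_shape <= 0 or self.tbv_sd <= 0 or self.cog_sd <= 0:
            raise ValidationError("dispersions and residual SDs must be positive")
        for name, rate in (
            ("missingness_rate", self.missingness_rate),
            ("followup_rate", self.followup_rate),
            ("female_prevalence", self.female_prevalence),
            ("hypertension_prevalence", self.hypertension_prevalence),
        ):
            if not 0 <= rate <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        for coefs in (self.wmh_coefs, self.tbv_coefs, self.cog_coefs):
            missing = set(_default_wmh_coefs()) - set(coefs)
            if missing:
                raise ValidationError(f"coefficient vector missing keys: {sorted(missing)}")
            if not all(np.isfinite(v) for v in coefs.values()):
                raise ValidationError("coefficients must be finite")

    def truth(self) -> dict:
        """Generative coefficients, for recovery tests and sidecar files."""
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "wmh": {"coefs": dict(self.wmh_coefs), "term": self.wmh_pulsatility_term,
                    "gamma_shape": self.gamma_shape},
            "tbv": {"coefs": dict(self.tbv_coefs), "term": self.tbv_pulsatility_term,
                    "sd": self.tbv_sd},
            "cognition": {"coefs": dict(self.cog_coefs), "term": self.cog_pulsatility_term,
                          "sd": self.cog_sd},
        }


@dataclass
class SubjectRecord:
    """One subject: covariates, pulsatility, volumes, SVD features, outcomes."""

    subject_id: str
    age: float
    sex: str  # "F" / "M"
    sbp: float
    dbp: float
    map: float
    hypertension: bool
    antihypertensive_classes: frozenset
    diagnosis: str  # "stroke" / "TIA"
    nihss: int
    tcbf: float  # ml/s
    metrics: Dict[str, Dict[str, Optional[PulsatilityMetrics]]]
    gm: float
    wm: float
    csf: float
    icv: float
    tbv_pct_icv: float
    wmh_pct_icv: float
    fazekas_pv: int
    fazekas_dwm: int
    fazekas_total: int
    microbleed_count: int
    lacune: bool
    recent_subcortical_infarct: bool
    svd: bool
    test_scores: Optional[Dict[str, float]]
    aggregate_z: Optional[float]


def compute_volume_fractions(gm: float, wm: float, csf: float, wmh: float):
    """ICV and the %ICV expressions of brain and lesion volume.

    ICV = GM + WM + CSF; TBV = GM + WM; both TBV and the WMH volume are
    expressed as percent of ICV.  Returns ``(icv, tbv_pct_icv,
    wmh_pct_icv)`` in (ml, %, %).
    """
    if min(gm, wm, csf, wmh) < 0:
        raise ValidationError("tissue volumes must be non-negative")
    icv = gm + wm + csf
    if icv <= 0:
        raise ValidationError("intracranial volume must be positive")
    return icv, 100.0 * (gm + wm) / icv, 100.0 * wmh / icv


def svd_composite(
    fazekas_total: int,
    recent_subcortical_infarct: bool,
    lacune: bool,
    microbleed_count: int,
) -> bool:
    """Small-vessel-disease composite.

    Positive iff total Fazekas score >= 4, OR a small recent subcortical
    infarct, OR a lacune, OR strictly more than 2 cerebral microbleeds.
    """
    for name, value in (
        ("fazekas_total", fazekas_total),
        ("recent_subcortical_infarct", recent_subcortical_infarct),
        ("lacune", lacune),
        ("microbleed_count", microbleed_count),
    ):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise MissingDataError(f"SVD feature {name} is missing")
    return bool(
        fazekas_total >= 4
        or recent_subcortical_infarct
        or lacune
        or microbleed_count > 2
    )


def classify_svd(record: SubjectRecord) -> bool:
    return svd_composite(
        record.fazekas_total,
        record.recent_subcortical_infarct,
        record.lacune,
        record.microbleed_count,
    )


def aggregate_cognition(
    test_scores: Mapping[str, float],
    norms: Mapping[str, Tuple[float, float, int]] = BATTERY_NORMS,
    missing_policy: str = "missing",
) -> float:
    """Aggregate cognitive score: sum of oriented per-test Z-scores.

    Each test score is converted to ``orientation * (score - mean) / SD``
    with orientation −1 for timed tests (lower is better) and +1
    otherwise, then summed over the battery.  A missing subtest yields a
    missing (NaN) aggregate by default; ``missing_policy="available"``
    sums over the available tests instead.
    """
    if missing_policy not in ("missing", "available"):
        raise ValidationError("missing_policy must be 'missing' or 'available'")
    missing = [t for t in COGNITIVE_TESTS if t not in norms]
    if missing:
        raise ValidationError(f"norms must cover all subtests; missing {missing}")
    total = 0.0
    for test in COGNITIVE_TESTS:
        mean, sd, orientation = norms[test]
        if sd <= 0:
            raise ValidationError(f"norm SD for {test} must be positive")
        score = test_scores.get(test)
        if score is None or (isinstance(score, float) and np.isnan(score)):
            if missing_policy == "missing":
                return float("nan")
            continue
        total += orientation * (score - mean) / sd
    return float(total)


def simulate_rater_pair(
    true_scores: Sequence[float],
    rater_sd: float,
    rater_bias: Tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    scale_max: int = 6,
):
    """Two raters' integer gradings of the same latent severity scores.

    Each rating is ``clamp(round(latent + bias_r + noise), 0, scale_max)``
    with independent Gaussian noise per rater; a fixture for interrater
    agreement (ICC) analyses.
    """
    if rater_sd < 0:
        raise ValidationError("rater_sd must be non-negative")
    latent = np.asarray(true_scores, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for bias in rater_bias:
        noisy = latent + bias + rng.normal(0.0, rater_sd, size=latent.shape)
        out.append(np.clip(np.round(noisy), 0, scale_max).astype(int))
    return tuple(out)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_COVARIATE_KEYS = ("age", "female", "map", "hypertension", "tcbf")


def _linear_predictor(coefs, frame, pulsatility):
    lp = np.full(len(frame), float(coefs["intercept"]))
    for key in _COVARIATE_KEYS:
        lp += coefs[key] * frame[key].to_numpy(float)
    lp += coefs["pulsatility"] * pulsatility
    return lp


def generate_cohort_frame(params: CohortParams):
    """Generate the cohort as a tidy table.

    Returns ``(frame, truth)``: one row per subject with covariates,
    per-side and bilateral (contralateral-fallback) standardized
    pulsatility metrics, volumes, SVD features and outcomes; and the
    generative-truth mapping.  Deterministic given ``params.seed``.
    """
    n = params.n_subjects
    rng = np.random.default_rng(params.seed)

    # covariates ------------------------------------------------------------
    age = np.clip(
        rng.normal(params.age_mean, params.age_sd, n), params.age_min, params.age_max
    )
    z_age = (age - params.age_mean) / params.age_sd
    female = rng.random(n) < params.female_prevalence
    dbp = rng.normal(params.dbp_mean, params.dbp_sd, n)
    pp = np.clip(
        rng.normal(params.pulse_pressure_mean, params.pulse_pressure_sd, n), 15.0, None
    )
    sbp = dbp + pp
    map_ = dbp + pp / 3.0  # standard clinical MAP estimate
    hypertension = rng.random(n) < params.hypertension_prevalence
    antihtn = {
        f"antihtn_{cls}": rng.random(n) < prev
        for cls, prev in params.antihypertensive_prevalence.items()
    }
    stroke = rng.random(n) < params.stroke_prevalence
    nihss = rng.poisson(params.nihss_rate, n)
    tcbf = np.clip(rng.normal(params.tcbf_mean, params.tcbf_sd, n), 4.0, None)
    rr = np.clip(rng.normal(params.rr_mean, params.rr_sd, n), 0.5, 1.4)

    # pulsatility (standardized values are the generative quantities) -------
    rho = params.age_pulsatility_corr
    cols = {}
    true_bilateral = {}
    for seg, (pi_m, pi_s, fvp_m, fvp_s) in PULSATILITY_DISTRIBUTIONS.items():
        for metric, m, s in (("pi", pi_m, pi_s), ("fvp", fvp_m, fvp_s)):
            z = rho * z_age + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            subject_value = m + s * z
            floor = 0.15 if metric == "pi" else 0.005
            sides = {}
            for side in ("left", "right"):
                val = subject_value + params.side_sd_fraction * s * rng.standard_normal(n)
                sides[side] = np.clip(val, floor, None)
            name = f"{seg}_{metric}"
            true_bilateral[name] = (sides["left"] + sides["right"]) / 2.0
            miss_l = rng.random(n) < params.missingness_rate
            miss_r = rng.random(n) < params.missingness_rate
            left = np.where(miss_l, np.nan, sides["left"])
            right = np.where(miss_r, np.nan, sides["right"])
            cols[f"{name}_left"] = left
            cols[f"{name}_right"] = right
            # contralateral fallback: mean of available sides, NaN if neither
            both = np.column_stack([left, right])
            any_side = ~np.all(np.isnan(both), axis=1)
            fallback = np.full(n, np.nan)
            fallback[any_side] = np.nanmean(both[any_side], axis=1)
            cols[name] = fallback

    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "age": age,
            "female": female.astype(int),
            "sex": np.where(female, "F", "M"),
            "sbp": sbp,
            "dbp": dbp,
            "map": map_,
            "hypertension": hypertension.astype(int),
            **{k: v.astype(int) for k, v in antihtn.items()},
            "diagnosis": np.where(stroke, "stroke", "TIA"),
            "nihss": nihss,
            "tcbf": tcbf,
            "rr_interval": rr,
            **cols,
        }
    )

    # outcomes from the pre-missingness bilateral values --------------------
    lp_wmh = _linear_predictor(
        params.wmh_coefs, frame, true_bilateral[params.wmh_pulsatility_term]
    )
    mu_wmh = np.exp(lp_wmh)
    shape = params.gamma_shape
    wmh_pct = np.maximum(rng.gamma(shape, mu_wmh / shape), params.wmh_floor)

    lp_tbv = _linear_predictor(
        params.tbv_coefs, frame, true_bilateral[params.tbv_pulsatility_term]
    )
    tbv_pct = np.clip(lp_tbv + rng.normal(0.0, params.tbv_sd, n), 45.0, 90.0)

    lp_cog = _linear_predictor(
        params.cog_coefs, frame, true_bilateral[params.cog_pulsatility_term]
    )
    aggregate = lp_cog + rng.normal(0.0, params.cog_sd, n)

    # volumes consistent with the %ICV identities ---------------------------
    icv = np.clip(rng.normal(params.icv_mean, params.icv_sd, n), 1000.0, 1900.0)
    tbv_ml = icv * tbv_pct / 100.0
    csf = icv - tbv_ml
    gm = 0.55 * tbv_ml
    wm = tbv_ml - gm
    wmh_ml = icv * wmh_pct / 100.0

    # Fazekas grades tied to WMH load, plus other SVD features --------------
    log_wmh = np.log(wmh_pct)
    faz_pv = np.clip(
        np.round(
            params.fazekas_intercept_pv
            + params.fazekas_slope * log_wmh
            + rng.normal(0.0, params.fazekas_noise_sd, n)
        ),
        0,
        3,
    ).astype(int)
    faz_dwm = np.clip(
        np.round(
            params.fazekas_intercept_dwm
            + params.fazekas_slope * log_wmh
            + rng.normal(0.0, params.fazekas_noise_sd, n)
        ),
        0,
        3,
    ).astype(int)
    microbleeds = rng.poisson(params.microbleed_rate, n)
    lacune = rng.random(n) < params.lacune_prevalence
    infarct = rng.random(n) < params.infarct_prevalence
    faz_total = faz_pv + faz_dwm
    svd = (faz_total >= 4) | infarct | lacune | (microbleeds > 2)

    # cognitive battery scores reproducing the aggregate exactly ------------
    followup = rng.random(n) < params.followup_rate
    n_tests = len(COGNITIVE_TESTS)
    e = rng.normal(0.0, 0.8, size=(n, n_tests))
    e -= e.mean(axis=1, keepdims=True)
    z_tests = aggregate[:, None] / n_tests + e
    for j, test in enumerate(COGNITIVE_TESTS):
        mean, sd, orientation = BATTERY_NORMS[test]
        scores = mean + orientation * z_tests[:, j] * sd
        frame[test] = np.where(followup, scores, np.nan)
    frame["aggregate_z"] = np.where(followup, aggregate, np.nan)

    frame["gm"] = gm
    frame["wm"] = wm
    frame["csf"] = csf
    frame["icv"] = icv
    frame["tbv_pct_icv"] = tbv_pct
    frame["wmh_pct_icv"] = wmh_pct
    frame["fazekas_pv"] = faz_pv
    frame["fazekas_dwm"] = faz_dwm
    frame["fazekas_total"] = faz_total
    frame["microbleed_count"] = microbleeds
    frame["lacune"] = lacune.astype(int)
    frame["recent_subcortical_infarct"] = infarct.astype(int)
    frame["svd"] = svd.astype(int)

    return frame, params.truth()


def _metrics_from_row(row, seg: str, side: str, rr: float):
    pi = row[f"{seg}_pi_{side}"]
    fvp = row[f"{seg}_fvp_{side}"]
    if np.isnan(pi) or np.isnan(fvp):
        return None
    artery = seg.upper() if seg != "ica" else "ICA"
    return PulsatilityMetrics(
        pi_raw=pi * rr,
        pi_std=pi,
        fvp_raw=fvp * rr,
        fvp_std=fvp,
        mean_flow=float("nan"),
        artery=artery,
        side=side,
    )


def generate_cohort(params: CohortParams):
    """Generate the cohort as :class:`SubjectRecord` objects.

    Same sampling as :func:`generate_cohort_frame` (identical seed →
    identical cohort); returns ``(records, truth)``.
    """
    frame, truth = generate_cohort_frame(params)
    records = []
    for _, row in frame.iterrows():
        rr = row["rr_interval"]
        metrics = {
            seg.upper() if seg != "ica" else "ICA": {
                side: _metrics_from_row(row, seg, side, rr)
                for side in ("left", "right")
            }
            for seg in PULSATILITY_DISTRIBUTIONS
        }
        has_followup = not np.isnan(row["aggregate_z"])
        scores = (
            {t: float(row[t]) for t in COGNITIVE_TESTS} if has_followup else None
        )
        classes = frozenset(
            cls
            for cls in params.antihypertensive_prevalence
            if row[f"antihtn_{cls}"]
        )
        records.append(
            SubjectRecord(
                subject_id=row["subject_id"],
                age=float(row["age"]),
                sex=row["sex"],
                sbp=float(row["sbp"]),
                dbp=float(row["dbp"]),
                map=float(row["map"]),
                hypertension=bool(row["hypertension"]),
                antihypertensive_classes=classes,
                diagnosis=row["diagnosis"],
                nihss=int(row["nihss"]),
                tcbf=float(row["tcbf"]),
                metrics=metrics,
                gm=float(row["gm"]),
                wm=float(row["wm"]),
                csf=float(row["csf"]),
                icv=float(row["icv"]),
                tbv_pct_icv=float(row["tbv_pct_icv"]),
                wmh_pct_icv=float(row["wmh_pct_icv"]),
                fazekas_pv=int(row["fazekas_pv"]),
                fazekas_dwm=int(row["fazekas_dwm"]),
                fazekas_total=int(row["fazekas_total"]),
                microbleed_count=int(row["microbleed_count"]),
                lacune=bool(row["lacune"]),
                recent_subcortical_infarct=bool(row["recent_subcortical_infarct"]),
                svd=bool(row["svd"]),
                test_scores=scores,
                aggregate_z=float(row["aggregate_z"]) if has_followup else None,
            )
        )
    return records, truth
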