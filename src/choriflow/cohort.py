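"""Synthetic three-group cohort generation and simulator calibration.

The generator emulates a cross-sectional cohort of control eyes, diabetic
eyes without retinopathy (dm_no_dr) and eyes with diabetic retinopathy
(dr): 12/15/18 eyes by default, with each group's published mean +/- SD for
the choriocapillaris flow area (CCFA) ratio, tile-CV, superficial vessel
length density (VLD), photoreceptor outer segment (PROS) length and RPE
volume, plus demographics and a systemic lab panel.

Cross-measure correlation is induced by a single latent severity factor
``z ~ N(0, 1)`` per eye: each channel is
``mu_g + sd_g * (lambda * z + sqrt(1 - lambda^2) * eps)``, so the
within-group correlation of two channels is the product of their loadings.
Loadings are solved in closed form so that the *pooled* cohort correlation
between nominated channel pairs (CCFA-VLD first among them) matches the
configured targets, accounting for the between-group mean structure.

``calibrate_preset`` closes the loop with the image pipeline: monotone
bisection on the simulator's void coverage until the *measured* mean CCFA
ratio hits the preset target, then on the heterogeneity amplitude for the
tile CV.  Local slopes are also estimated so per-eye targets can be mapped
to per-eye simulator controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.random import default_rng

__all__ = [
    "GroupPreset",
    "CohortConfig",
    "CalibratedPreset",
    "CalibrationError",
    "ConvergenceError",
    "ConfigurationError",
    "DEFAULT_PRESETS",
    "DEFAULT_ASSOCIATION_PRESET",
    "latent_loadings",
    "generate_cohort",
    "sample_systemic",
    "generate_risk_dataset",
    "calibrate_preset",
]

GROUPS = ("control", "dm_no_dr", "dr")


class ConfigurationError(ValueError):
    """A preset or config field is out of its valid range."""


class CalibrationError(RuntimeError):
    """Bisection bracket does not straddle the calibration target."""


class ConvergenceError(RuntimeError):
    """Calibration ran out of iterations; carries the residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class GroupPreset:
    """Target statistics of one study group plus its simulator controls.

    The default targets are the published group statistics; void_param and
    heterogeneity_param are simulator controls filled in by calibration.
    """

    group: str
    target_ccfa_mean: float  # percent
    target_ccfa_sd: float
    target_cv_mean: float
    target_cv_sd: float
    target_vld_mean: float  # mm/mm^2
    target_vld_sd: float
    pros_mean: float  # um
    pros_sd: float
    rpe_mean: float  # device-reported volume units
    rpe_sd: float
    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    male_fraction: float
    bcva_mean: float
    bcva_sd: float
    crt_mean: float  # central retinal thickness, um
    crt_sd: float
    void_param: Optional[float] = None
    heterogeneity_param: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "target_ccfa_sd",
            "target_cv_sd",
            "target_vld_sd",
            "pros_sd",
            "rpe_sd",
            "age_sd",
            "bcva_sd",
            "crt_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if not (0.0 <= self.target_ccfa_mean <= 100.0):
            raise ConfigurationError(
                f"target_ccfa_mean must lie in [0, 100], got {self.target_ccfa_mean}"
            )
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ConfigurationError(f"male_fraction must lie in [0, 1], got {self.male_fraction}")
        if self.void_param is not None and not (0.0 <= self.void_param <= 1.0):
            raise ConfigurationError(f"void_param must lie in [0, 1], got {self.void_param}")


#: Published group statistics; no dm_no_dr RPE volume is reported and it is set
#: midway between the control and DR values.
DEFAULT_PRESETS: dict[str, GroupPreset] = {
    "control": GroupPreset(
        group="control",
        target_ccfa_mean=69.1, target_ccfa_sd=3.8,
        target_cv_mean=0.124, target_cv_sd=0.019,
        target_vld_mean=21.2, target_vld_sd=0.7,
        pros_mean=64.5, pros_sd=5.2,
        rpe_mean=0.38, rpe_sd=0.02,
        age_mean=44.8, age_sd=12.1, age_range=(27.0, 61.0),
        male_fraction=2 / 12,
        bcva_mean=-0.17, bcva_sd=0.03,
        crt_mean=264.0, crt_sd=17.0,
    ),
    "dm_no_dr": GroupPreset(
        group="dm_no_dr",
        target_ccfa_mean=62.7, target_ccfa_sd=6.9,
        target_cv_mean=0.150, target_cv_sd=0.028,
        target_vld_mean=20.7, target_vld_sd=0.7,
        pros_mean=57.0, pros_sd=6.0,
        rpe_mean=0.39, rpe_sd=0.025,
        age_mean=50.0, age_sd=5.8, age_range=(37.0, 60.0),
        male_fraction=8 / 15,
        bcva_mean=-0.11, bcva_sd=0.08,
        crt_mean=269.0, crt_sd=10.0,
    ),
    "dr": GroupPreset(
        group="dr",
        target_ccfa_mean=58.4, target_ccfa_sd=6.1,
        target_cv_mean=0.174, target_cv_sd=0.035,
        target_vld_mean=18.2, target_vld_sd=1.7,
        pros_mean=56.7, pros_sd=6.0,
        rpe_mean=0.40, rpe_sd=0.03,
        age_mean=52.5, age_sd=4.9, age_range=(42.0, 60.0),
        male_fraction=15 / 18,
        bcva_mean=-0.12, bcva_sd=0.05,
        crt_mean=264.0, crt_sd=24.0,
    ),
}

#: Pooled-cohort correlation targets the latent loadings are solved against.
DEFAULT_CORRELATION_TARGETS = {
    ("ccfa", "vld"): 0.572,
    ("ccfa", "pros"): 0.395,
    ("ccfa", "rpe"): -0.445,
    ("cv", "vld"): -0.578,
}

_CHANNEL_FIELDS = {
    "ccfa": ("target_ccfa_mean", "target_ccfa_sd"),
    "cv": ("target_cv_mean", "target_cv_sd"),
    "vld": ("target_vld_mean", "target_vld_sd"),
    "pros": ("pros_mean", "pros_sd"),
    "rpe": ("rpe_mean", "rpe_sd"),
}


@dataclass(frozen=True)
class CohortConfig:
    n_per_group: tuple[int, int, int] = (12, 15, 18)
    base_seed: int = 0
    presets: dict = field(default_factory=lambda: dict(DEFAULT_PRESETS))
    correlation_targets: dict = field(
        default_factory=lambda: dict(DEFAULT_CORRELATION_TARGETS)
    )

    def __post_init__(self) -> None:
        if len(self.n_per_group) != len(GROUPS):
            raise ConfigurationError("n_per_group must give one size per group")
        if any(n < 2 for n in self.n_per_group):
            raise ConfigurationError("n_per_group requires >= 2 eyes per group")
        if self.base_seed < 0:
            raise ConfigurationError("base_seed must be a nonnegative integer")


def _pooled_moments(presets, weights, channel):
    mf, sf = _CHANNEL_FIELDS[channel]
    mus = np.array([getattr(presets[g], mf) for g in GROUPS])
    sds = np.array([getattr(presets[g], sf) for g in GROUPS])
    mean = float(weights @ mus)
    var = float(weights @ (sds**2) + weights @ ((mus - mean) ** 2))
    return mus, sds, mean, var


def latent_loadings(
    presets: dict[str, GroupPreset] | None = None,
    n_per_group: Sequence[int] = (12, 15, 18),
    correlation_targets: dict | None = None,
) -> dict[str, float]:
    """Solve per-channel latent-severity loadings from pooled correlation targets.

    Within a group corr(X, Y) = lambda_x * lambda_y; pooled over groups the
    between-group mean structure adds its own covariance.  The CCFA-VLD
    target fixes lambda_ccfa = lambda_vld = sqrt(c) (both positive); each
    further target then determines its channel's loading linearly.
    """
    presets = presets or DEFAULT_PRESETS
    targets = dict(DEFAULT_CORRELATION_TARGETS if correlation_targets is None else correlation_targets)
    w = np.asarray(n_per_group, dtype=float)
    w = w / w.sum()

    def within_corr_needed(chx, chy, pooled_target):
        mx, sx, meanx, varx = _pooled_moments(presets, w, chx)
        my, sy, meany, vary = _pooled_moments(presets, w, chy)
        between = float(w @ ((mx - meanx) * (my - meany)))
        needed = pooled_target * math.sqrt(varx * vary) - between
        scale = float(w @ (sx * sy))
        if scale == 0.0:  # a zero-variance channel carries no wiring
            return 0.0
        return needed / scale

    c = within_corr_needed("ccfa", "vld", targets.pop(("ccfa", "vld")))
    if c == 0.0:
        return {ch: 0.0 for ch in _CHANNEL_FIELDS}
    if not (0.0 < c < 1.0):
        raise ConfigurationError(
            f"ccfa-vld pooled target implies within-group correlation {c:.3f} outside (0, 1)"
        )
    loadings = {"ccfa": math.sqrt(c), "vld": math.sqrt(c)}
    for (chx, chy), target in targets.items():
        known, other = (chx, chy) if chx in loadings else (chy, chx)
        if known not in loadings:
            raise ConfigurationError(f"correlation target {(chx, chy)} has no anchored channel")
        lam = within_corr_needed(chx, chy, target) / loadings[known]
        if abs(lam) >= 1.0:
            raise ConfigurationError(
                f"loading for channel {other!r} came out at {lam:.3f}, outside (-1, 1)"
            )
        loadings[other] = lam
    return loadings


def _truncated_normal(rng, mean, sd, lo=-math.inf, hi=math.inf, max_tries=1000):
    """Normal draw truncated by resampling (preserves the bulk of the density)."""
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a reproducible synthetic cohort table, one row per eye.

    Each eye uses its own Generator seeded ``base_seed + eye_index`` so the
    table is byte-identical across runs and insensitive to group order.
    Eyes violating the inclusion invariants (BCVA < 0.05 logMAR, axial
    length < 27 mm, positive measures) are resampled, never emitted.
    """
    config = config or CohortConfig()
    loadings = latent_loadings(
        config.presets, config.n_per_group, config.correlation_targets
    )
    rows = []
    eye_index = 0
    for g, n in zip(GROUPS, config.n_per_group):
        preset = config.presets[g]
        for _ in range(n):
            rng = default_rng(config.base_seed + eye_index)
            z = rng.standard_normal()

            def channel(name, mean, sd, lo=-math.inf, hi=math.inf):
                lam = loadings[name]
                resid = math.sqrt(max(0.0, 1.0 - lam * lam))
                for _ in range(1000):
                    x = mean + sd * (lam * z + resid * rng.standard_normal())
                    if lo <= x <= hi:
                        return float(x)
                return float(min(max(mean, lo), hi))

            ccfa = channel("ccfa", preset.target_ccfa_mean, preset.target_ccfa_sd, 0.0, 100.0)
            cv = channel("cv", preset.target_cv_mean, preset.target_cv_sd, 1e-6)
            vldt = channel("vld", preset.target_vld_mean, preset.target_vld_sd, 1e-6, 40.0)
            pros = channel("pros", preset.pros_mean, preset.pros_sd, 1e-6)
            rpe = channel("rpe", preset.rpe_mean, preset.rpe_sd, 1e-6)
            age = _truncated_normal(rng, preset.age_mean, preset.age_sd, *preset.age_range)
            bcva = _truncated_normal(rng, preset.bcva_mean, preset.bcva_sd, -0.3, 0.0499)
            crt = _truncated_normal(rng, preset.crt_mean, preset.crt_sd, 150.0, 400.0)
            axial = _truncated_normal(rng, 24.2, 0.8, 22.3, 26.9)
            rows.append(
                {
                    "eye_id": f"{g}_{eye_index:04d}",
                    "group": g,
                    "age": age,
                    "sex": "male" if rng.random() < preset.male_fraction else "female",
                    "bcva_logmar": bcva,
                    "axial_length": axial,
                    "quality_index": int(rng.integers(8, 11)),
                    "central_retinal_thickness": crt,
                    "pros_length": pros,
                    "rpe_volume": rpe,
                    "rpe_volume_unit": "um3",
                    "target_ccfa": ccfa,
                    "target_cv": cv,
                    "target_vld": vldt,
                    "severity_z": float(z),
                }
            )
            eye_index += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# systemic labs


@dataclass(frozen=True)
class ExposureSpec:
    """One binary exposure: cutoff on a lab, its generative odds ratio for
    impaired flow, baseline exceedance probability and age slope."""

    column: str
    cutoff: float
    odds_ratio: float
    base_rate: float = 0.25  # P(exceed) for an unimpaired 50-year-old
    age_coef: float = 0.03  # per year of age
    above_is_exceed: bool = True
    spread: float = 1.0  # half-normal spread of the continuous value


#: Generative exceedance odds ratios default to the published age-adjusted
#: values.  Composite lipid indices (LDL/HDL, total and non-HDL cholesterol)
#: are derived from the continuous panel, not independently enforced.
DEFAULT_ASSOCIATION_PRESET: dict[str, ExposureSpec] = {
    "hba1c": ExposureSpec("hba1c", 7.0, 4.992, base_rate=0.25, spread=1.0),
    "systolic_bp": ExposureSpec("systolic_bp", 135.0, 5.572, base_rate=0.30, spread=12.0),
    "diastolic_bp": ExposureSpec("diastolic_bp", 85.0, 1.207, base_rate=0.30, spread=8.0),
    "hdl_c": ExposureSpec("hdl_c", 40.0, 1.759, base_rate=0.15, above_is_exceed=False, spread=10.0),
    "ldl_c": ExposureSpec("ldl_c", 140.0, 1.148, base_rate=0.25, spread=20.0),
    "triglyceride": ExposureSpec("triglyceride", 150.0, 0.946, base_rate=0.25, spread=40.0),
}


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def sample_systemic(
    cohort: pd.DataFrame,
    impaired: Sequence[bool] | str = "impaired",
    assoc_preset: dict[str, ExposureSpec] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill the systemic lab panel conditionally on impaired-flow status.

    For each exposure a binary exceedance indicator is drawn from a
    logistic model ``logit P = logit(base_rate) + ln(OR) * impaired +
    age_coef * (age - 50)``; the continuous lab value is then drawn on the
    matching side of the cutoff (half-normal offset).  Total cholesterol
    and the derived indices follow from the panel (TC = LDL + HDL + TG/5).
    """
    assoc = DEFAULT_ASSOCIATION_PRESET if assoc_preset is None else assoc_preset
    out = cohort.copy()
    flags = (
        out[impaired].to_numpy(dtype=bool)
        if isinstance(impaired, str)
        else np.asarray(impaired, dtype=bool)
    )
    if len(flags) != len(out):
        raise ConfigurationError("impaired flag length does not match the cohort")
    rng = default_rng(seed)
    ages = out["age"].to_numpy(dtype=float) if "age" in out else np.full(len(out), 50.0)
    for name, spec in assoc.items():
        if spec.odds_ratio <= 0:
            raise ConfigurationError(f"odds_ratio for {name} must be positive")
        logit0 = math.log(spec.base_rate / (1.0 - spec.base_rate))
        probs = np.array(
            [
                _logistic(logit0 + math.log(spec.odds_ratio) * f + spec.age_coef * (a - 50.0))
                for f, a in zip(flags, ages)
            ]
        )
        exceed = rng.random(len(out)) < probs
        offset = np.abs(rng.normal(0.0, spec.spread, size=len(out)))
        sign = np.where(exceed == spec.above_is_exceed, 1.0, -1.0)
        values = spec.cutoff + sign * np.maximum(offset, 1e-3)
        values = np.maximum(values, 0.1)  # labs strictly positive
        out[spec.column] = values
        out[f"{spec.column}_exceed"] = exceed
    if {"hdl_c", "ldl_c", "triglyceride"} <= set(out.columns):
        out["total_cholesterol"] = out["hdl_c"] + out["ldl_c"] + out["triglyceride"] / 5.0
        out["non_hdl_c"] = out["total_cholesterol"] - out["hdl_c"]
        out["ldl_hdl_ratio"] = out["ldl_c"] / out["hdl_c"]
        out["total_cholesterol_exceed"] = out["total_cholesterol"] >= 220.0
        out["non_hdl_c_exceed"] = out["non_hdl_c"] >= 170.0
        out["ldl_hdl_ratio_exceed"] = out["ldl_hdl_ratio"] >= 2.5
    return out


def generate_risk_dataset(
    n: int,
    seed: int = 0,
    assoc_preset: dict[str, ExposureSpec] | None = None,
    impaired_base_rate: float = 0.35,
    impaired_age_coef: float = 0.04,
) -> pd.DataFrame:
    """Tabular-only dataset for risk-model recovery experiments.

    Age ~ N(50, 8); impaired flow ~ Bernoulli(logistic in age); labs via
    :func:`sample_systemic`.  Because the binary-binary odds ratio is
    symmetric within each age stratum, regressing impaired status on an
    exceedance indicator plus age recovers the generative OR.
    """
    rng = default_rng(seed)
    ages = rng.normal(50.0, 8.0, size=n)
    logit0 = math.log(impaired_base_rate / (1.0 - impaired_base_rate))
    p = 1.0 / (1.0 + np.exp(-(logit0 + impaired_age_coef * (ages - 50.0))))
    impaired = rng.random(n) < p
    df = pd.DataFrame({"eye_id": [f"eye_{i:05d}" for i in range(n)], "age": ages, "impaired": impaired})
    return sample_systemic(df, "impaired", assoc_preset, seed=seed + 1)


# ---------------------------------------------------------------------------
# pipeline-in-the-loop calibration


@dataclass(frozen=True)
class CalibratedPreset:
    """A GroupPreset with simulator controls fixed by calibration, plus the
    achieved pipeline means and local sensitivities for per-eye mapping."""

    preset: GroupPreset
    achieved_ccfa: float
    achieved_cv: float
    ccfa_slope: float  # d(measured CCFA %) / d(void_param)
    cv_slope: float  # d(measured CV) / d(heterogeneity_param)
    ccfa_dh: float = 0.0  # d(measured CCFA %) / d(heterogeneity_param)
    cv_dv: float = 0.0  # d(measured CV) / d(void_param)

    @property
    def void_param(self) -> float:
        return self.preset.void_param

    @property
    def heterogeneity_param(self) -> float:
        return self.preset.heterogeneity_param

    def controls_for(self, target_ccfa: float, target_cv: float) -> tuple[float, float]:
        """Map per-eye targets to (void_param, heterogeneity_param) by
        inverting the local 2x2 Jacobian of the measured response around the
        calibrated operating point (void coverage also raises the tile CV,
        so the two controls cross-talk)."""
        jac = np.array([[self.ccfa_slope, self.ccfa_dh], [self.cv_dv, self.cv_slope]])
        rhs = np.array(
            [target_ccfa - self.achieved_ccfa, target_cv - self.achieved_cv]
        )
        try:
            dv, dh = np.linalg.solve(jac, rhs)
        except np.linalg.LinAlgError:
            dv = rhs[0] / self.ccfa_slope
            dh = rhs[1] / self.cv_slope
        v = self.preset.void_param + dv
        h = self.preset.heterogeneity_param + dh
        return float(np.clip(v, 0.0, 1.0)), float(max(h, 0.0))


def _bisect(f, lo, hi, target, tol, max_iter, label):
    f_lo, f_hi = f(lo), f(hi)
    if not (min(f_lo, f_hi) - tol <= target <= max(f_lo, f_hi) + tol):
        raise CalibrationError(
            f"{label}: bracket [{lo}, {hi}] -> [{f_lo:.4g}, {f_hi:.4g}] "
            f"does not straddle target {target:.4g}"
        )
    increasing = f_hi > f_lo
    best_x, best_f = (lo, f_lo) if abs(f_lo - target) < abs(f_hi - target) else (hi, f_hi)
    for _ in range(max_iter):
        if abs(best_f - target) <= tol:
            return best_x, best_f, (lo, f_lo, hi, f_hi)
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid - target) < abs(best_f - target):
            best_x, best_f = mid, f_mid
        if (f_mid < target) == increasing:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    raise ConvergenceError(
        f"{label}: no convergence within {max_iter} iterations "
        f"(best {best_f:.4g}, target {target:.4g})",
        residual=abs(best_f - target),
    )


def calibrate_preset(
    preset: GroupPreset,
    pipeline: Callable[[float, float, int], tuple[float, float]],
    tol: float = 0.5,
    cv_tol: float = 0.01,
    max_iter: int = 30,
    seed: int = 1,
    n_eyes: int = 20,
    het_bracket: tuple[float, float] = (0.0, 2.5),
    initial_heterogeneity: float = 0.4,
) -> CalibratedPreset:
    """Set void_param then heterogeneity_param by pipeline-in-the-loop bisection.

    ``pipeline(void_param, heterogeneity_param, seed) -> (ccfa, cv)`` must
    run the full simulate-correct-binarize-measure chain for one eye.  Each
    candidate control is scored as the mean over ``n_eyes`` eyes with common
    random seeds, which makes the score deterministic and monotone so plain
    bisection applies.  Raises :class:`CalibrationError` when a bracket does
    not straddle its target (e.g. a CV target below the spatial-sampling
    floor of the tile grid) and :class:`ConvergenceError` on iteration
    exhaustion.
    """
    if tol <= 0 or cv_tol <= 0:
        raise ConfigurationError("tolerances must be positive")
    seeds = [seed + 100_000 + i for i in range(n_eyes)]
    cache: dict[tuple[float, float], tuple[float, float]] = {}

    def score(v, h):
        key = (round(v, 10), round(h, 10))
        if key not in cache:
            pairs = [pipeline(v, h, s) for s in seeds]
            cvs = [p[1] for p in pairs if p[1] is not None]
            cache[key] = (
                float(np.mean([p[0] for p in pairs])),
                float(np.mean(cvs)) if cvs else float("nan"),
            )
        return cache[key]

    h0 = initial_heterogeneity
    v_star, _, _ = _bisect(
        lambda v: score(v, h0)[0], 0.0, 1.0, preset.target_ccfa_mean,
        tol, max_iter, "void_param/CCFA",
    )
    h_star, _, _ = _bisect(
        lambda h: score(v_star, h)[1], het_bracket[0], het_bracket[1],
        preset.target_cv_mean, cv_tol, max_iter, "heterogeneity_param/CV",
    )
    # achieved means at the operating point, and finite-difference local
    # sensitivities (common random seeds keep the differences smooth)
    ccfa_final, cv_final = score(v_star, h_star)
    dv = 0.04 if v_star <= 0.96 else -0.04
    ccfa_v, cv_v = score(v_star + dv, h_star)
    ccfa_slope = (ccfa_v - ccfa_final) / dv
    cv_dv = (cv_v - cv_final) / dv if math.isfinite(cv_v) else 0.0
    if abs(ccfa_slope) < 1.0:  # degenerate response; fall back to the ideal slope
        ccfa_slope = -100.0
    dh = 0.2
    ccfa_h, cv_h = score(v_star, h_star + dh)
    cv_slope = (cv_h - cv_final) / dh
    ccfa_dh = (ccfa_h - ccfa_final) / dh
    if cv_slope < 1e-3:
        cv_slope = 0.15

    return CalibratedPreset(
        preset=replace(preset, void_param=v_star, heterogeneity_param=h_star),
        achieved_ccfa=ccfa_final,
        achieved_cv=cv_final,
        ccfa_slope=ccfa_slope,
        cv_slope=cv_slope,
        ccfa_dh=ccfa_dh,
        cv_dv=cv_dv,
    )
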