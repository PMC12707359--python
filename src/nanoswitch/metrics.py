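"""Precision and accuracy metrics for continuous concentration monitoring.

Implements the assay-performance toolbox: coefficient of variation of
repeated 1-min concentration determinations (CV_C), blank-based limit of
detection via calibration-curve inversion, precision-profile limit of
quantification, dilution correction, mean absolute relative difference
(MARD) against a reference method, and normal/log-normal fits of the
imprecision distribution with Anderson–Darling goodness of fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calibration import FLAG_OK, CalibrationCurve, invert_sigmoid
from .errors import InputError

__all__ = [
    "PrecisionProfile",
    "BlankStats",
    "LodResult",
    "LoqResult",
    "MardResult",
    "DistributionFits",
    "cv_c",
    "lod",
    "loq_from_profile",
    "dilution_correct",
    "mard",
    "imprecision_distribution",
    "precision_profile",
]


def cv_c(per_interval_concs) -> float:
    """Coefficient of variation (%) of repeated concentration values.

    100 * sample SD (n-1 denominator) / mean.
    """
    x = np.asarray(per_interval_concs, dtype=float)
    if len(x) < 2:
        raise InputError("need >= 2 values")
    mean = x.mean()
    if mean <= 0:
        raise InputError("mean must be > 0")
    return float(100.0 * x.std(ddof=1) / mean)


@dataclass(frozen=True)
class BlankStats:
    """Blank signal level and its SD on the normalized-signal scale."""

    signal_blank: float
    sigma_blank: float

    def __post_init__(self) -> None:
        if self.sigma_blank < 0:
            raise InputError("sigma_blank must be >= 0")


@dataclass(frozen=True)
class LodResult:
    conc_pM: float
    signal: float
    below_curve_floor: bool


def lod(blank: BlankStats, curve: CalibrationCurve) -> LodResult:
    """Limit of detection: concentration at blank signal + 3 sigma.

    If that signal does not exceed the curve's bottom plateau the LoD is
    below the curve floor and is reported as 0 pM with a flag.
    """
    s = blank.signal_blank + 3.0 * blank.sigma_blank
    if s <= curve.S_min:
        return LodResult(conc_pM=0.0, signal=s, below_curve_floor=True)
    x, flag = invert_sigmoid(curve, s)
    return LodResult(conc_pM=x, signal=s, below_curve_floor=flag != FLAG_OK)


@dataclass
class PrecisionProfile:
    """Mean/SD of CV_C per concentration, concentrations ascending."""

    concentrations_pM: np.ndarray
    mean_cv_pct: np.ndarray
    sd_cv_pct: np.ndarray
    n_measurements: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations_pM = np.asarray(self.concentrations_pM, float)
        self.mean_cv_pct = np.asarray(self.mean_cv_pct, float)
        self.sd_cv_pct = np.asarray(self.sd_cv_pct, float)
        self.n_measurements = np.asarray(self.n_measurements, int)
        if np.any(np.diff(self.concentrations_pM) <= 0):
            raise InputError("concentrations must be strictly increasing")
        if np.any(self.mean_cv_pct < 0):
            raise InputError("CV_C must be >= 0")


def precision_profile(estimates) -> PrecisionProfile:
    """Aggregate :class:`ConcentrationEstimate` objects by true concentration."""
    by_conc: dict[float, list[float]] = {}
    for est in estimates:
        if est.true_conc_pM is None or math.isnan(est.cv_c_pct):
            continue
        by_conc.setdefault(float(est.true_conc_pM), []).append(est.cv_c_pct)
    concs = np.array(sorted(by_conc))
    means = np.array([np.mean(by_conc[c]) for c in concs])
    sds = np.array([np.std(by_conc[c], ddof=1) if len(by_conc[c]) > 1 else 0.0
                    for c in concs])
    ns = np.array([len(by_conc[c]) for c in concs])
    return PrecisionProfile(concs, means, sds, ns)


@dataclass(frozen=True)
class LoqResult:
    conc_pM: float
    flag: str  # "interpolated" | "at_or_below_lowest" | "not_quantifiable"


def loq_from_profile(profile: PrecisionProfile,
                     cv_threshold_pct: float = 10.0) -> LoqResult:
    """Lower limit of quantification from a precision profile.

    The lowest concentration where the mean-CV_C curve crosses below the
    threshold, log-linearly interpolated between the bracketing
    concentrations.  If every CV is already below the threshold the lowest
    measured concentration is returned with an "at_or_below_lowest" flag.
    """
    if len(profile.concentrations_pM) < 2:
        raise InputError("profile needs >= 2 concentrations")
    cv = profile.mean_cv_pct
    concs = profile.concentrations_pM
    if cv_threshold_pct <= 0 or np.all(cv >= cv_threshold_pct):
        return LoqResult(conc_pM=float("nan"), flag="not_quantifiable")
    below = np.nonzero(cv < cv_threshold_pct)[0]
    i = int(below[0])
    if i == 0:
        return LoqResult(conc_pM=float(concs[0]), flag="at_or_below_lowest")
    frac = (cv[i - 1] - cv_threshold_pct) / (cv[i - 1] - cv[i])
    log_c = math.log(concs[i - 1]) + frac * (math.log(concs[i])
                                             - math.log(concs[i - 1]))
    return LoqResult(conc_pM=float(math.exp(log_c)), flag="interpolated")


def dilution_correct(conc_pM: float, dilution_factor: float) -> float:
    """Back-calculate the undiluted concentration, returned in nM."""
    if dilution_factor < 1:
        raise InputError("dilution_factor must be >= 1")
    return conc_pM * dilution_factor / 1000.0


@dataclass(frozen=True)
class MardResult:
    mard_pct: float
    n_used: int
    n_excluded: int


def mard(sensor_pM, reference_pM, exclude=None) -> MardResult:
    """Mean absolute relative difference (%) of sensor vs reference values.

    ``exclude`` is an optional boolean mask of pairs flagged outside the
    calibration range; excluded pairs are counted, not averaged.
    """
    s = np.asarray(sensor_pM, dtype=float)
    r = np.asarray(reference_pM, dtype=float)
    if len(s) != len(r) or len(s) == 0:
        raise InputError("need equal-length, non-empty pair lists")
    keep = np.ones(len(s), dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    if np.any(r[keep] <= 0):
        raise InputError("reference concentrations must be > 0")
    if not keep.any():
        raise InputError("all pairs excluded")
    val = 100.0 * np.mean(np.abs(s[keep] - r[keep]) / r[keep])
    return MardResult(mard_pct=float(val), n_used=int(keep.sum()),
                      n_excluded=int((~keep).sum()))


@dataclass(frozen=True)
class DistributionFits:
    normal_mean: float
    normal_sd: float
    ad_p_normal: float
    geometric_mean: float
    geometric_sd: float
    ad_p_lognormal: float


def _ad_pvalue_normal(x: np.ndarray) -> float:
    """Anderson–Darling p-value for normality with estimated parameters.

    Prefers scipy's tabulated p-value (scipy >= 1.17); otherwise falls back
    to the small-sample statistic adjustment and piecewise exponential
    approximation of D'Agostino & Stephens for the estimated-parameter case.
    """
    n = len(x)
    try:
        res = stats.anderson(x, dist="norm", method="interpolate")
        return float(res.pvalue)
    except TypeError:  # pragma: no cover - older scipy
        pass
    a2 = stats.anderson(x, dist="norm").statistic
    a2s = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2s >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s**2)
    elif a2s > 0.34:
        p = math.exp(0.9177 - 4.279 * a2s - 1.38 * a2s**2)
    elif a2s > 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a2s - 59.938 * a2s**2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a2s - 223.73 * a2s**2)
    return float(min(max(p, 0.0), 1.0))


def imprecision_distribution(cv_values_pct) -> DistributionFits:
    """Fit normal and log-normal models to a set of CV_C values (%).

    The log-normal fit is the normal fit of log values; its location is
    reported as the geometric mean exp(mean(log x)) and geometric SD
    exp(SD(log x)).  Goodness of fit uses the Anderson–Darling test with
    estimated parameters on the raw and log scales respectively.
    """
    x = np.asarray(cv_values_pct, dtype=float)
    if len(x) < 8:
        raise InputError("need >= 8 values")
    if np.any(x <= 0):
        raise InputError("CV values must be > 0")
    if np.ptp(x) == 0:
        raise InputError("degenerate (constant) sample")
    logx = np.log(x)
    return DistributionFits(
        normal_mean=float(x.mean()),
        normal_sd=float(x.std(ddof=1)),
        ad_p_normal=_ad_pvalue_normal(x),
        geometric_mean=float(np.exp(logx.mean())),
        geometric_sd=float(np.exp(logx.std(ddof=1))),
        ad_p_lognormal=_ad_pvalue_normal(logx),
    )
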