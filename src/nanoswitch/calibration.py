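"""Signal normalization, sigmoidal dose-response fitting and quantification.

The sensor's raw activity drifts slowly; it is therefore normalized against
a repeated pair of reference samples (a *zero* and a *unity* anchor) by
linear interpolation of each anchor's activity over time.  The normalized
signal follows a four-parameter logistic in concentration,

    S(X) = S_min + (S_max - S_min) * X**n / (EC50**n + X**n),

which is fitted by nonlinear least squares and inverted to convert signals
into concentrations.  Three quantification strategies are provided:
periodically refitted calibration, a single up-front fit, and a fixed
pre-established curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from ._types import ActivityTrace
from .errors import CalibrationError, FitConvergenceError, InputError

__all__ = [
    "CalibrationCurve",
    "FIXED_CURVE",
    "NormalizationAnchors",
    "ConcentrationEstimate",
    "FitDiagnostics",
    "evaluate_sigmoid",
    "invert_sigmoid",
    "normalize_signals",
    "normalize_values",
    "fit_calibration",
    "apply_strategy",
]

FLAG_OK = "ok"
FLAG_BELOW = "below_range"
FLAG_ABOVE = "above_range"


@dataclass(frozen=True)
class CalibrationCurve:
    """Four-parameter logistic dose-response on the normalized-signal scale."""

    S_min: float
    S_max: float
    EC50_pM: float
    n: float

    def __post_init__(self) -> None:
        if not self.S_max > self.S_min:
            raise InputError("S_max must be > S_min")
        if self.EC50_pM <= 0:
            raise InputError("EC50 must be > 0")
        if self.n <= 0:
            raise InputError("slope factor n must be > 0")


#: Fixed curve used by quantification strategy 3.
FIXED_CURVE = CalibrationCurve(S_min=-0.5, S_max=4.0, EC50_pM=1030.0, n=1.0)


def evaluate_sigmoid(curve: CalibrationCurve, X):
    """Normalized signal at concentration ``X`` (pM); monotone increasing."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise InputError("concentration must be >= 0")
    xn = np.where(X > 0, X, 1.0) ** curve.n
    frac = np.where(X > 0, xn / (curve.EC50_pM**curve.n + xn), 0.0)
    S = curve.S_min + (curve.S_max - curve.S_min) * frac
    return S if S.ndim else float(S)


def invert_sigmoid(curve: CalibrationCurve, S):
    """Concentration (pM) at normalized signal ``S``; exact inverse.

    Returns ``(X, flags)``.  Signals at or below ``S_min`` map to 0 pM with
    flag ``below_range``; at or above ``S_max`` to ``inf`` with flag
    ``above_range``.  Out-of-range values are flagged, never silently
    clipped.
    """
    S_arr = np.asarray(S, dtype=float)
    scalar = S_arr.ndim == 0
    S_arr = np.atleast_1d(S_arr)
    X = np.empty_like(S_arr)
    flags = np.full(S_arr.shape, FLAG_OK, dtype=object)

    below = S_arr <= curve.S_min
    above = S_arr >= curve.S_max
    ok = ~(below | above)
    X[below] = 0.0
    flags[below] = FLAG_BELOW
    X[above] = np.inf
    flags[above] = FLAG_ABOVE
    ratio = (S_arr[ok] - curve.S_min) / (curve.S_max - S_arr[ok])
    X[ok] = curve.EC50_pM * ratio ** (1.0 / curve.n)
    if scalar:
        return float(X[0]), str(flags[0])
    return X, flags


@dataclass
class NormalizationAnchors:
    """Repeated zero/unity reference measurements over the experiment clock.

    ``t_min[j]`` is the timestamp of the j-th anchor repeat; at that time the
    zero-anchor sample measured ``zero_activity[j]`` and the unity-anchor
    sample ``unity_activity[j]``.
    """

    t_min: np.ndarray
    zero_activity: np.ndarray
    unity_activity: np.ndarray
    zero_conc_pM: float = 125.0
    unity_conc_pM: float = 506.0

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.zero_activity = np.asarray(self.zero_activity, dtype=float)
        self.unity_activity = np.asarray(self.unity_activity, dtype=float)
        if not (len(self.t_min) == len(self.zero_activity)
                == len(self.unity_activity)):
            raise InputError("anchor array length mismatch")
        if len(self.t_min) < 1:
            raise InputError("need at least one anchor repeat")
        if np.any(np.diff(self.t_min) <= 0):
            raise InputError("anchor timestamps must be increasing")
        if np.any(self.unity_activity <= self.zero_activity):
            raise InputError("unity anchor activity must exceed zero anchor")


def normalize_values(t_min, activity, anchors: NormalizationAnchors):
    """Normalize raw activities against time-interpolated anchors.

    The zero/unity anchor levels are interpolated linearly in time between
    anchor repeats (constant extrapolation outside); the normalized signal
    is (A - A_zero(t)) / (A_unity(t) - A_zero(t)).
    """
    t = np.asarray(t_min, dtype=float)
    a = np.asarray(activity, dtype=float)
    low = np.interp(t, anchors.t_min, anchors.zero_activity)
    high = np.interp(t, anchors.t_min, anchors.unity_activity)
    if np.any(high <= low):
        raise CalibrationError("degenerate anchors: unity level <= zero level")
    return (a - low) / (high - low)


def normalize_signals(activity: ActivityTrace, anchors: NormalizationAnchors):
    """Normalized signal per interval of an :class:`ActivityTrace`."""
    return normalize_values(activity.t_min, activity.activity, anchors)


@dataclass
class FitDiagnostics:
    stderr: dict
    residual_sd: float
    n_points: int
    n_distinct_conc: int


def fit_calibration(X, S, fix_n: float | None = None
                    ) -> tuple[CalibrationCurve, FitDiagnostics]:
    """Unweighted nonlinear least-squares fit of the dose-response sigmoid.

    Requires >= 4 distinct concentrations (>= 3 when ``fix_n`` pins the
    slope factor).  Initializer: S_min = min(S), S_max = max(S), EC50 = the
    concentration whose mean signal is nearest mid-signal, n = 1; bounds
    EC50 in [1, 1e6] pM, n in [0.3, 3].
    """
    X = np.asarray(X, dtype=float)
    S = np.asarray(S, dtype=float)
    if len(X) != len(S):
        raise InputError("X/S length mismatch")
    distinct = np.unique(X)
    need = 3 if fix_n is not None else 4
    if len(distinct) < need:
        raise CalibrationError(
            f"need >= {need} distinct concentrations, got {len(distinct)}")
    if np.ptp(S) == 0:
        raise FitConvergenceError("all signals identical; sigmoid is degenerate",
                                  data_summary={"n": len(S), "S": float(S[0])})

    s_lo, s_hi = float(S.min()), float(S.max())
    mid = 0.5 * (s_lo + s_hi)
    means = np.array([S[X == c].mean() for c in distinct])
    pos = distinct[distinct > 0]
    if len(pos):
        pos_means = means[distinct > 0]
        ec50_0 = float(pos[np.argmin(np.abs(pos_means - mid))])
    else:  # pragma: no cover - guarded by distinct-count check
        ec50_0 = 1.0
    ec50_0 = min(max(ec50_0, 1.0), 1e6)

    if fix_n is None:
        def model(x, s_min, s_max, ec50, n):
            return evaluate_sigmoid_raw(x, s_min, s_max, ec50, n)
        p0 = [s_lo, s_hi, ec50_0, 1.0]
        bounds = ([-np.inf, -np.inf, 1.0, 0.3], [np.inf, np.inf, 1e6, 3.0])
        names = ["S_min", "S_max", "EC50_pM", "n"]
    else:
        def model(x, s_min, s_max, ec50):
            return evaluate_sigmoid_raw(x, s_min, s_max, ec50, fix_n)
        p0 = [s_lo, s_hi, ec50_0]
        bounds = ([-np.inf, -np.inf, 1.0], [np.inf, np.inf, 1e6])
        names = ["S_min", "S_max", "EC50_pM"]

    try:
        popt, pcov = curve_fit(model, X, S, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError(
            f"calibration fit did not converge: {exc}", p0=p0,
            data_summary={"n": len(S), "distinct": len(distinct)},
        ) from exc

    params = dict(zip(names, popt))
    if fix_n is not None:
        params["n"] = fix_n
    curve = CalibrationCurve(params["S_min"], params["S_max"],
                             params["EC50_pM"], params["n"])
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    resid = S - evaluate_sigmoid(curve, X)
    dof = max(len(S) - len(popt), 1)
    diag = FitDiagnostics(stderr=dict(zip(names, perr)),
                          residual_sd=float(np.sqrt((resid**2).sum() / dof)),
                          n_points=len(S), n_distinct_conc=len(distinct))
    return curve, diag


def evaluate_sigmoid_raw(X, s_min, s_max, ec50, n):
    """Sigmoid on raw parameters (for the optimizer; X=0 maps to s_min)."""
    X = np.asarray(X, dtype=float)
    xn = np.where(X > 0, X, 1.0) ** n
    frac = np.where(X > 0, xn / (ec50**n + xn), 0.0)
    return s_min + (s_max - s_min) * frac


@dataclass
class ConcentrationEstimate:
    """Per-sample concentration from repeated 1-min interval inversions."""

    sample_id: str
    t_min: float
    true_conc_pM: float | None
    concs_pM: np.ndarray
    flags: np.ndarray
    n_intervals: int
    n_excluded: int
    mean_pM: float
    sd_pM: float
    cv_c_pct: float

    @classmethod
    def from_inversions(cls, sample_id, t_min, true_conc_pM, concs, flags):
        concs = np.asarray(concs, dtype=float)
        flags = np.asarray(flags, dtype=object)
        ok = flags == FLAG_OK
        used = concs[ok]
        n_excluded = int((~ok).sum())
        if len(used) == 0:
            mean = sd = cv = float("nan")
        else:
            mean = float(used.mean())
            sd = float(used.std(ddof=1)) if len(used) > 1 else 0.0
            cv = 100.0 * sd / mean if mean > 0 else float("nan")
        return cls(sample_id=sample_id, t_min=float(t_min),
                   true_conc_pM=true_conc_pM, concs_pM=concs, flags=flags,
                   n_intervals=len(concs), n_excluded=n_excluded,
                   mean_pM=mean, sd_pM=sd, cv_c_pct=cv)


def anchors_from_records(records) -> NormalizationAnchors:
    """Build normalization anchors from an experiment record table.

    Uses ``norm_reference`` injections when present (the two distinct
    concentrations become the zero/unity anchors; repeats are paired in
    time order).  Falls back to blank injections (zero) and the highest
    calibrant concentration (unity) for schedules without dedicated
    normalization references.  Anchor activities are interval means per
    injection; the timestamp is the mean time of the pair.
    """
    df = _with_activity(records)
    norm = df[df["role"] == "norm_reference"]
    if len(norm) and norm["true_conc_pM"].nunique() >= 2:
        concs = np.sort(norm["true_conc_pM"].unique())
        lo_c, hi_c = float(concs[0]), float(concs[-1])
        lo = _injection_means(norm[norm["true_conc_pM"] == lo_c])
        hi = _injection_means(norm[norm["true_conc_pM"] == hi_c])
    else:
        blanks = df[df["role"] == "blank"]
        cal = df[df["role"].isin(["calibrant", "norm_reference"])]
        if not len(blanks) or not len(cal):
            raise CalibrationError(
                "cannot build anchors: need norm_reference pairs or "
                "blank + calibrant injections")
        hi_c = float(cal["true_conc_pM"].max())
        lo_c = 0.0
        lo = _injection_means(blanks)
        hi = _injection_means(cal[cal["true_conc_pM"] == hi_c])
    n = min(len(lo), len(hi))
    if n == 0:
        raise CalibrationError("no complete anchor pairs found")
    t = 0.5 * (lo["t"].to_numpy()[:n] + hi["t"].to_numpy()[:n])
    return NormalizationAnchors(t_min=t,
                                zero_activity=lo["a"].to_numpy()[:n],
                                unity_activity=hi["a"].to_numpy()[:n],
                                zero_conc_pM=lo_c, unity_conc_pM=hi_c)


def _with_activity(records):
    df = records.copy()
    if "activity" not in df.columns:
        df["activity"] = df["counts"] / df["n_particles"]
    return df


def _injection_means(df):
    g = df.groupby("injection_index", sort=True)
    out = g.agg(t=("t_min", "mean"), a=("activity", "mean")).reset_index()
    return out.sort_values("t")


def _calibrant_blocks(df):
    """Consecutive runs of calibrant injections → list of record frames."""
    cal = df[df["role"] == "calibrant"]
    blocks = []
    current: list[int] = []
    prev = None
    for idx in sorted(cal["injection_index"].unique()):
        if prev is not None and idx != prev + 1:
            blocks.append(current)
            current = []
        current.append(idx)
        prev = idx
    if current:
        blocks.append(current)
    return [cal[cal["injection_index"].isin(b)] for b in blocks]


def apply_strategy(
    records,
    strategy: int,
    fixed_curve: CalibrationCurve | None = None,
    recal_period_h: float = 4.0,
    fix_n: float | None = None,
    quantify_roles: tuple[str, ...] = ("blind",),
) -> list[ConcentrationEstimate]:
    """Quantify samples in an experiment record table.

    1. refit the sigmoid on the most recent calibrant block, taking a new
       block no more often than every ``recal_period_h`` hours;
    2. fit once on the first calibrant block;
    3. use ``fixed_curve`` as-is.

    All strategies first normalize against the schedule's anchor samples.
    Each quantified injection's intervals are inverted individually; flagged
    out-of-range inversions are excluded from the mean/SD/CV.
    """
    if strategy not in (1, 2, 3):
        raise InputError("strategy must be 1, 2 or 3")
    if strategy == 3 and fixed_curve is None:
        raise CalibrationError("strategy 3 requires a fixed curve")

    df = _with_activity(records)
    anchors = anchors_from_records(df)
    df["S_norm"] = normalize_values(df["t_min"].to_numpy(),
                                    df["activity"].to_numpy(), anchors)

    if strategy in (1, 2):
        blocks = _calibrant_blocks(df)
        if not blocks:
            raise CalibrationError(
                f"strategy {strategy} requires calibrant injections")
        fitted = []  # (block_start_min, curve)
        last_t = -math.inf
        for blk in blocks:
            t0 = float(blk["t_min"].min())
            if fitted and t0 - last_t < 60.0 * recal_period_h:
                continue
            curve, _ = fit_calibration(blk["true_conc_pM"].to_numpy(),
                                       blk["S_norm"].to_numpy(), fix_n=fix_n)
            fitted.append((t0, curve))
            last_t = t0
            if strategy == 2:
                break

    estimates = []
    target = df[df["role"].isin(quantify_roles)]
    for idx in sorted(target["injection_index"].unique()):
        inj = target[target["injection_index"] == idx]
        t_inj = float(inj["t_min"].mean())
        if strategy == 3:
            curve = fixed_curve
        else:
            eligible = [c for t0, c in fitted if t0 <= t_inj] or [fitted[0][1]]
            curve = eligible[-1]
        concs, flags = invert_sigmoid(curve, inj["S_norm"].to_numpy())
        true_c = float(inj["true_conc_pM"].iloc[0])
        role = inj["role"].iloc[0]
        estimates.append(ConcentrationEstimate.from_inversions(
            sample_id=f"inj{idx:03d}_{role}_{true_c:g}pM",
            t_min=t_inj, true_conc_pM=true_c, concs=concs, flags=flags))
    return estimates
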