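"""Death-specific drug-response metrics from plate-reader kinetics.

The FLICK-style assay measures dead-cell dye fluorescence per well over
time, plus the total-cell fluorescence of lysed duplicate plates at assay
start and end. From these, live-cell fluorescence and the death-specific
metrics follow:

- lethal fraction  LF = dead / (live + dead), fractional viability FV = 1 - LF
- relative viability  RV = live_treated / live_untreated
- GR value  GR = 2**(log2(live_tx/live_T0) / log2(live_unt/live_T0)) - 1,
  the growth-rate-normalized response (1 = no effect, 0 = complete arrest,
  negative = net population shrinkage)

Kinetic LF(t) curves are fit with the lag-exponential death (LED) model;
dose-response curves with a four-parameter logistic; and the coordination
between growth inhibition and death activation across doses is summarized
by the GRADE angle-ratio statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "infer_total_timecourse",
    "subtract_background",
    "compute_metrics",
    "LEDCurve",
    "FourParamLogistic",
    "fit_led",
    "fit_dose_response",
    "GradeResult",
    "compute_grade",
    "led_curve",
    "logistic4",
]


def infer_total_timecourse(t0_total: float, end_total: float, times, t_end: float):
    """Interpolate total-cell fluorescence between lysed-plate endpoints.

    Assumes simple exponential growth between the two lysed plates:
    ``total(t) = t0_total * (end_total / t0_total)**(t / t_end)``.
    Endpoints reproduce the inputs exactly; net shrinkage
    (``end_total < t0_total``) is allowed but logged.
    """
    if t0_total <= 0 or end_total <= 0:
        raise ValueError("lysed-plate totals must be positive")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(times > t_end):
        raise ValueError("times must lie within [0, t_end]")
    if end_total < t0_total:
        logger.warning(
            "end_total (%g) < t0_total (%g): modeling net population shrinkage",
            end_total, t0_total,
        )
    return t0_total * (end_total / t0_total) ** (times / t_end)


def subtract_background(signal, background):
    """Subtract cell-free-well background; clip negatives to 0 with a log entry."""
    out = np.asarray(signal, dtype=float) - np.asarray(background, dtype=float)
    n_neg = int(np.sum(out < 0))
    if n_neg:
        logger.info("background subtraction clipped %d negative values to 0", n_neg)
    return np.clip(out, 0.0, None)


def compute_metrics(dead, total, untreated_live, live_t0: float) -> pd.DataFrame:
    """Compute LF, FV, RV and GR from background-subtracted fluorescence.

    Parameters
    ----------
    dead, total : array-like
        Dead-cell and total-cell fluorescence of the treated wells, paired
        element-wise (background already subtracted).
    untreated_live : array-like
        Live-cell fluorescence of matched untreated wells at the same times.
    live_t0 : float
        Live-cell fluorescence at treatment start.

    Returns
    -------
    DataFrame with columns ``live, LF, FV, RV, GR``. Points where the GR
    denominator is undefined (untreated not grown past T0) carry GR = NaN
    and are counted in ``df.attrs['n_gr_undefined']`` rather than dropped;
    points with zero total leave FV/LF as NaN
    (``df.attrs['n_fv_undefined']``).
    """
    dead = np.asarray(dead, dtype=float)
    total = np.asarray(total, dtype=float)
    untreated_live = np.asarray(untreated_live, dtype=float)
    live = total - dead
    n_neg = int(np.sum(live < 0))
    if n_neg:
        warnings.warn(
            f"{n_neg} points had dead > total; live clipped to 0", stacklevel=2
        )
        live = np.clip(live, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        fv = np.where(total > 0, live / (live + dead), np.nan)
        rv = live / untreated_live
        log_num = np.log2(live / live_t0)
        log_den = np.log2(untreated_live / live_t0)
        gr_ok = untreated_live > live_t0
        gr = np.where(gr_ok & (live > 0), np.exp2(log_num / log_den) - 1.0, np.nan)
        # complete kill: live == 0 maps to GR -> -1 in the growing-reference limit
        gr = np.where(gr_ok & (live == 0), -1.0, gr)
    out = pd.DataFrame({"live": live, "LF": 1.0 - fv, "FV": fv, "RV": rv, "GR": gr})
    out.attrs["n_gr_undefined"] = int(np.sum(~gr_ok))
    out.attrs["n_fv_undefined"] = int(np.sum(~(total > 0)))
    return out


def led_curve(t, lf0: float, lfp: float, d0: float, dr: float):
    """Lag-exponential death curve.

    LF(t) = LF0 for t <= D0, and
    LF(t) = LF0 + (LFp - LF0) * (1 - exp(-DR * (t - D0))) for t > D0.
    """
    t = np.asarray(t, dtype=float)
    dt = np.maximum(t - d0, 0.0)
    return lf0 + (lfp - lf0) * (1.0 - np.exp(-dr * dt))


def logistic4(x, fv0: float, ecmax: float, ec50: float, hillslope: float):
    """Four-parameter logistic in log10-dose ``x``.

    response(x) = ECmax + (FV0 - ECmax) / (1 + 10**((x - EC50) * hillslope)).
    At ``x = EC50`` the curve equals the plateau midpoint (FV0 + ECmax) / 2.
    """
    x = np.asarray(x, dtype=float)
    return ecmax + (fv0 - ecmax) / (1.0 + 10.0 ** ((x - ec50) * hillslope))


class LEDCurve(BaseEstimator):
    """Lag-exponential death (LED) model of the lethal-fraction timecourse.

    Fits ``LF(t)`` by bounded nonlinear least squares with deterministic
    multi-start: death onset ``D0`` is started at the quartiles of the time
    window and ties are broken by lowest residual sum of squares, then
    lowest ``D0``.

    Parameters
    ----------
    flat_tol : float
        LF range below which the input is treated as flat (degenerate fit
        with ``DR = 0`` and unidentifiable ``D0``).
    n_auc : int
        Number of grid points for the trapezoidal AUC of the fitted curve.

    Attributes
    ----------
    lf0_, lfp_, d0_, dr_ : float
        Fitted starting lethal fraction, plateau, onset time (h) and
        maximum death rate (per h).
    auc_ : float
        Trapezoidal area under the fitted LF(t) over the observed window.
    rss_ : float
        Residual sum of squares.
    degenerate_ : bool
        True for flat input where ``D0`` is unidentifiable.
    """

    def __init__(self, flat_tol: float = 1e-3, n_auc: int = 512):
        self.flat_tol = flat_tol
        self.n_auc = n_auc

    def fit(self, t, lf):
        t = np.asarray(t, dtype=float)
        lf = np.asarray(lf, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:  # sklearn-style column vector
            t = t.ravel()
        if t.shape != lf.shape or t.ndim != 1:
            raise ValueError("t and lf must be 1-d arrays of equal length")
        if t.size < 6:
            raise ValueError("need at least 6 timepoints to fit the LED model")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any((lf < -1e-9) | (lf > 1 + 1e-9)):
            raise ValueError("LF values must lie in [0, 1]")
        lf = np.clip(lf, 0.0, 1.0)

        if np.ptp(lf) < self.flat_tol:
            self.lf0_ = float(np.mean(lf))
            self.lfp_ = float(np.mean(lf))
            self.d0_ = float("nan")
            self.dr_ = 0.0
            self.rss_ = float(np.sum((lf - np.mean(lf)) ** 2))
            self.degenerate_ = True
            self.auc_ = float(np.mean(lf) * (t[-1] - t[0]))
            return self
        if np.all(np.diff(lf) <= 0) and (lf[0] - lf[-1]) > self.flat_tol:
            raise ValueError(
                "LF decreases monotonically over time; data violate the LED model"
            )

        t_span = t[-1] - t[0]
        lo = np.array([0.0, 0.0, 0.0, 0.0])
        hi = np.array([1.0, 1.0, t[-1], np.inf])
        lf0_init = float(np.clip(np.min(lf[: max(2, t.size // 4)]), 0, 1))
        lfp_init = float(np.clip(np.max(lf), 1e-6, 1))
        dr_init = 2.0 / t_span

        def resid(p):
            return led_curve(t, *p) - lf

        best = None
        for q in (0.125, 0.375, 0.625, 0.875):
            d0_start = float(t[0] + q * t_span)
            x0 = np.clip([lf0_init, lfp_init, d0_start, dr_init], lo, [1, 1, t[-1], 1e6])
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
            key = (round(float(sol.cost), 12), float(sol.x[2]))
            if best is None or key < best[0]:
                best = (key, sol)
        sol = best[1]
        self.lf0_, self.lfp_, self.d0_, self.dr_ = (float(v) for v in sol.x)
        self.rss_ = float(2 * sol.cost)
        self.degenerate_ = False
        grid = np.linspace(t[0], t[-1], self.n_auc)
        self.auc_ = float(np.trapezoid(self.predict(grid), grid))
        return self

    def predict(self, t):
        if self.degenerate_:
            return np.full(np.asarray(t, dtype=float).shape, self.lf0_)
        return led_curve(t, self.lf0_, self.lfp_, self.d0_, self.dr_)


class FourParamLogistic(BaseEstimator):
    """Four-parameter logistic dose-response model on the log10-dose scale.

    Vehicle wells (dose 0) are excluded from the log-dose regression but,
    when present, anchor the zero-dose plateau ``FV0`` via the initial
    guess. Works for FV, RV or GR response series.

    Attributes
    ----------
    fv0_, ecmax_, ec50_, hillslope_ : float
        Zero-dose plateau, saturating-dose plateau, log10-dose of half
        effect, and slope.
    rss_ : float
        Residual sum of squares.
    degenerate_ : bool
        True when the response is flat; ``hillslope_`` is then pinned to 0
        and ``ec50_`` is NaN.
    """

    def __init__(self, metric: str = "FV", flat_tol: float = 1e-6):
        self.metric = metric
        self.flat_tol = flat_tol

    def fit(self, doses, response):
        doses = np.asarray(doses, dtype=float)
        response = np.asarray(response, dtype=float)
        if doses.ndim == 2 and doses.shape[1] == 1:
            doses = doses.ravel()
        if doses.shape != response.shape or doses.ndim != 1:
            raise ValueError("doses and response must be 1-d arrays of equal length")
        pos = doses > 0
        if np.unique(doses[pos]).size < 5:
            raise ValueError("need at least 5 distinct positive doses")
        x = np.log10(doses[pos])
        y = response[pos]
        order = np.argsort(x)
        x, y = x[order], y[order]
        anchor0 = float(np.mean(response[~pos])) if np.any(~pos) else float(y[0])

        if np.ptp(response) < self.flat_tol:
            self.fv0_ = float(np.mean(response))
            self.ecmax_ = float(np.mean(response))
            self.ec50_ = float("nan")
            self.hillslope_ = 0.0
            self.rss_ = float(np.sum((response - np.mean(response)) ** 2))
            self.degenerate_ = True
            return self

        mid = 0.5 * (anchor0 + y[-1])
        ec50_init = float(x[np.argmin(np.abs(y - mid))])

        def resid(p):
            return logistic4(x, *p) - y

        best = None
        for slope in (0.3, 1.0, 3.0):
            x0 = np.array([anchor0, float(y[-1]), ec50_init, slope])
            sol = least_squares(resid, x0, method="lm", max_nfev=2000)
            if best is None or sol.cost < best.cost:
                best = sol
        sol = best
        if not sol.success and sol.cost > 1e-6 * max(1.0, float(np.sum(y**2))):
            err = RuntimeError(
                f"4PL fit did not converge (rss={2 * sol.cost:.3g})"
            )
            err.best_params = tuple(float(v) for v in sol.x)
            err.rss = float(2 * sol.cost)
            raise err
        self.fv0_, self.ecmax_, self.ec50_, self.hillslope_ = (float(v) for v in sol.x)
        self.rss_ = float(2 * sol.cost)
        self.degenerate_ = False
        return self

    def predict(self, doses):
        doses = np.asarray(doses, dtype=float)
        if self.degenerate_:
            return np.full(doses.shape, self.fv0_)
        return logistic4(np.log10(doses), self.fv0_, self.ecmax_, self.ec50_, self.hillslope_)

    def dose_at_half_effect(self) -> float:
        """Dose (linear scale) producing the half-maximal effect."""
        return float(10.0 ** self.ec50_)


def fit_led(times, lf) -> LEDCurve:
    """Fit the LED kinetic model; thin wrapper over :class:`LEDCurve`."""
    return LEDCurve().fit(times, lf)


def fit_dose_response(doses, response, metric: str = "FV") -> FourParamLogistic:
    """Fit a 4PL dose-response; thin wrapper over :class:`FourParamLogistic`."""
    return FourParamLogistic(metric=metric).fit(doses, response)


def analyze_plate(plate: pd.DataFrame, totals: pd.DataFrame,
                  background: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-well death metrics from long-format plate-reader tables.

    Parameters
    ----------
    plate : DataFrame
        Columns ``well, dose_um, time_h, dead_signal`` (one row per well
        per timepoint; all wells on a shared time grid).
    totals : DataFrame
        Columns ``well, total_signal_t0, total_signal_end`` from the lysed
        duplicate plates.
    background : DataFrame, optional
        Columns ``time_h, background`` (mean cell-free-well signal);
        subtracted from dead signals before any ratio.

    Returns a tidy frame with per-well, per-time ``total, live, LF, FV,
    RV, GR``; RV and GR reference the mean live signal of the vehicle
    (dose 0) wells.
    """
    required = {"well", "dose_um", "time_h", "dead_signal"}
    if not required.issubset(plate.columns):
        raise ValueError(f"plate table must have columns {sorted(required)}")
    if not {"well", "total_signal_t0", "total_signal_end"}.issubset(totals.columns):
        raise ValueError("totals table must have well,total_signal_t0,total_signal_end")
    plate = plate.copy()
    if background is not None:
        bg = background.set_index("time_h")["background"]
        plate["dead_signal"] = subtract_background(
            plate["dead_signal"].to_numpy(),
            plate["time_h"].map(bg).fillna(0.0).to_numpy(),
        )
    tot = totals.set_index("well")

    per_well = {}
    for well, grp in plate.groupby("well", sort=False):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"well {well!r}: time grid not strictly increasing")
        if well not in tot.index:
            raise ValueError(f"well {well!r} missing from totals table")
        total = infer_total_timecourse(
            tot.loc[well, "total_signal_t0"], tot.loc[well, "total_signal_end"],
            times, t_end=times[-1],
        )
        per_well[well] = grp.assign(total=total,
                                    live=np.clip(total - grp["dead_signal"], 0, None))

    vehicle = [w for w, g in per_well.items() if (g["dose_um"] == 0).all()]
    if vehicle:
        unt = pd.concat([per_well[w] for w in vehicle])
        unt_live = unt.groupby("time_h")["live"].mean()
        live_t0 = float(unt_live.iloc[0])
    else:
        warnings.warn("no vehicle (dose 0) wells: RV and GR unavailable", stacklevel=2)
        unt_live = live_t0 = None

    out = []
    for well, grp in per_well.items():
        if unt_live is not None:
            ref = grp["time_h"].map(unt_live).to_numpy()
            metrics = compute_metrics(grp["dead_signal"].to_numpy(),
                                      grp["total"].to_numpy(), ref, live_t0)
        else:
            metrics = compute_metrics(grp["dead_signal"].to_numpy(),
                                      grp["total"].to_numpy(),
                                      np.full(len(grp), np.nan), np.nan)
        out.append(pd.concat([grp.reset_index(drop=True),
                              metrics.drop(columns="live").reset_index(drop=True)],
                             axis=1))
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class GradeResult:
    """GRADE coordination score between growth inhibition and death.

    ``grade = arctan(m_drug) / arctan(m_max)``: 1 when death is maximally
    coupled to growth inhibition over the observed GR range, 0 when no
    death accompanies growth inhibition.
    """

    m_drug: float
    m_max: float
    grade: float
    n_doses_used: int
    basal_lf: float
    undefined: bool = False


def compute_grade(gr, fv, basal_lf: float = 0.0) -> GradeResult:
    """Compute GRADE from paired per-dose (GR, FV) measurements.

    FV is first normalized for basal (vehicle) death:
    ``LF_norm = max(0, (LF - basal_LF) / (1 - basal_LF))``,
    ``FV_norm = 1 - LF_norm``, which pins untreated wells to FV_norm = 1.
    Doses with GR >= 0 are fit to a line, giving the observed slope
    ``m_drug``; the maximum observable slope over the same GR range is that
    of the line through (GR=1, FV_norm=1) and (GR_min, FV_norm=0),
    ``m_max = 1 / (1 - GR_min)``. GRADE is the ratio of the two slope
    angles and is invariant to any common positive gain on the raw
    fluorescence because GR and FV are themselves ratios.
    """
    gr = np.asarray(gr, dtype=float)
    fv = np.asarray(fv, dtype=float)
    if gr.shape != fv.shape or gr.ndim != 1:
        raise ValueError("gr and fv must be 1-d arrays of equal length")
    if not 0.0 <= basal_lf < 1.0:
        raise ValueError(f"basal_lf must be in [0, 1), got {basal_lf}")
    lf = 1.0 - fv
    lf_norm = np.clip((lf - basal_lf) / (1.0 - basal_lf), 0.0, None)
    fv_norm = 1.0 - lf_norm
    mask = gr >= 0
    n_used = int(np.sum(mask))
    if n_used < 2:
        warnings.warn("fewer than 2 doses with GR >= 0; GRADE undefined", stacklevel=2)
        return GradeResult(float("nan"), float("nan"), float("nan"),
                           n_used, basal_lf, undefined=True)
    gr_u, fv_u = gr[mask], fv_norm[mask]
    m_drug = float(np.polyfit(gr_u, fv_u, 1)[0])
    gr_min = float(np.min(gr_u))
    if gr_min >= 1.0:
        raise ValueError("all GR values at 1: no growth inhibition observed")
    m_max = 1.0 / (1.0 - gr_min)
    grade = float(np.arctan(m_drug) / np.arctan(m_max))
    return GradeResult(m_drug=m_drug, m_max=m_max, grade=grade,
                       n_doses_used=n_used, basal_lf=basal_lf)
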