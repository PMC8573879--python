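"""Non-compartmental pulse-tracer kinetics.

After an IV pulse of a stable tracer, the plasma tracer-to-tracee ratio
(TTR) decays as a sum of exponentials,

    TTR(t) = a1 * exp(-k1 t) + a2 * exp(-k2 t) [+ a3 * exp(-k3 t)],

with amplitudes in TTR units and rate constants per hour (k1 > k2 > k3).
Whole-body production (WBP, umol/h) is the pulse dose divided by the area
under the fitted curve between 10 and 120 min; clearance (L/h) is WBP
divided by plasma concentration; conversion fluxes between amino acids
(e.g. Phe -> Tyr hydroxylation) scale the product's WBP by the ratio of the
secondary-tracer AUC to the substrate-tracer AUC.

Times cross the API in minutes (the sampling protocol's unit); rates and
AUCs are carried per hour internally so that WBP comes out in umol/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InputError, ModelError

__all__ = [
    "TTRSeries", "ExponentialFit", "KineticRates",
    "fit_exponential_decay", "select_exponential_model", "auc_fitted",
    "compute_wbp", "compute_clearance", "compute_conversion", "fit_cohort",
]

#: AUC integration window (min) for WBP, fixed by the pulse protocol
AUC_WINDOW_MIN: tuple[float, float] = (10.0, 120.0)

_MIN_POINTS = {2: 4, 3: 6}


@dataclass
class TTRSeries:
    """One tracer's TTR decay curve for one subject."""

    subject_id: str
    tracer: str
    times_min: np.ndarray
    ttr: np.ndarray
    dose_umol: float = np.nan

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.ttr = np.asarray(self.ttr, dtype=float)
        if self.times_min.ndim != 1 or self.times_min.shape != self.ttr.shape:
            raise InputError("times and ttr must be 1-D arrays of equal "
                             "length")
        if np.any(np.diff(self.times_min) <= 0):
            raise InputError(
                f"times must be strictly increasing "
                f"(subject {self.subject_id}, tracer {self.tracer})")
        if np.any(self.times_min <= 0):
            raise InputError("times must be > 0 (post-pulse sampling)")
        if not np.all(np.isfinite(self.ttr)):
            raise InputError("TTR values must be finite")

    @property
    def n(self) -> int:
        return self.times_min.size


@dataclass
class ExponentialFit:
    """Multi-exponential decay fit, parameters sorted by descending rate."""

    order: int
    amplitudes: np.ndarray        # TTR units, aligned with ``rates_per_h``
    rates_per_h: np.ndarray       # strictly decreasing
    sse: float
    aicc: float
    converged: bool

    def predict(self, times_min: np.ndarray) -> np.ndarray:
        t_h = np.asarray(times_min, dtype=float) / 60.0
        return np.sum(
            self.amplitudes[:, None]
            * np.exp(-self.rates_per_h[:, None] * t_h[None, :]), axis=0)

    def is_valid(self, rate_sep: float = 1.02) -> bool:
        """Invariant check: positive amplitudes, positive well-separated
        rates in strictly decreasing order."""
        a, k = self.amplitudes, self.rates_per_h
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(k))):
            return False
        if np.any(a <= 0) or np.any(k <= 0):
            return False
        # amplitudes collapsed to the optimizer floor are degenerate
        if np.any(a < 1e-9 * np.max(a)):
            return False
        return bool(np.all(k[:-1] >= rate_sep * k[1:]))


@dataclass
class KineticRates:
    """Per-subject, per-amino-acid kinetic summary."""

    subject_id: str
    amino_acid: str
    wbp_umol_h: float
    auc_ttr_h: float
    clearance_l_h: float = np.nan
    conversions: dict = field(default_factory=dict)


def _model(t_h, amps, rates):
    return np.sum(amps[:, None] * np.exp(-rates[:, None] * t_h[None, :]),
                  axis=0)


def _peel_initial_guess(t_h: np.ndarray, y: np.ndarray, order: int):
    """Curve-peeling start values: log-linear fit of the tail gives the
    slowest phase; subtract and repeat on what remains.

    Rates are clamped to the window the sampling design can identify
    (roughly 3 rate doublings before the first sample) so a steep curve
    cannot launch the optimizer from an absurd corner.
    """
    k_max = 5.0 / t_h[0]          # decayed ~e^-5 by the first sample
    amps, rates = [], []
    resid = y.copy()
    prev_k = None
    for phase in range(order):
        last = phase == order - 1
        pos = resid > 0
        if pos.sum() >= 2:
            tt, yy = t_h[pos], resid[pos]
            take = len(tt) if last else max(2, len(tt) // 2)
            tt, yy = tt[-take:], yy[-take:]
            slope, intercept = np.polyfit(tt, np.log(yy), 1)
            k = float(np.clip(-slope, 1e-3, k_max))
            a = float(np.clip(np.exp(intercept), 1e-12,
                              10.0 * np.max(y) * np.exp(k * t_h[0])))
        else:
            k = min((prev_k or 1.0) * 4.0, k_max)
            a = max(float(np.max(y)) / order, 1e-12)
        if prev_k is not None and k <= prev_k:
            k = min(prev_k * 4.0, k_max * 2.0)
        amps.append(a)
        rates.append(k)
        prev_k = k
        resid = resid - a * np.exp(-k * t_h)
    # peeled slow-to-fast; return fast-to-slow
    return np.array(amps[::-1]), np.array(rates[::-1])


def _grid_starts(t_h: np.ndarray, y: np.ndarray, order: int):
    """Deterministic fallback starts: fixed rate patterns scaled to the
    sampling window, with amplitudes from non-negative linear least
    squares (the model is linear in the amplitudes given the rates)."""
    from scipy.optimize import nnls
    span = t_h[-1] - t_h[0]
    if order == 2:
        patterns = [(6.0, 0.6), (3.0, 0.35), (12.0, 1.2), (1.5, 0.2)]
    else:
        patterns = [(12.0, 2.0, 0.3), (8.0, 1.2, 0.2), (20.0, 4.0, 0.5)]
    starts = []
    for pat in patterns:
        k = np.array(pat) * (2.0 / span)
        A = np.exp(-t_h[:, None] * k[None, :])
        a, _ = nnls(A, y)
        starts.append((np.maximum(a, 1e-10 * max(np.max(y), 1e-12)), k))
    return starts


def _aicc(n: int, n_params: int, sse: float, y: np.ndarray) -> float:
    # SSE floor keeps noiseless (machine-zero residual) comparisons stable
    floor = n * (1e-12 * max(float(np.max(np.abs(y))), 1e-300)) ** 2
    sse = max(sse, floor)
    if n - n_params - 1 <= 0:
        return np.inf
    return (n * np.log(sse / n) + 2 * n_params
            + 2 * n_params * (n_params + 1) / (n - n_params - 1))


def fit_exponential_decay(series: TTRSeries, order: int = 2,
                          weighted: bool = False) -> ExponentialFit:
    """Least-squares fit of an ``order``-exponential decay to a TTR series.

    Initialization is by curve peeling; optimization is bounded below zero
    so non-negativity is built in rather than clipped afterwards.  If the
    optimizer fails, the best-effort parameters are returned with
    ``converged=False``.

    Parameters
    ----------
    series : TTRSeries
    order : {2, 3}
    weighted : bool
        If true, residuals are weighted by 1/observed TTR (relative error);
        default is unweighted least squares.
    """
    if order not in _MIN_POINTS:
        raise InputError(f"order must be 2 or 3, got {order}")
    if series.n < _MIN_POINTS[order]:
        raise InputError(
            f"order-{order} fit needs >= {_MIN_POINTS[order]} points, "
            f"series has {series.n}")
    y = series.ttr
    if np.all(y <= 0):
        raise InputError("TTR series is all non-positive; nothing to fit")
    t_h = series.times_min / 60.0

    w = 1.0 / np.maximum(y, 1e-6 * np.max(y)) if weighted else None

    def resid(x):
        r = _model(t_h, x[:order], x[order:]) - y
        return r * w if w is not None else r

    lb = np.full(2 * order, 1e-12)
    ub = np.full(2 * order, np.inf)
    starts = [_peel_initial_guess(t_h, np.maximum(y, 1e-12), order)]
    starts += _grid_starts(t_h, y, order)
    # residual floor at which further starts cannot improve meaningfully
    floor = 1e-20 * float(np.sum(y ** 2))
    best_x, best_cost, success = None, np.inf, False
    for a0, k0 in starts:
        x0 = np.maximum(np.concatenate([a0, k0]), 1e-10)
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                                xtol=1e-13, ftol=1e-13, gtol=1e-13,
                                max_nfev=1000)
        except Exception:
            continue
        if sol.cost < best_cost:
            best_x, best_cost = sol.x, sol.cost
            success = bool(sol.success)
        if best_cost <= floor:
            break
    if best_x is None:
        best_x, success = np.maximum(
            np.concatenate(starts[0]), 1e-10), False

    amps, rates = best_x[:order], best_x[order:]
    idx = np.argsort(rates)[::-1]
    amps, rates = amps[idx], rates[idx]
    sse = float(np.sum((_model(t_h, amps, rates) - y) ** 2))
    return ExponentialFit(order=order, amplitudes=amps, rates_per_h=rates,
                          sse=sse, aicc=_aicc(series.n, 2 * order, sse, y),
                          converged=success)


def select_exponential_model(series: TTRSeries,
                             weighted: bool = False) -> ExponentialFit:
    """Fit order 2 always; additionally try order 3 when the series has at
    least 6 points, and keep whichever has the lower AICc.

    An order-3 fit that fails to converge or violates the parameter
    invariants (positive amplitudes, strictly ordered positive rates) falls
    back to order 2; so do ties.
    """
    fit2 = fit_exponential_decay(series, order=2, weighted=weighted)
    if series.n < _MIN_POINTS[3]:
        return fit2
    try:
        fit3 = fit_exponential_decay(series, order=3, weighted=weighted)
    except InputError:
        return fit2
    if not (fit3.converged and fit3.is_valid()):
        return fit2
    return fit3 if fit3.aicc < fit2.aicc else fit2


def auc_fitted(fit: ExponentialFit,
               t_start_min: float = AUC_WINDOW_MIN[0],
               t_end_min: float = AUC_WINDOW_MIN[1]) -> float:
    """Analytic area under the fitted TTR curve (TTR*h) over the window.

    AUC = sum_i (a_i / k_i) (exp(-k_i t0) - exp(-k_i t1)), times in hours;
    ``t_end_min`` may be ``inf`` for the total-area variant.
    """
    if not t_start_min < t_end_min:
        raise InputError("AUC window must satisfy t_start < t_end")
    k = np.asarray(fit.rates_per_h, dtype=float)
    a = np.asarray(fit.amplitudes, dtype=float)
    if np.any(k <= 0):
        raise ModelError("degenerate fit: non-positive rate constant")
    t0, t1 = t_start_min / 60.0, t_end_min / 60.0
    upper = 0.0 if np.isinf(t1) else np.exp(-k * t1)
    auc = float(np.sum(a / k * (np.exp(-k * t0) - upper)))
    if auc <= 0:
        raise ModelError("AUC must be strictly positive")
    return auc


def compute_wbp(dose_umol: float, auc_ttr_h: float) -> float:
    """Whole-body production rate: pulse dose / AUC (umol/h)."""
    if dose_umol <= 0 or auc_ttr_h <= 0:
        raise InputError("dose and AUC must be > 0")
    return dose_umol / auc_ttr_h


def compute_clearance(wbp_umol_h: float, concentration_umol_l: float) -> float:
    """Plasma clearance: WBP / plasma concentration (L/h)."""
    if wbp_umol_h <= 0 or concentration_umol_l <= 0:
        raise InputError("WBP and concentration must be > 0")
    return wbp_umol_h / concentration_umol_l


def compute_conversion(wbp_product_umol_h: float,
                       auc_product_from_substrate: float,
                       auc_substrate: float) -> float:
    """Conversion flux substrate -> product (umol/h).

    Scales the product amino acid's WBP by the ratio of the AUC of the
    product tracer appearing after the substrate pulse to the AUC of the
    substrate's own tracer.
    """
    if wbp_product_umol_h <= 0:
        raise InputError("product WBP must be > 0")
    if auc_product_from_substrate < 0 or auc_substrate <= 0:
        raise InputError("AUCs must be positive (substrate strictly)")
    return wbp_product_umol_h * auc_product_from_substrate / auc_substrate


def _series_from_long(ttr_long: pd.DataFrame, doses: dict[str, float]):
    for (sid, tracer), grp in ttr_long.groupby(["subject_id", "tracer"],
                                               sort=True):
        grp = grp.sort_values("time_min")
        yield TTRSeries(subject_id=str(sid), tracer=str(tracer),
                        times_min=grp["time_min"].to_numpy(),
                        ttr=grp["ttr"].to_numpy(),
                        dose_umol=doses.get(str(tracer), np.nan))


def fit_cohort(ttr_long: pd.DataFrame, doses: pd.DataFrame,
               concentrations: pd.DataFrame | None = None,
               weighted: bool = False
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every TTR series of a cohort and assemble kinetic endpoints.

    Parameters
    ----------
    ttr_long : DataFrame with columns subject_id, tracer, time_min, ttr.
        Primary tracers are named by amino acid ("Phe"); secondary
        (conversion) series as "product<-substrate" ("Tyr<-Phe").
    doses : DataFrame with columns tracer, dose_umol.
    concentrations : optional DataFrame indexed by subject_id with columns
        conc_<aa> (umol/L); enables clearance.

    Returns
    -------
    (kinetics, conversions) : per subject/amino-acid rates, and per
        subject/pair conversion fluxes.
    """
    dose_map = dict(zip(doses["tracer"].astype(str),
                        doses["dose_umol"].astype(float)))
    fits: dict[tuple[str, str], tuple[ExponentialFit, float]] = {}
    rows = []
    for series in _series_from_long(ttr_long, dose_map):
        fit = select_exponential_model(series, weighted=weighted)
        auc = auc_fitted(fit)
        fits[(series.subject_id, series.tracer)] = (fit, auc)
        if "<-" in series.tracer:
            continue
        wbp = compute_wbp(series.dose_umol, auc)
        clearance = np.nan
        if concentrations is not None:
            col = f"conc_{series.tracer}"
            if (series.subject_id in concentrations.index
                    and col in concentrations.columns):
                conc = float(concentrations.loc[series.subject_id, col])
                if conc > 0:
                    clearance = compute_clearance(wbp, conc)
        rows.append({"subject_id": series.subject_id,
                     "amino_acid": series.tracer,
                     "order": fit.order,
                     "wbp_umol_h": wbp,
                     "auc_ttr_h": auc,
                     "clearance_l_h": clearance,
                     "converged": fit.converged})
    kinetics = pd.DataFrame(rows)

    conv_rows = []
    for (sid, tracer), (fit, auc_sec) in fits.items():
        if "<-" not in tracer:
            continue
        product, substrate = tracer.split("<-")
        sub = fits.get((sid, substrate))
        if sub is None or kinetics.empty:
            continue
        mask = ((kinetics["subject_id"] == sid)
                & (kinetics["amino_acid"] == product))
        if not mask.any():
            continue
        wbp_product = float(kinetics.loc[mask, "wbp_umol_h"].iloc[0])
        rate = compute_conversion(wbp_product, auc_sec, sub[1])
        conv_rows.append({"subject_id": sid, "substrate": substrate,
                          "product": product, "rate_umol_h": rate})
    conversions = pd.DataFrame(
        conv_rows, columns=["subject_id", "substrate", "product",
                            "rate_umol_h"])
    return kinetics, conversions
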