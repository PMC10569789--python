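"""Macroscopic relaxation analysis.

After ATP removal no channel can reopen, so the macroscopic current decays as
bursting channels terminally close; for non-hydrolytic mutants (``k_1 = 0``)
the ensemble mean is a single exponential with time constant ``tau_b =
1 / k_minus1``.  Currents are normalized to their steady-state value just
before removal and fitted with ``A * exp(-(t - t_off) / tau)`` with the
offset fixed at zero; ``1 / tau`` estimates the non-hydrolytic closing rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .synth import CurrentTrace

__all__ = [
    "RelaxationFit",
    "normalize_steady_state",
    "fit_single_exponential",
    "aggregate_replicates",
]

#: slope-based step rise time of a Gaussian filter with cutoff fc,
#: sqrt(2 pi) * sigma_t = 0.3321/fc (the 10-90% rise is ~2% longer).
RISE_TIME_COEF = 0.3321


@dataclass(frozen=True)
class RelaxationFit:
    """Single-exponential fit result (or replicate aggregate when n > 1).

    ``sem_tau`` is the standard error of ``tau``: across replicates for
    aggregates; for a single ensemble fit it derives from the number of
    observed channel closures when ``fit_single_exponential`` was told the
    ensemble size (see there), else from the least-squares covariance.
    """

    tau: float
    amplitude: float
    resid_rms: float
    t_fit: tuple[float, float]
    n: int = 1
    sem_tau: float = float("nan")

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"fitted time constant must be positive, got {self.tau}")

    @property
    def rate(self) -> float:
        """Closing rate 1/tau (1/s)."""
        return 1.0 / self.tau

    def rate_ci95(self) -> tuple[float, float]:
        """95% interval for the closing rate.

        Uses a normal interval on ``log tau`` (rates and time constants are
        scale parameters); for replicate aggregates a t quantile with
        ``n - 1`` degrees of freedom replaces 1.96.
        """
        if not math.isfinite(self.sem_tau):
            raise ValueError("fit carries no tau uncertainty")
        q = stats.t.ppf(0.975, self.n - 1) if self.n > 1 else 1.959963984540054
        half = q * self.sem_tau / self.tau  # relative, symmetric on log scale
        return (self.rate * math.exp(-half), self.rate * math.exp(half))


def normalize_steady_state(
    trace: CurrentTrace, t_atp_off: float | None = None, window: float = 2.0
) -> CurrentTrace:
    """Divide a trace by its mean current over the pre-removal window.

    The window is the ``window`` seconds immediately preceding ``t_atp_off``;
    the normalized current just before removal is ~1 and the sign convention
    drops out.  Errors out when the steady-state mean is indistinguishable
    from zero (|mean| < 5 standard errors of the window samples).
    """
    if t_atp_off is None:
        t_atp_off = trace.markers.get("t_atp_off")
    if t_atp_off is None:
        raise ValueError("trace carries no t_atp_off marker")
    if window <= 0 or window > t_atp_off - trace.t0:
        raise ValueError("normalization window must lie within (0, t_atp_off)")
    t = trace.times
    mask = (t >= t_atp_off - window) & (t < t_atp_off)
    seg = trace.samples[mask]
    mean = seg.mean()
    se = seg.std(ddof=1) / math.sqrt(len(seg)) if len(seg) > 1 else 0.0
    if abs(mean) < 5 * se:
        raise ValueError(
            f"steady-state current ({mean:.3g} pA) not resolvable above noise; "
            "cannot normalize")
    meta = dict(trace.meta)
    meta["normalized"] = True
    meta["steady_state_pA"] = float(mean)
    return CurrentTrace(trace.t0, trace.fs, trace.samples / mean,
                        markers=dict(trace.markers), meta=meta)


def _initial_guesses(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    a0 = float(y[0]) if y[0] > 0 else max(float(np.max(y)), 1e-6)
    below = np.nonzero(y <= a0 / math.e)[0]
    tau0 = float(t[below[0]] - t[0]) if len(below) else float(t[-1] - t[0])
    if tau0 <= 0:
        tau0 = float(t[-1] - t[0]) or 1.0
    return a0, tau0


def fit_single_exponential(
    trace: CurrentTrace,
    t_atp_off: float | None = None,
    *,
    ensemble_size: int | None = None,
) -> RelaxationFit:
    """Least-squares fit of ``A * exp(-(t - t_off) / tau)`` with zero offset.

    The fitted window starts two filter rise times after ``t_atp_off`` (to
    skip the solution-exchange/filter transient) and runs to the end of the
    record.  If the record outlasts five initial-guess time constants, the
    median of the post-decay plateau is subtracted first (residual leak).  A
    ``UserWarning`` is emitted when the record covers fewer than three fitted
    time constants (the estimate is then poorly constrained).

    Uncertainty: the residuals of an ensemble relaxation are a correlated
    survival path, so the plain least-squares covariance wildly understates
    the error.  When ``ensemble_size`` (number of channels in the patch) is
    given, ``sem_tau`` instead comes from exponential-lifetime counting
    statistics, ``tau / sqrt(n_closed)``, with ``n_closed`` the estimated
    number of closures observed in the fitted window.  Without it the
    least-squares value is reported and is only meaningful for noise-shaped
    (uncorrelated) residuals.
    """
    if t_atp_off is None:
        t_atp_off = trace.markers.get("t_atp_off")
    if t_atp_off is None:
        raise ValueError("trace carries no t_atp_off marker")
    f_acq = trace.meta.get("f_acq")
    t_start = t_atp_off + (2 * RISE_TIME_COEF / f_acq if f_acq else 0.0)
    t = trace.times
    mask = t >= t_start
    if mask.sum() < 10:
        raise ValueError("fewer than 10 samples after the fit window start")
    tf = t[mask]
    yf = trace.samples[mask].copy()
    if np.nanmean(yf[: max(1, len(yf) // 100)]) < 0:
        yf = -yf  # tolerate unnormalized negative-going traces

    a0, tau0 = _initial_guesses(tf, yf)
    # leak handling: subtract the post-decay plateau when clearly reached
    plateau = 0.0
    if tf[-1] - t_atp_off > 5 * tau0:
        tail = yf[tf > t_atp_off + 5 * tau0]
        if len(tail) >= 10:
            plateau = float(np.median(tail))
            yf = yf - plateau

    def model(tt, a, tau):
        return a * np.exp(-(tt - t_atp_off) / tau)

    popt = None
    last_err: Exception | None = None
    for scale in (1.0, 0.1, 10.0):
        try:
            popt, pcov = optimize.curve_fit(
                model, tf, yf, p0=(a0, tau0 * scale),
                bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000)
            break
        except (RuntimeError, ValueError) as err:  # pragma: no cover - fallback
            last_err = err
    if popt is None:
        raise RuntimeError(
            f"exponential fit failed (initial A={a0:.3g}, tau={tau0:.3g}, "
            f"{len(tf)} samples spanning {tf[-1] - tf[0]:.3g} s): {last_err}")
    a_fit, tau_fit = float(popt[0]), float(popt[1])
    if tau_fit <= 0:
        raise RuntimeError(f"non-physical fitted time constant {tau_fit}")
    resid = yf - model(tf, *popt)
    resid_rms = float(np.sqrt(np.mean(resid**2)))
    if tf[-1] - t_atp_off < 3 * tau_fit:
        warnings.warn(
            f"record spans only {(tf[-1] - t_atp_off) / tau_fit:.2f} fitted "
            "time constants; tau is poorly constrained", stacklevel=2)

    if ensemble_size is not None:
        frac_closed = 1.0 - math.exp(-(tf[-1] - t_atp_off) / tau_fit)
        n_closed = max(1.0, ensemble_size * min(a_fit, 1.0) * frac_closed)
        sem_tau = tau_fit / math.sqrt(n_closed)
    else:
        sem_tau = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")

    return RelaxationFit(
        tau=tau_fit, amplitude=a_fit, resid_rms=resid_rms,
        t_fit=(float(tf[0]), float(tf[-1])), n=1, sem_tau=sem_tau)


def aggregate_replicates(fits: list[RelaxationFit]) -> RelaxationFit:
    """Mean tau with SEM = sd / sqrt(n) over replicate experiments."""
    if len(fits) < 2:
        raise ValueError(f"need >= 2 replicate fits, got {len(fits)}")
    taus = np.array([f.tau for f in fits])
    amps = np.array([f.amplitude for f in fits])
    return RelaxationFit(
        tau=float(taus.mean()),
        amplitude=float(amps.mean()),
        resid_rms=float(np.mean([f.resid_rms for f in fits])),
        t_fit=fits[0].t_fit,
        n=len(fits),
        sem_tau=float(taus.std(ddof=1) / math.sqrt(len(taus))),
    )
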