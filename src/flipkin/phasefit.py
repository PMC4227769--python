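"""Extraction of observed rate constants from traces and series.

Sums of exponentials are notoriously ill-conditioned, so the
multi-exponential fitter combines two standard defences: variable
projection (for any trial rate vector the offset and amplitudes are solved
exactly by linear least squares, leaving only the rates to the nonlinear
optimizer) and a log-spaced multistart over the rate grid (8 starts per
phase count, best residual wins).  Rates are optimized in log space and
reported sorted descending; near-degenerate rate pairs (within 5%) are
merged and flagged rather than reported as distinct phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy import stats

from .mechanism import FlipKinError, ValidationError

__all__ = [
    "FitFailureError",
    "PhaseFit",
    "ConcentrationSeries",
    "fit_exponential_phases",
    "assign_binding_phases",
    "fit_bimolecular_slope",
    "classify_concentration_dependence",
    "fit_quadratic_binding",
    "fit_ic50",
    "fit_single_turnover",
]


class FitFailureError(FlipKinError, RuntimeError):
    """Nonlinear fit failed to converge after multistart."""


#: relative separation below which two fitted rates are considered one phase
MERGE_TOL = 0.05
N_STARTS = 8


@dataclass
class PhaseFit:
    """Result of an n-exponential fit y(t) = y_inf + sum_i A_i exp(-k_i t).

    Rates are sorted descending (k[0] = k_1,obs is the fastest phase).
    ``flags`` collects soft diagnostics such as 'merged-rates' or
    'rate-unidentifiable'.
    """

    y_inf: float
    amplitudes: np.ndarray
    rates: np.ndarray
    rms: float
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    flags: list = field(default_factory=list)

    @property
    def n_phases(self) -> int:
        return len(self.rates)

    def phase(self, i: int) -> tuple:
        """(amplitude, rate) of phase i (1-based, fastest first)."""
        return float(self.amplitudes[i - 1]), float(self.rates[i - 1])

    def to_dict(self) -> dict:
        return {
            "y_inf": float(self.y_inf),
            "amplitudes": [float(a) for a in self.amplitudes],
            "rates": [float(k) for k in self.rates],
            "rms": float(self.rms),
            "stderr": {k: float(v) for k, v in self.stderr.items()},
            "converged": bool(self.converged),
            "flags": list(self.flags),
        }


def _design(t: np.ndarray, rates: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore", under="ignore"):
        return np.column_stack([np.ones_like(t)] +
                               [np.exp(-k * t) for k in rates])


def _varpro_residual(logk: np.ndarray, t: np.ndarray, y: np.ndarray):
    X = _design(t, np.exp(np.minimum(logk, 700.0)))
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef, coef


def fit_exponential_phases(times, signal, n_phases: int,
                           n_starts: int = N_STARTS) -> PhaseFit:
    """Least-squares n-exponential fit (n = 1..3) of a trace.

    Requires at least 5 points per phase.  Degenerate fits are not reported
    silently: rates closer than 5% are merged and flagged, and a fit whose
    amplitude is indistinguishable from zero is flagged rate-unidentifiable.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    if not 1 <= n_phases <= 3:
        raise ValidationError("n_phases must be 1, 2 or 3")
    if t.size != y.size or t.size < 5 * n_phases:
        raise ValidationError(
            f"need >= {5 * n_phases} points for a {n_phases}-phase fit")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("trace times must be strictly increasing")

    span = t[-1] - t[0]
    dt = max(np.min(np.diff(t)), 1e-12)
    # flat trace: rates are unidentifiable, report zero amplitude
    if np.ptp(y) <= 1e-12 * max(1.0, np.max(np.abs(y))):
        return PhaseFit(y_inf=float(np.mean(y)),
                        amplitudes=np.zeros(n_phases),
                        rates=np.full(n_phases, 1.0 / span),
                        rms=float(np.std(y)), converged=True,
                        flags=["rate-unidentifiable"])

    k_lo, k_hi = 0.2 / span, 2.0 / dt
    best = None
    rng_starts = np.geomspace(k_lo, k_hi, n_starts)
    for k0 in rng_starts:
        # spread the n starting rates around k0, one decade apart
        ks = k0 * (10.0 ** np.arange(n_phases))
        ks = np.clip(ks, k_lo / 10, k_hi * 10)
        x0 = np.log(ks)
        try:
            res = least_squares(lambda x: _varpro_residual(x, t, y)[0], x0,
                                method="lm" if n_phases > 0 else "trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError(
            f"{n_phases}-phase fit failed for all {n_starts} starts")

    rates = np.exp(best.x)
    _, coef = _varpro_residual(best.x, t, y)
    order = np.argsort(rates)[::-1]
    rates = rates[order]
    amps = coef[1:][order]
    y_inf = coef[0]
    resid = y - _design(t, rates) @ np.concatenate([[y_inf], amps])
    rms = float(np.sqrt(np.mean(resid ** 2)))

    flags = []
    for i in range(len(rates) - 1):
        if rates[i + 1] > 0 and rates[i] / rates[i + 1] - 1.0 < MERGE_TOL:
            flags.append("merged-rates")
            break
    if np.max(np.abs(amps)) <= 10 * max(rms, 1e-14):
        flags.append("rate-unidentifiable")

    stderr = _phase_stderr(t, y, y_inf, amps, rates, rms)
    return PhaseFit(y_inf=float(y_inf), amplitudes=amps, rates=rates,
                    rms=rms, stderr=stderr,
                    converged=bool(best.status > 0), flags=flags)


def _phase_stderr(t, y, y_inf, amps, rates, rms) -> dict:
    """Asymptotic standard errors from the full (offset+amps+rates) jacobian."""
    n = len(rates)
    cols = [np.ones_like(t)]
    for i in range(n):
        cols.append(np.exp(-rates[i] * t))
    for i in range(n):
        cols.append(-amps[i] * t * np.exp(-rates[i] * t))
    J = np.column_stack(cols)
    dof = max(len(t) - J.shape[1], 1)
    s2 = np.sum((y - cols[0] * y_inf -
                 sum(a * c for a, c in zip(amps, cols[1:n + 1]))) ** 2) / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(J.shape[1], np.nan)
    out = {"y_inf": se[0]}
    for i in range(n):
        out[f"A_{i + 1}"] = se[1 + i]
        out[f"k_{i + 1}"] = se[1 + n + i]
    return out


def assign_binding_phases(fit: PhaseFit) -> dict:
    """Label fitted phases as the binding rise and the flipping quench.

    In y = y_inf + sum A_i exp(-k_i t) a rise has negative amplitude and a
    quench positive.  The principal rise (largest |A| among negative-
    amplitude phases) is the binding/searching phase (k_1,obs); the largest
    positive-amplitude phase slower than it is the flipping phase
    (k_2,obs).  Traces whose fast phases completed within the dead time
    show no rise, in which case the dominant phase is the flipping quench.
    """
    amps, rates = fit.amplitudes, fit.rates
    rise = [(abs(a), k) for a, k in zip(amps, rates) if a < 0]
    k1 = max(rise)[1] if rise else None
    quench = [(abs(a), k) for a, k in zip(amps, rates)
              if a > 0 and (k1 is None or k < k1)]
    k2 = max(quench)[1] if quench else None
    if k1 is None and k2 is None and len(rates):
        k2 = rates[int(np.argmax(np.abs(amps)))]
    return {"k1_obs": k1, "k2_obs": k2}


# ---------------------------------------------------------------------------
# Concentration-series analysis
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationSeries:
    """Observed rates versus concentration in one mixing regime."""

    concentrations: np.ndarray
    rates: np.ndarray
    sd: np.ndarray = None
    regime: str = "excess-protein"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.size != self.rates.size:
                raise ValidationError("sd length must match rates")
        if self.concentrations.size != self.rates.size:
            raise ValidationError("concentration/rate lengths differ")
        if self.concentrations.size < 3:
            raise ValidationError("need >= 3 points for slope analysis")


def _wls_line(x, y, w):
    """Weighted least-squares line fit; returns slope, intercept and their
    standard errors plus residual dof."""
    W = np.diag(w)
    X = np.column_stack([x, np.ones_like(x)])
    A = X.T @ W @ X
    beta = np.linalg.solve(A, X.T @ W @ y)
    resid = y - X @ beta
    dof = len(x) - 2
    if dof > 0:
        s2 = (resid * w * resid).sum() / dof
        cov = s2 * np.linalg.inv(A)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    else:
        se = np.full(2, np.nan)
    return beta[0], beta[1], se[0], se[1], dof


def fit_bimolecular_slope(series: ConcentrationSeries):
    """Linear fit of first-phase rates vs concentration: slope = k_on.

    The intercept is unconstrained; slightly negative intercepts are the
    signature of extremely fast, tight binding and are permitted.  Returns
    (k_on, intercept, slope_se, intercept_se).
    """
    if series.regime != "excess-protein":
        raise ValidationError(
            "bimolecular slope is defined for the excess-protein regime")
    x, y = series.concentrations, series.rates
    if np.ptp(x) == 0:
        raise ValidationError("singular design: all concentrations equal")
    w = (1.0 / np.clip(series.sd, 1e-300, None) ** 2
         if series.sd is not None and np.all(series.sd > 0)
         else np.ones_like(y))
    slope, intercept, se_s, se_i, _ = _wls_line(x, y, w)
    return float(slope), float(intercept), float(se_s), float(se_i)


def classify_concentration_dependence(series: ConcentrationSeries,
                                      alpha: float = 0.05) -> dict:
    """t-test of the slope: is the observed rate concentration dependent?

    If independent, the summary rate is the inverse-variance weighted mean
    (this is k_find for phase 1 in the excess-DNA regime, and the flipping
    rate for phase 2 in either regime).
    """
    x, y = series.concentrations, series.rates
    if series.sd is not None:
        if np.all(series.sd == 0):
            raise ValidationError("zero-variance inputs")
        w = 1.0 / np.clip(series.sd, 1e-300, None) ** 2
    else:
        w = np.ones_like(y)
    slope, intercept, se_s, _, dof = _wls_line(x, y, w)

    mean_rate = float(np.sum(w * y) / np.sum(w))
    # exact data: decide on the raw slope against numerical noise
    if not np.isfinite(se_s) or se_s == 0:
        dependent = abs(slope) * np.ptp(x) > 1e-9 * max(abs(mean_rate), 1e-30)
        p_value = 0.0 if dependent else 1.0
    else:
        t_stat = slope / se_s
        p_value = float(2 * stats.t.sf(abs(t_stat), dof))
        dependent = p_value < alpha
    out = {
        "classification": "dependent" if dependent else "independent",
        "slope": float(slope),
        "intercept": float(intercept),
        "p_value": p_value,
    }
    if not dependent:
        out["summary_rate"] = mean_rate
        out["summary_rate_se"] = (float(1.0 / np.sqrt(np.sum(w)))
                                  if series.sd is not None else
                                  float(np.std(y, ddof=1) / np.sqrt(len(y))))
    return out


# ---------------------------------------------------------------------------
# Titration, inhibition and gel fits
# ---------------------------------------------------------------------------

def fit_quadratic_binding(enzyme_series, signal, D_tot: float) -> dict:
    """Fit the tight-binding quadratic quench model to a titration curve.

    Model: F/F0 = 1 - (1 - 1/q) * bound_fraction(E; Kd, n, D_tot).
    Kd below D_tot/10 cannot be resolved by a titration at concentration
    D_tot and is flagged as an upper limit.
    """
    from .synth import tight_binding_fraction

    E = np.asarray(enzyme_series, dtype=float)
    y = np.asarray(signal, dtype=float)
    if E.size < 5:
        raise ValidationError("need >= 5 titration points")
    if np.ptp(y) < 1e-6:
        raise ValidationError("no curvature: titration is unidentifiable")

    def resid(x):
        logKd, n, q = x
        fb = tight_binding_fraction(E, np.exp(logKd), n, D_tot)
        return 1.0 - (1.0 - 1.0 / q) * fb - y

    best = None
    for kd0 in (D_tot / 100, D_tot / 10, D_tot, 10 * D_tot):
        res = least_squares(resid, [np.log(kd0), 1.0, 3.0],
                            bounds=([np.log(D_tot) - 25, 0.05, 1.0],
                                    [np.log(D_tot) + 25, 20.0, 1e3]),
                            xtol=1e-14, ftol=1e-14)
        if best is None or res.cost < best.cost:
            best = res
    Kd, n, q = np.exp(best.x[0]), best.x[1], best.x[2]
    return {
        "Kd": float(Kd),
        "n": float(n),
        "quench_factor": float(q),
        "Kd_is_upper_limit": bool(Kd < D_tot / 10),
        "rms": float(np.sqrt(np.mean(best.fun ** 2))),
    }


def fit_ic50(competitor_series, rates) -> dict:
    """Fit rate = r0 / (1 + [N]/IC50) to a competition series.

    Returns IC50 = inf (flagged) when the best fit puts IC50 above 10x the
    highest tested concentration — the uninhibited phenotype.
    """
    N = np.asarray(competitor_series, dtype=float)
    y = np.asarray(rates, dtype=float)
    finite = np.isfinite(N)
    if N.size < 4 or not np.any(N[finite] == 0):
        raise ValidationError(
            "need >= 4 competitor concentrations including 0")
    order = np.argsort(N[finite])
    dy = np.diff(y[finite][order])
    if np.any(dy > 3 * max(np.std(y) / np.sqrt(len(y)), 1e-12)):
        warnings.warn("competition series is non-monotonic beyond noise",
                      stacklevel=2)
    Nmax = np.max(N[finite])

    def resid(x):
        r0, log_ic50 = x
        pred = np.where(np.isinf(N), 0.0, r0 / (1.0 + N / np.exp(log_ic50)))
        return pred - y

    best = None
    for ic0 in np.geomspace(max(Nmax, 1e-9) / 100, max(Nmax, 1e-9) * 100, 5):
        res = least_squares(resid, [max(y.max(), 1e-6), np.log(ic0)],
                            xtol=1e-14, ftol=1e-14)
        if best is None or res.cost < best.cost:
            best = res
    ic50 = float(np.exp(best.x[1]))
    no_inhibition = ic50 > 10 * Nmax
    return {
        "IC50": float("inf") if no_inhibition else ic50,
        "r0": float(best.x[0]),
        "no_inhibition": bool(no_inhibition),
        "rms": float(np.sqrt(np.mean(best.fun ** 2))),
    }


def fit_single_turnover(times, fraction_product, endpoint_max: float = 1.05):
    """Exponential-approach fit of a gel time course.

    Model: frac = Y_inf (1 - exp(-k t)) with Y_inf <= endpoint_max.
    Returns a dict with k_obs (s^-1 if times are s), the endpoint and
    flags.  The saturation-control hook ``saturating(k_a, k_b)`` of the
    caller compares fits at two enzyme concentrations.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(fraction_product, dtype=float)
    if t.size < 5:
        raise ValidationError("need >= 5 gel time points")
    if np.ptp(y) <= 1e-12:
        return {"k_obs": np.nan, "endpoint": float(np.mean(y)),
                "flags": ["rate-unidentifiable"], "rms": 0.0}

    def resid(x):
        logk, yinf = x
        return yinf * (1.0 - np.exp(-np.exp(logk) * t)) - y

    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    best = None
    for k0 in np.geomspace(0.1 / span, 100.0 / span, N_STARTS):
        res = least_squares(resid, [np.log(k0), min(max(y.max(), 0.1), 1.0)],
                            bounds=([-np.inf, 0.0], [np.inf, endpoint_max]),
                            xtol=1e-14, ftol=1e-14)
        if best is None or res.cost < best.cost:
            best = res
    k = float(np.exp(best.x[0]))
    flags = []
    if best.x[1] * (1 - np.exp(-k * t[-1])) < 0.5 * best.x[1]:
        flags.append("plateau-not-reached")
    return {"k_obs": k, "endpoint": float(best.x[1]), "flags": flags,
            "rms": float(np.sqrt(np.mean(best.fun ** 2)))}
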