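"""The rate-inference chain for rapid-kinetics absorbance traces.

Implements the fitting workflow used to extract ligand rate constants
from stopped-flow and flash-photolysis time courses:

* multi-exponential decomposition with information-criterion phase-count
  selection (single vs double exponential, plus identifiability guards);
* hyperbolic trap-saturation fits returning the limiting k_off;
* second-order regression of k_obs against ligand concentration;
* classification of concentration dependence (distal-His gating makes
  binding rates concentration independent; bimolecular reactions are
  linear in ligand);
* dead-time censoring: reactions faster than the observable half-time
  yield lower bounds, never finite constants;
* equilibrium affinity constants and fold-change comparisons against the
  nitrite-reductase constants of reference globins.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit, least_squares

from .kinetics import Affinity, affinity_constants, round_sig
from .synth import TimeCourse

__all__ = [
    "ExpFitResult",
    "RateDetermination",
    "TrapFit",
    "Dependence",
    "NIR_REFERENCES",
    "fit_multiexponential",
    "fit_trap_saturation",
    "fit_second_order",
    "classify_dependence",
    "censored_bound",
    "compare_to_references",
    "observability_bound",
]

#: Published nitrite-reductase bimolecular constants (M^-1 s^-1) of
#: reference hemoglobins, used for fold-change context.
NIR_REFERENCES: Dict[str, float] = dict(
    MappingProxyType(
        {
            "SynHb": 68.0,
            "Arabidopsis_class1_Glb": 58.0,
            "rice_Glb": 83.0,
            "sperm_whale_myoglobin": 2.9,
            "human_neuroglobin": 0.25,
            "neuroglobin_HisD_mutant": 956.0,
        }
    )
)


class Dependence(str, enum.Enum):
    GATED_INDEPENDENT = "gated_independent"
    BIMOLECULAR_DEPENDENT = "bimolecular_dependent"
    INDETERMINATE = "indeterminate"


@dataclass
class ExpFitResult:
    """Result of a baseline + sum-of-exponentials fit.

    ``rates`` are sorted descending (fast phase first); amplitudes carry
    sign and refer to the first observable sample as time origin.
    ``selection_scores`` maps candidate phase counts to their corrected
    Akaike scores.
    """

    n_phases: int
    amplitudes: np.ndarray
    rates: np.ndarray
    amplitude_stderr: np.ndarray
    rate_stderr: np.ndarray
    baseline: float
    baseline_stderr: float
    objective: float
    selection_scores: Dict[int, float]
    converged: bool = True
    demoted_from: Optional[int] = None

    @property
    def total_amplitude(self) -> float:
        return float(np.sum(np.abs(self.amplitudes)))

    def predict(self, t: np.ndarray, t0: float = 0.0) -> np.ndarray:
        y = np.full_like(np.asarray(t, float), self.baseline)
        for a, k in zip(self.amplitudes, self.rates):
            y = y + a * np.exp(-k * (np.asarray(t, float) - t0))
        return y


@dataclass
class RateDetermination:
    """A second-order constant, a gating verdict, or a censored bound.

    Invariant: a censored determination never carries a finite
    ``second_order_k``; it reports ``lower_bound`` (s^-1) instead.
    """

    second_order_k: Optional[float] = None      # M^-1 s^-1
    second_order_stderr: Optional[float] = None
    intercept: Optional[float] = None           # s^-1
    intercept_stderr: Optional[float] = None
    slope_ci95: Optional[Tuple[float, float]] = None
    independence_verdict: Optional[Dependence] = None
    censored: bool = False
    lower_bound: Optional[float] = None         # s^-1
    details: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.censored and self.second_order_k is not None:
            raise ValueError(
                "a censored determination cannot carry a finite "
                "second-order constant"
            )


# ---------------------------------------------------------------------------
# multi-exponential fitting (variable projection + AICc selection)


def _aicc(ssr: float, n: int, p: int) -> float:
    ssr = max(ssr, 1e-300)
    score = n * math.log(ssr / n) + 2 * p
    if n - p - 1 > 0:
        score += 2 * p * (p + 1) / (n - p - 1)
    else:
        score = math.inf
    return score


def _varpro_fit(
    t: np.ndarray, y: np.ndarray, n_phases: int, starts: Sequence[np.ndarray]
) -> Tuple[np.ndarray, np.ndarray, float, bool]:
    """Fit baseline + sum of exponentials by variable projection.

    Nonlinear parameters are log-rates; amplitudes and baseline are solved
    linearly at every step.  Returns (rates, linear coeffs [b, a_1..a_n],
    SSR, converged).
    """

    def design(logk: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(t)]
        for lk in logk:
            k = math.exp(min(max(lk, -60.0), 60.0))
            cols.append(np.exp(np.clip(-k * t, -700.0, 0.0)))
        return np.column_stack(cols)

    def resid(logk: np.ndarray) -> np.ndarray:
        X = design(logk)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return X @ coef - y

    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, method="lm", max_nfev=4000)
        except Exception:
            continue
        ssr = float(2 * sol.cost)
        if best is None or ssr < best[1]:
            best = (sol, ssr)
    if best is None:
        raise RuntimeError("all multi-exponential starts failed")
    sol, ssr = best
    logk = np.clip(sol.x, -60.0, 60.0)
    X = design(logk)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rates = np.exp(logk)
    return rates, coef, ssr, bool(sol.success)


def _full_covariance(
    t: np.ndarray, y: np.ndarray, baseline: float,
    amps: np.ndarray, rates: np.ndarray, ssr: float
) -> Optional[np.ndarray]:
    n, p = len(t), 1 + 2 * len(amps)
    if n <= p:
        return None
    cols = [np.ones_like(t)]
    for a, k in zip(amps, rates):
        e = np.exp(-k * t)
        cols.append(e)            # d/da
        cols.append(-a * t * e)   # d/dk
    J = np.column_stack(cols)
    try:
        cov = np.linalg.inv(J.T @ J) * ssr / (n - p)
    except np.linalg.LinAlgError:
        return None
    return cov


def _rate_starts(t: np.ndarray, n_phases: int, n_starts: int) -> List[np.ndarray]:
    span = max(t[-1] - t[0], np.finfo(float).eps)
    dt = max(np.min(np.diff(t)) if len(t) > 1 else span, np.finfo(float).eps)
    lo, hi = math.log(0.2 / span), math.log(1.0 / (2 * dt))
    base = np.linspace(lo, hi, n_starts)
    starts = []
    for b in base:
        if n_phases == 1:
            starts.append(np.array([b]))
        else:
            starts.append(np.array([b, b - math.log(5.0)]))
    return starts


def fit_multiexponential(
    tc: TimeCourse | Tuple[np.ndarray, np.ndarray],
    max_phases: int = 2,
    amp_floor: float = 0.05,
    rate_ratio_min: float = 1.5,
    n_starts: int = 5,
) -> ExpFitResult:
    """Fit baseline + sum of up to ``max_phases`` decaying exponentials.

    The phase count is chosen by the corrected Akaike criterion over
    n = 0..max_phases, then guarded for identifiability: a phase whose
    amplitude is below ``amp_floor`` of the total signal change, or whose
    rate lies within a factor ``rate_ratio_min`` of another phase, demotes
    the model to one fewer phase.  Uncertainties come from the local
    quadratic approximation at the optimum.  Five deterministic log-spaced
    rate seeds guard against local minima.
    """
    if isinstance(tc, TimeCourse):
        t_raw, y = tc.times, tc.signal
    else:
        t_raw, y = tc
        t_raw = np.asarray(t_raw, float)
        y = np.asarray(y, float)
    if len(t_raw) < 10:
        raise ValueError("need at least 10 points after the dead time")
    t0 = float(t_raw[0])
    t = t_raw - t0

    candidates: Dict[int, Dict] = {}
    # n = 0: constant model
    base0 = float(np.mean(y))
    ssr0 = float(np.sum((y - base0) ** 2))
    candidates[0] = dict(rates=np.array([]), amps=np.array([]),
                         baseline=base0, ssr=ssr0, converged=True)
    for n_ph in range(1, max_phases + 1):
        try:
            rates, coef, ssr, ok = _varpro_fit(
                t, y, n_ph, _rate_starts(t, n_ph, n_starts)
            )
        except RuntimeError:
            continue
        order = np.argsort(rates)[::-1]
        candidates[n_ph] = dict(
            rates=rates[order], amps=coef[1:][order], baseline=float(coef[0]),
            ssr=ssr, converged=ok,
        )

    n_pts = len(t)
    scores = {
        n_ph: _aicc(c["ssr"], n_pts, 1 + 2 * n_ph)
        for n_ph, c in candidates.items()
    }
    chosen = min(scores, key=scores.get)
    demoted_from: Optional[int] = None

    def violates_guards(c: Dict, n_ph: int) -> bool:
        if n_ph < 1:
            return False
        amps = np.abs(c["amps"])
        total = amps.sum()
        if total == 0:
            return True
        if n_ph >= 2:
            if np.min(amps) / total < amp_floor:
                return True
            r = np.sort(c["rates"])
            if np.any(r[1:] / r[:-1] < rate_ratio_min):
                return True
        return False

    while chosen >= 1 and violates_guards(candidates[chosen], chosen):
        demoted_from = chosen if demoted_from is None else demoted_from
        chosen -= 1
        if chosen not in candidates:
            chosen += 1
            break

    c = candidates[chosen]
    amps = np.asarray(c["amps"], float)
    rates = np.asarray(c["rates"], float)
    cov = _full_covariance(t, y, c["baseline"], amps, rates, c["ssr"]) \
        if chosen >= 1 else None
    if cov is not None:
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        baseline_se = float(se[0])
        amp_se = se[1::2]
        rate_se = se[2::2]
    else:
        dof = max(n_pts - 1, 1)
        baseline_se = float(np.sqrt(c["ssr"] / dof / n_pts))
        amp_se = np.full_like(amps, np.nan)
        rate_se = np.full_like(rates, np.nan)

    return ExpFitResult(
        n_phases=chosen,
        amplitudes=amps,
        rates=rates,
        amplitude_stderr=np.asarray(amp_se, float),
        rate_stderr=np.asarray(rate_se, float),
        baseline=float(c["baseline"]),
        baseline_stderr=baseline_se,
        objective=float(c["ssr"]),
        selection_scores=scores,
        converged=bool(c["converged"]),
        demoted_from=demoted_from,
    )


# ---------------------------------------------------------------------------
# saturation / regression


@dataclass
class TrapFit:
    k_max: float
    k_max_stderr: float
    c_half: float
    c_half_stderr: float
    extrapolation_warning: bool
    details: Dict = field(default_factory=dict)


def fit_trap_saturation(
    kobs_by_conc: Sequence[Tuple[float, float]]
) -> TrapFit:
    """Hyperbolic fit ``k_obs = k_max c / (c_half + c)``.

    Returns the limiting rate ``k_max`` (the dissociation constant the
    trap experiment extrapolates to) with its standard error; warns when
    ``c_half`` exceeds the largest measured concentration, i.e. the
    maximum is an extrapolation.
    """
    pts = np.asarray(kobs_by_conc, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("kobs_by_conc must be (conc, k_obs) pairs")
    c, k = pts[:, 0], pts[:, 1]
    if len(np.unique(c)) < 3:
        raise ValueError("need k_obs at >= 3 distinct concentrations")
    k_mean = float(np.mean(k))
    spread = float(np.ptp(k))
    if k_mean > 0 and spread / k_mean < 1e-9:
        # saturated limit: identical rates at all concentrations
        return TrapFit(k_max=k_mean, k_max_stderr=0.0, c_half=0.0,
                       c_half_stderr=0.0, extrapolation_warning=False)

    def hyper(cc, kmax, chalf):
        return kmax * cc / (chalf + cc)

    p0 = (float(np.max(k)) * 1.05, float(np.median(c)) * 0.3 + 1e-12)
    popt, pcov = curve_fit(
        hyper, c, k, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=20000,
    )
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return TrapFit(
        k_max=float(popt[0]), k_max_stderr=float(perr[0]),
        c_half=float(popt[1]), c_half_stderr=float(perr[1]),
        extrapolation_warning=bool(popt[1] > np.max(c)),
    )


def fit_second_order(
    kobs_by_conc: Sequence[Tuple[float, float]],
    through_origin: bool = False,
) -> RateDetermination:
    """Ordinary least squares of k_obs on ligand concentration.

    The slope is the second-order bimolecular constant (M^-1 s^-1); the
    intercept is reported and tested against zero unless the fit is
    constrained through the origin.
    """
    pts = np.asarray(kobs_by_conc, float)
    c, k = pts[:, 0], pts[:, 1]
    if len(np.unique(c)) < 3:
        raise ValueError("need k_obs at >= 3 distinct concentrations")
    if float(np.ptp(c)) <= 0 or float(np.ptp(c)) / float(np.max(c)) < 1e-9:
        raise ValueError("degenerate concentration spread")
    n = len(c)
    if through_origin:
        slope = float(np.sum(c * k) / np.sum(c * c))
        resid = k - slope * c
        dof = n - 1
        s2 = float(np.sum(resid ** 2) / dof) if dof > 0 else float("nan")
        se = math.sqrt(s2 / float(np.sum(c * c))) if dof > 0 else float("nan")
        tcrit = stats.t.ppf(0.975, dof) if dof > 0 else float("nan")
        return RateDetermination(
            second_order_k=slope, second_order_stderr=se,
            intercept=0.0, intercept_stderr=0.0,
            slope_ci95=(slope - tcrit * se, slope + tcrit * se),
            details={"through_origin": True, "n": n},
        )
    res = stats.linregress(c, k)
    dof = n - 2
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else float("nan")
    intercept_t = res.intercept / res.intercept_stderr \
        if res.intercept_stderr > 0 else float("inf")
    intercept_p = 2 * stats.t.sf(abs(intercept_t), dof) if dof > 0 else float("nan")
    return RateDetermination(
        second_order_k=float(res.slope),
        second_order_stderr=float(res.stderr),
        intercept=float(res.intercept),
        intercept_stderr=float(res.intercept_stderr),
        slope_ci95=(float(res.slope - tcrit * res.stderr),
                    float(res.slope + tcrit * res.stderr)),
        details={"through_origin": False, "n": n,
                 "intercept_p_value": float(intercept_p),
                 "r_value": float(res.rvalue)},
    )


def classify_dependence(
    kobs_by_conc: Sequence[Tuple[float, float]],
    alpha: float = 0.05,
    aicc_margin: float = 2.0,
) -> Dependence:
    """Is k_obs ligand-concentration independent (distal-His gated)?

    Verdict ``gated_independent`` when the 95% CI of the OLS slope
    contains zero AND the linear model's corrected-AIC improvement over
    the constant model is below ``aicc_margin``; ``bimolecular_dependent``
    otherwise.  Requires >= 3 distinct concentrations spanning >= 4-fold,
    else ``indeterminate``.
    """
    pts = np.asarray(kobs_by_conc, float)
    c, k = pts[:, 0], pts[:, 1]
    uniq = np.unique(c)
    if len(uniq) < 3 or uniq.min() <= 0 or uniq.max() / uniq.min() < 4.0:
        return Dependence.INDETERMINATE
    n = len(c)
    res = stats.linregress(c, k)
    dof = n - 2
    tcrit = stats.t.ppf(1 - alpha / 2, dof)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    ssr_line = float(np.sum((k - (res.intercept + res.slope * c)) ** 2))
    ssr_const = float(np.sum((k - np.mean(k)) ** 2))
    improvement = _aicc(ssr_const, n, 2) - _aicc(ssr_line, n, 3)
    slope_zero_ok = ci[0] <= 0.0 <= ci[1]
    if slope_zero_ok and improvement < aicc_margin:
        return Dependence.GATED_INDEPENDENT
    return Dependence.BIMOLECULAR_DEPENDENT


# ---------------------------------------------------------------------------
# censoring


def observability_bound(sampling_interval: float,
                        t_half_factor: float = 2.5) -> float:
    """ln2 / t_half_min: the fastest observable rate's lower bound (s^-1).

    ``t_half_min = t_half_factor * sampling_interval`` (3 ms at the
    default 1.2 ms sampling): reactions with shorter half-times cannot be
    resolved and only bound the true rate from below.
    """
    return math.log(2.0) / (t_half_factor * sampling_interval)


def censored_bound(
    tc: TimeCourse,
    expected_amplitude: Optional[float] = None,
    missing_frac: float = 0.95,
    t_half_factor: float = 2.5,
) -> RateDetermination:
    """Dead-time censoring verdict for a single trace.

    A trace is censored when (a) at least ``missing_frac`` of the expected
    amplitude is already missing at the first observable sample, or
    (b) the empirical half-time of the transition -- the time, counted
    from mixing and including the dead time, at which half the expected
    amplitude is gone -- is below ``t_half_min = t_half_factor *
    sampling_interval`` (3 ms at the default 1.2 ms sampling): such
    reactions are too fast for the instrument to resolve.  Censored
    results carry only the lower bound ``ln2 / t_half_min``, never a
    finite constant.
    """
    if expected_amplitude is None:
        if tc.truth and "expected_amplitude_au" in tc.truth:
            expected_amplitude = float(tc.truth["expected_amplitude_au"])
        else:
            raise ValueError(
                "expected_amplitude not given and absent from trace metadata"
            )
    expected = abs(float(expected_amplitude))
    bound = observability_bound(tc.instrument.sampling_interval, t_half_factor)
    t_half_min = t_half_factor * tc.instrument.sampling_interval
    n_head = max(1, min(3, len(tc.signal)))
    n_tail = max(1, len(tc.signal) // 20)
    first = float(np.median(tc.signal[:n_head]))
    last = float(np.median(tc.signal[-n_tail:]))
    remaining = abs(first - last)
    missing = max(expected - remaining, 0.0)
    frac_missing = missing / expected if expected > 0 else 0.0

    # empirical half-time: first crossing of the half-amplitude level
    t_half = None
    if expected > 0:
        rem = np.abs(tc.signal - last)
        below = np.nonzero(rem <= 0.5 * expected)[0]
        if frac_missing >= 0.5:
            t_half = float(tc.times[0])  # already past half before data
        elif len(below):
            i = int(below[0])
            if i == 0:
                t_half = float(tc.times[0])
            else:
                r0, r1 = rem[i - 1], rem[i]
                t0, t1 = tc.times[i - 1], tc.times[i]
                frac = (r0 - 0.5 * expected) / (r0 - r1) if r0 != r1 else 0.5
                t_half = float(t0 + frac * (t1 - t0))

    is_censored = frac_missing >= missing_frac or (
        t_half is not None and t_half < t_half_min
    )
    details = {
        "fraction_amplitude_missing": frac_missing,
        "t_half_s": t_half,
        "t_half_min_s": t_half_min,
    }
    if is_censored:
        return RateDetermination(censored=True, lower_bound=bound,
                                 details=details)
    return RateDetermination(censored=False, details=details)


def compare_to_references(
    k: float, table: Optional[Dict[str, float]] = None
) -> Dict[str, float]:
    """Fold-change of a NiR constant over each reference globin (3 s.f.)."""
    if k <= 0:
        raise ValueError("k must be > 0")
    table = NIR_REFERENCES if table is None else table
    return {name: round_sig(k / ref, 3) for name, ref in table.items()}
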