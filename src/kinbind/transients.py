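"""Phase analysis of stopped-flow transients.

Each transient is fit to a sum of exponentials (1–3 phases, selected by AIC),
phases are ordered fast-to-slow, and the observed rates are then analysed
against titrant concentration: the fast phase by the pseudo-first-order line
kobs = kon [L] + koff, the slow phase by the saturating hyperbola
kobs = kslow [L] / (K0.5 + [L]).  This mirrors the per-construct kinetic
summaries of the stopped-flow study (kon, koff, Kd_app = koff/kon, kslow,
K0.5, each with a standard error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    DegeneratePhasesWarning,
    ExtrapolationWarning,
    FitFailureError,
    IllDeterminedWarning,
    InsufficientDataError,
    NoDecayWarning,
    PseudoFirstOrderWarning,
)

__all__ = [
    "ExponentialFit",
    "LinearPhaseFit",
    "HyperbolicPhaseFit",
    "PhaseSummary",
    "fit_exponentials",
    "select_model",
    "fast_phase_fit",
    "slow_phase_fit",
    "summarize",
    "TitrationAnalysis",
]


@dataclass
class ExponentialFit:
    """offset + sum_i A_i exp(-kobs_i t), phases sorted fast to slow."""

    n_phases: int
    amplitudes: np.ndarray
    kobs: np.ndarray
    offset: float
    residual_ss: float
    aic: float
    n_points: int
    warnings: list = field(default_factory=list)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        y = np.full(t.shape, self.offset)
        for a, k in zip(self.amplitudes, self.kobs):
            y += a * np.exp(-k * t)
        return y


def _varpro_residual(log_k: np.ndarray, t: np.ndarray, y: np.ndarray):
    """Residuals after projecting out the linear amplitudes and offset."""
    k = 10.0 ** log_k
    X = np.column_stack([np.ones_like(t)] + [np.exp(-ki * t) for ki in k])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X @ coef - y, coef


def fit_exponentials(t, y, n_phases: int) -> ExponentialFit:
    """Nonlinear least-squares multi-exponential fit of one transient.

    The rates are optimised in log space with the amplitudes and offset
    solved linearly at every step (variable projection); optimisation is
    multi-started from log-spaced rate guesses spanning the resolvable
    window of the trace.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if not 1 <= n_phases <= 3:
        raise InsufficientDataError("n_phases must be between 1 and 3")
    n_min = 5 * (2 * n_phases + 1)
    if t.size < n_min:
        raise InsufficientDataError(
            f"{t.size} samples < {n_min} required for {n_phases} phases"
        )
    t = t - t[0]  # rates are origin-independent; amplitudes refer to the window start

    span = t[-1]
    dt = np.median(np.diff(t))
    lo, hi = np.log10(0.5 / span), np.log10(0.5 / dt)
    grid = np.linspace(lo, hi, 4 + 2 * n_phases)

    best = None
    rng_starts = []
    if n_phases == 1:
        rng_starts = [[g] for g in grid]
    elif n_phases == 2:
        rng_starts = [[g1, g2] for i, g1 in enumerate(grid) for g2 in grid[i + 1:]]
    else:
        step = max(1, len(grid) // 4)
        g = grid[::step]
        rng_starts = [[a, b, c] for i, a in enumerate(g)
                      for j, b in enumerate(g[i + 1:], i + 1) for c in g[j + 1:]]

    failures = []
    for x0 in rng_starts:
        try:
            res = optimize.least_squares(
                lambda lk: _varpro_residual(lk, t, y)[0],
                x0=np.asarray(x0, float),
                bounds=(lo - 2.0, hi + 2.0),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        ss = float(np.sum(res.fun**2))
        if best is None or ss < best[0]:
            best = (ss, res.x)
    if best is None:
        raise FitFailureError(f"all {len(rng_starts)} starts failed: {failures[:3]}")

    ss, log_k = best
    _, coef = _varpro_residual(log_k, t, y)
    k = 10.0 ** log_k
    order = np.argsort(k)[::-1]
    k = k[order]
    amps = coef[1:][order]
    offset = float(coef[0])

    n = t.size
    p = 2 * n_phases + 1
    aic = n * np.log(max(ss, 1e-300) / n) + 2 * p

    fit = ExponentialFit(
        n_phases=n_phases, amplitudes=amps, kobs=k, offset=offset,
        residual_ss=ss, aic=float(aic), n_points=n,
    )
    for i in range(n_phases - 1):
        if k[i + 1] > 0 and abs(k[i] / k[i + 1] - 1.0) < 0.05:
            msg = (f"recovered rates {k[i]:.4g} and {k[i + 1]:.4g} s^-1 are "
                   "within 5%: phases are degenerate")
            fit.warnings.append(msg)
            warnings.warn(msg, DegeneratePhasesWarning, stacklevel=2)
    return fit


def select_model(t, y, max_phases: int = 3) -> ExponentialFit:
    """Fit 1..max_phases exponentials and return the lowest-AIC model."""
    fits, errors = [], []
    for n in range(1, max_phases + 1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegeneratePhasesWarning)
                fits.append(fit_exponentials(t, y, n))
        except (InsufficientDataError, FitFailureError) as exc:
            errors.append(f"n={n}: {exc}")
    if not fits:
        raise FitFailureError("no exponential model could be fit: " + "; ".join(errors))
    best = min(fits, key=lambda f: f.aic)
    total_amp = np.sum(np.abs(best.amplitudes))
    scale = max(np.ptp(np.asarray(y)), abs(best.offset), 1e-300)
    if total_amp < 1e-3 * scale:
        warnings.warn("trace carries no resolvable decay amplitude",
                      NoDecayWarning, stacklevel=2)
    return best


@dataclass
class LinearPhaseFit:
    """kobs = kon [L] + koff with first-order-propagated Kd_app = koff/kon."""

    kon: float
    kon_se: float
    koff: float
    koff_se: float
    kd_app: float
    kd_app_se: float
    n_points: int
    warnings: list = field(default_factory=list)


def fast_phase_fit(concentrations, kobs) -> LinearPhaseFit:
    """Ordinary least-squares line through the fast-phase observed rates.

    A negative intercept is reported as-is with its standard error.  With
    exactly two points the line is exact and the errors are undefined.
    """
    c = np.asarray(concentrations, float)
    k = np.asarray(kobs, float)
    if c.size < 3:
        if c.size == 2 and c[0] != c[1]:
            kon = (k[1] - k[0]) / (c[1] - c[0])
            koff = k[0] - kon * c[0]
            kd = koff / kon if kon != 0 else np.nan
            return LinearPhaseFit(kon, np.nan, koff, np.nan, kd, np.nan, 2,
                                  ["two-point line: standard errors undefined"])
        raise InsufficientDataError("fast-phase fit needs >= 3 concentrations")
    if np.ptp(k) == 0.0:
        w = ["all kobs identical: kon = 0 and Kd_app is undefined"]
        warnings.warn(w[0], IllDeterminedWarning, stacklevel=2)
        return LinearPhaseFit(0.0, 0.0, float(k[0]), 0.0, np.nan, np.nan,
                              c.size, w)
    res = stats.linregress(c, k)
    kon, koff = float(res.slope), float(res.intercept)
    kon_se, koff_se = float(res.stderr), float(res.intercept_stderr)
    kd = koff / kon
    kd_se = (
        abs(kd) * np.hypot(koff_se / koff if koff != 0 else 0.0, kon_se / kon)
        if kon != 0 else np.nan
    )
    return LinearPhaseFit(kon, kon_se, koff, koff_se, kd, kd_se, c.size)


@dataclass
class HyperbolicPhaseFit:
    """kobs = kslow [L] / (K0.5 + [L]) (no additive offset by default)."""

    kslow: float
    kslow_se: float
    k0_5: float
    k0_5_se: float
    n_points: int
    warnings: list = field(default_factory=list)


def slow_phase_fit(concentrations, kobs, with_offset: bool = False) -> HyperbolicPhaseFit:
    """Nonlinear least-squares hyperbolic fit of the slow-phase rates.

    The optional additive offset (``with_offset=True``) is off by default;
    the published analysis quotes only the maximal rate and half-saturation
    concentration.
    """
    c = np.asarray(concentrations, float)
    k = np.asarray(kobs, float)
    if c.size < 2:
        raise InsufficientDataError("slow-phase fit needs >= 2 concentrations")
    warns = []
    if c.size < 4:
        warns.append("fewer than 4 concentrations: hyperbola weakly constrained")

    def model(L, kslow, k05, off=0.0):
        return kslow * L / (k05 + L) + off

    p0 = [max(k.max(), 1e-12), np.median(c)] + ([0.0] if with_offset else [])
    try:
        popt, pcov = optimize.curve_fit(
            (model if with_offset else lambda L, a, b: model(L, a, b)),
            c, k, p0=p0, maxfev=20000,
        )
    except Exception as exc:
        raise FitFailureError(f"hyperbolic fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    kslow, k05 = float(popt[0]), float(popt[1])

    if not (c.min() <= k05 <= c.max()):
        warns.append(f"K0.5 = {k05:.3g} M lies outside the sampled range")
        warnings.warn(warns[-1], ExtrapolationWarning, stacklevel=2)
    if k05 < c.min() / 5.0:
        warns.append("all concentrations are saturating: K0.5 is ill-determined")
        warnings.warn(warns[-1], IllDeterminedWarning, stacklevel=2)
    elif not (np.any(c < k05) and np.any(c > k05)):
        warns.append("concentrations do not span the half-saturation point")

    return HyperbolicPhaseFit(kslow, float(perr[0]), k05, float(perr[1]),
                              c.size, warns)


@dataclass
class PhaseSummary:
    """Per-construct kinetic summary with the per-concentration amplitudes."""

    scheme: str
    fast: LinearPhaseFit
    slow: HyperbolicPhaseFit | None
    amplitudes: pd.DataFrame  # concentration_M, kobs per phase, relative amplitudes
    warnings: list = field(default_factory=list)

    @property
    def kon(self): return self.fast.kon
    @property
    def koff(self): return self.fast.koff
    @property
    def kd_app(self): return self.fast.kd_app
    @property
    def kslow(self): return self.slow.kslow if self.slow else np.nan
    @property
    def k0_5(self): return self.slow.k0_5 if self.slow else np.nan

    def to_frame(self) -> pd.DataFrame:
        s = self.slow
        return pd.DataFrame(
            [{
                "scheme": self.scheme,
                "kon": self.fast.kon, "kon_se": self.fast.kon_se,
                "koff": self.fast.koff, "koff_se": self.fast.koff_se,
                "kd_app": self.fast.kd_app, "kd_app_se": self.fast.kd_app_se,
                "kslow": s.kslow if s else np.nan,
                "kslow_se": s.kslow_se if s else np.nan,
                "k0_5": s.k0_5 if s else np.nan,
                "k0_5_se": s.k0_5_se if s else np.nan,
            }]
        ).set_index("scheme")

    def summary(self) -> str:
        f = self.fast
        lines = [
            f"Phase summary [{self.scheme}]",
            f"  fast phase : kon  = {f.kon:.3g} +/- {f.kon_se:.2g} M^-1 s^-1",
            f"               koff = {f.koff:.3g} +/- {f.koff_se:.2g} s^-1",
            f"               Kd_app = {f.kd_app:.3g} +/- {f.kd_app_se:.2g} M",
        ]
        if self.slow is not None:
            lines += [
                f"  slow phase : kslow = {self.slow.kslow:.3g} +/- "
                f"{self.slow.kslow_se:.2g} s^-1",
                f"               K0.5  = {self.slow.k0_5:.3g} +/- "
                f"{self.slow.k0_5_se:.2g} M",
            ]
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


def summarize(series, max_phases: int = 2) -> PhaseSummary:
    """Full per-series phase analysis.

    Runs AIC model selection on every usable transient, assigns phases by
    rate magnitude, fits the fast-phase line and (where at least two phases
    were found) the slow-phase hyperbola, and tabulates the relative
    pre-exponential amplitudes per concentration.
    """
    usable = series.usable()
    if len(usable) < 3:
        raise InsufficientDataError(
            f"only {len(usable)} usable transients; need >= 3"
        )
    notes = []
    fixed = series.design.fixed_conc
    rows = []
    for conc, y in usable:
        if conc < 5.0 * fixed:
            msg = (f"[L] = {conc:.3g} M < 5x fixed partner: "
                   "pseudo-first-order assumption weak")
            notes.append(msg)
            warnings.warn(msg, PseudoFirstOrderWarning, stacklevel=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = select_model(series.time, y, max_phases=max_phases)
        total = np.sum(np.abs(fit.amplitudes))
        row = {"concentration_M": conc, "n_phases": fit.n_phases}
        for i in range(fit.n_phases):
            row[f"kobs_{i + 1}"] = fit.kobs[i]
            row[f"rel_amp_{i + 1}"] = abs(fit.amplitudes[i]) / total if total else np.nan
        rows.append(row)
    amp = pd.DataFrame(rows)

    fast = fast_phase_fit(amp["concentration_M"], amp["kobs_1"])
    slow = None
    if "kobs_2" in amp.columns:
        mask = amp["kobs_2"].notna()
        if mask.sum() >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                slow = slow_phase_fit(
                    amp.loc[mask, "concentration_M"], amp.loc[mask, "kobs_2"]
                )
            notes.extend(slow.warnings)
    notes.extend(fast.warnings)
    return PhaseSummary(
        scheme=series.design.scheme, fast=fast, slow=slow,
        amplitudes=amp, warnings=notes,
    )


class TitrationAnalysis:
    """Model-style wrapper: ``TitrationAnalysis(series).fit()`` -> PhaseSummary."""

    def __init__(self, series, max_phases: int = 2):
        self.series = series
        self.max_phases = max_phases

    def fit(self) -> PhaseSummary:
        return summarize(self.series, max_phases=self.max_phases)
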