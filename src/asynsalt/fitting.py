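"""Normalization, median traces and global seeded fits of ThT time courses.

The experimental observable is thioflavin-T fluorescence versus time per
well.  The analysis chain is: per-well normalization to [0, 1] (baseline and
amplitude are nuisance parameters of the reporter, not of the kinetics),
median traces across replicates, and a global fit of the seeded
secondary-nucleation model to all replicates of one condition, yielding the
rate-constant product k2*k_plus per salt concentration.

Only the product k2*k_plus (and k_plus*P0) is identifiable from seeded
traces, so the elongation rate is pinned to 1 in internal units and k_2
absorbs the product; the seed number P0 follows from the seed mass via a
configurable mean seed length.  With the per-well amplitude/baseline entering
linearly, the fit has a single nonlinear parameter (log10 k2k+), which is
multi-started and then polished jointly with the linear parameters to obtain
a covariance-based confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import KineticParams, closed_form_mass, half_time

__all__ = [
    "ThTTrace",
    "NormalizedTrace",
    "SaltFit",
    "SaltSeriesFit",
    "normalize",
    "median_trace",
    "fit_seeded_series",
    "t_half_vs_salt",
]

#: A condition is called non-aggregating when its fitted amplitude is below
#: this fraction of the largest amplitude seen in the series.
NON_AGGREGATING_FRACTION = 0.05


@dataclass
class ThTTrace:
    """One well: time (h), fluorescence (a.u.) and condition metadata."""

    t: np.ndarray
    F: np.ndarray
    monomer_uM: float
    seed_uM: float
    salt_mM: float
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if len(self.t) < 10:
            raise ValueError("a trace needs at least 10 time points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("fluorescence must be finite")


@dataclass
class NormalizedTrace:
    t: np.ndarray
    y: np.ndarray
    baseline: float
    amplitude: float
    aggregating: bool
    monomer_uM: float = 0.0
    seed_uM: float = 0.0
    salt_mM: float = 0.0
    replicate_id: str = "r1"


@dataclass
class SaltFit:
    salt_mM: float
    aggregating: bool
    k2kplus: float = math.nan  # M^(-n2-1) h^-2
    ci_low: float = math.nan
    ci_high: float = math.nan
    t_half_h: float = math.nan  # median over replicates
    converged: bool = False
    n_replicates: int = 0


@dataclass
class SaltSeriesFit:
    seed_uM: float
    monomer_uM: float
    n_2: float
    n_c: float
    seed_length: float
    fits: list[SaltFit] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(f) for f in self.fits])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _richards(t: np.ndarray, b: float, a: float, t0: float, tau: float,
              nu: float) -> np.ndarray:
    """Generalized logistic; the shape exponent nu accommodates the concave
    early growth of secondary-nucleation traces."""
    x = np.clip(-(t - t0) / tau, -500.0, 500.0)
    return b + a / (1.0 + np.exp(x)) ** np.clip(nu, 0.05, 20.0)


def normalize(trace: ThTTrace, min_amplitude: Optional[float] = None) -> NormalizedTrace:
    """Normalize one trace to y = (F - baseline) / amplitude.

    The baseline is the median of the pre-growth segment (points before the
    signal exceeds 5% of the robust range) and the plateau the median of the
    final segment; a generalized-logistic envelope fit refines both and is
    kept only when it reduces the residual.  A trace whose amplitude does
    not exceed ``min_amplitude`` (default: 5 noise standard deviations of
    the early segment) is flagged non-aggregating and returned unscaled
    around its baseline.
    """
    t, F = trace.t, trace.F
    n = len(t)
    edge = max(5, n // 10)
    lo = float(np.quantile(F, 0.02))
    hi = float(np.quantile(F, 0.98))
    # pre-growth segment: everything before the first 5%-of-range crossing
    level = lo + 0.05 * (hi - lo)
    above = np.nonzero(F > level)[0]
    pre_end = int(above[0]) if len(above) else n
    baseline = float(np.median(F[: max(pre_end, 3)]))
    plateau = float(np.median(F[-edge:]))
    amplitude = plateau - baseline

    # envelope refinement, accepted only on improvement
    if amplitude > 0:
        try:
            from scipy.optimize import curve_fit

            t0_guess = half_time(t, F, baseline, amplitude)
            if t0_guess is not None:
                p0 = [baseline, amplitude, t0_guess,
                      max(t[-1] / 20.0, 1e-3), 1.0]
                popt, _ = curve_fit(_richards, t, F, p0=p0, maxfev=4000)
                res_fit = float(np.sum((F - _richards(t, *popt)) ** 2))
                crude = np.where(t < t0_guess, baseline, plateau)
                res_crude = float(np.sum((F - crude) ** 2))
                sane = (
                    popt[1] > 0
                    and popt[1] < 2.0 * (hi - lo)  # amplitude within range
                    and lo - (hi - lo) < popt[0] < hi  # baseline plausible
                )
                if sane and res_fit < res_crude:
                    baseline, amplitude = float(popt[0]), float(popt[1])
        except Exception:
            pass  # robust estimates stand

    noise_sd = float(np.std(np.diff(F[:edge]))) / math.sqrt(2.0) if edge > 2 else 0.0
    threshold = min_amplitude if min_amplitude is not None else 5.0 * noise_sd
    aggregating = amplitude > max(threshold, 0.0) and amplitude > 0
    if aggregating:
        y = (F - baseline) / amplitude
    else:
        amplitude = math.nan
        y = F - baseline
    return NormalizedTrace(
        t=t, y=y, baseline=baseline, amplitude=amplitude, aggregating=aggregating,
        monomer_uM=trace.monomer_uM, seed_uM=trace.seed_uM,
        salt_mM=trace.salt_mM, replicate_id=trace.replicate_id,
    )


def median_trace(replicates: Sequence[NormalizedTrace]) -> NormalizedTrace:
    """Pointwise median across replicates on the intersection time grid."""
    if len(replicates) < 1:
        raise ValueError("need at least one replicate")
    t_lo = max(float(r.t[0]) for r in replicates)
    t_hi = min(float(r.t[-1]) for r in replicates)
    if t_hi <= t_lo:
        raise ValueError("replicate time ranges do not overlap")
    ref = replicates[0].t
    grid = ref[(ref >= t_lo) & (ref <= t_hi)]
    ys = np.vstack([np.interp(grid, r.t, r.y) for r in replicates])
    med = np.median(ys, axis=0)
    r0 = replicates[0]
    return NormalizedTrace(
        t=grid, y=med, baseline=0.0, amplitude=1.0,
        aggregating=any(r.aggregating for r in replicates),
        monomer_uM=r0.monomer_uM, seed_uM=r0.seed_uM, salt_mM=r0.salt_mM,
        replicate_id="median",
    )


def _model_curve(log10_k2kp: float, t: np.ndarray, m0: float, M0: float,
                 P0: float, n_2: float, n_c: float) -> np.ndarray:
    p = KineticParams(k_n=0.0, k_2=10.0**log10_k2kp, k_plus=1.0,
                      n_c=n_c, n_2=n_2, m0=m0, M0=M0, P0=P0)
    return closed_form_mass(p, t).M_frac


def _projected_cost(log10_k2kp: float, traces: Sequence[NormalizedTrace],
                    m0: float, M0: float, P0: float,
                    n_2: float, n_c: float) -> float:
    """Cost with per-well amplitude/baseline profiled out (linear solve)."""
    cost = 0.0
    for tr in traces:
        m = _model_curve(log10_k2kp, tr.t, m0, M0, P0, n_2, n_c)
        A = np.column_stack([m, np.ones_like(m)])
        coef, res, *_ = np.linalg.lstsq(A, tr.y, rcond=None)
        r = tr.y - A @ coef
        cost += float(r @ r)
    return cost


def fit_seeded_series(
    traces: Sequence[ThTTrace],
    n_2: float = 2.0,
    n_c: float = 2.0,
    seed_length: float = 500.0,
    horizon_h: Optional[float] = None,
    n_starts: int = 5,
    start_range: tuple[float, float] = (13.0, 19.0),
) -> SaltSeriesFit:
    """Global seeded fit per salt concentration.

    All traces must share one monomer and one seed concentration; they are
    grouped by salt.  Per group, replicates are fitted jointly by the exact
    seeded mass curve with shared log10(k2*k_plus) and free per-well
    amplitude and baseline (no time offset: plates start at t = 0).  The
    single nonlinear parameter is multi-started on ``n_starts`` log-spaced
    initial values, then polished jointly with the linear parameters; the
    confidence interval comes from the Jacobian at the optimum (95%, on the
    log10 scale, reported on the linear scale).

    Conditions whose every replicate is flat (amplitude below 5% of the
    series' largest amplitude) are flagged non-aggregating and carry no
    estimate; their half-time is censored at the horizon.
    """
    if not traces:
        raise ValueError("no traces given")
    monomer = {tr.monomer_uM for tr in traces}
    seed = {tr.seed_uM for tr in traces}
    if len(monomer) != 1 or len(seed) != 1:
        raise ValueError("fit one (monomer, seed) series at a time")
    monomer_uM, seed_uM = monomer.pop(), seed.pop()
    m0 = monomer_uM * 1e-6
    M0 = seed_uM * 1e-6
    P0 = M0 / seed_length
    horizon = horizon_h if horizon_h is not None else max(float(tr.t[-1]) for tr in traces)

    normalized = [normalize(tr) for tr in traces]
    max_amp = max((nt.amplitude for nt in normalized if nt.aggregating),
                  default=math.nan)
    # series-level non-aggregation rule
    for nt in normalized:
        if nt.aggregating and not math.isnan(max_amp):
            if nt.amplitude < NON_AGGREGATING_FRACTION * max_amp:
                nt.aggregating = False

    out = SaltSeriesFit(seed_uM=seed_uM, monomer_uM=monomer_uM,
                        n_2=n_2, n_c=n_c, seed_length=seed_length)
    for salt in sorted({tr.salt_mM for tr in traces}):
        group = [nt for nt in normalized if nt.salt_mM == salt]
        live = [nt for nt in group if nt.aggregating]
        fit = SaltFit(salt_mM=salt, aggregating=bool(live),
                      n_replicates=len(group))
        if not live:
            out.fits.append(fit)
            continue

        t_halves = [half_time(nt.t, nt.y, 0.0, 1.0) for nt in live]
        t_halves = [th for th in t_halves if th is not None]
        if t_halves:
            fit.t_half_h = float(np.median(t_halves))

        starts = np.linspace(*start_range, n_starts)
        costs = [
            _projected_cost(s, live, m0, M0, P0, n_2, n_c) for s in starts
        ]
        best = starts[int(np.argmin(costs))]

        # polish the nonlinear parameter on the projected cost
        from scipy.optimize import minimize_scalar

        # polish within the winning start's basin (the starts are 1.5 log
        # units apart, so ±1 covers the basin without hopping to another)
        res1 = minimize_scalar(
            _projected_cost,
            bounds=(best - 1.0, best + 1.0), method="bounded",
            args=(live, m0, M0, P0, n_2, n_c),
        )
        log10_best = float(res1.x)

        # joint refinement for the covariance: theta = [log10k2, (a,b) per well]
        def residuals(theta: np.ndarray) -> np.ndarray:
            lk = theta[0]
            out_r = []
            for i, tr in enumerate(live):
                a, b = theta[1 + 2 * i], theta[2 + 2 * i]
                m = _model_curve(lk, tr.t, m0, M0, P0, n_2, n_c)
                out_r.append(tr.y - (a * m + b))
            return np.concatenate(out_r)

        theta0 = [log10_best]
        for tr in live:
            m = _model_curve(log10_best, tr.t, m0, M0, P0, n_2, n_c)
            A = np.column_stack([m, np.ones_like(m)])
            coef, *_ = np.linalg.lstsq(A, tr.y, rcond=None)
            theta0 += [float(coef[0]), float(coef[1])]
        ls = least_squares(residuals, np.asarray(theta0), method="lm",
                           max_nfev=400)
        lk_hat = float(ls.x[0])
        fit.k2kplus = 10.0**lk_hat
        dof = max(len(ls.fun) - len(ls.x), 1)
        s2 = float(ls.fun @ ls.fun) / dof
        JTJ = ls.jac.T @ ls.jac
        try:
            cov = np.linalg.inv(JTJ) * s2
            sd_lk = math.sqrt(max(cov[0, 0], 0.0))
            fit.ci_low = 10.0 ** (lk_hat - 1.96 * sd_lk)
            fit.ci_high = 10.0 ** (lk_hat + 1.96 * sd_lk)
        except np.linalg.LinAlgError:
            pass
        fit.converged = bool(ls.success) and np.isfinite(fit.k2kplus)
        out.fits.append(fit)
    return out


def t_half_vs_salt(
    traces: Sequence[ThTTrace],
    horizon_h: Optional[float] = None,
) -> pd.DataFrame:
    """Median half-time per salt; flat conditions are censored at the horizon.

    Returns a table with columns salt_mM, t_half_h (NaN when censored),
    censored and n_replicates; censored rows represent "> horizon".
    """
    horizon = horizon_h if horizon_h is not None else max(float(tr.t[-1]) for tr in traces)
    rows = []
    for salt in sorted({tr.salt_mM for tr in traces}):
        group = [normalize(tr) for tr in traces if tr.salt_mM == salt]
        live = [nt for nt in group if nt.aggregating]
        t_halves = [half_time(nt.t, nt.y, 0.0, 1.0) for nt in live]
        t_halves = [th for th in t_halves if th is not None]
        if t_halves:
            rows.append(dict(salt_mM=salt, t_half_h=float(np.median(t_halves)),
                             censored=False, horizon_h=horizon,
                             n_replicates=len(group)))
        else:
            rows.append(dict(salt_mM=salt, t_half_h=math.nan,
                             censored=True, horizon_h=horizon,
                             n_replicates=len(group)))
    return pd.DataFrame(rows)
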