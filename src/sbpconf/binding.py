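"""Ligand-binding and thermal-stability fits.

The binding model is the exact 1:1 mass-action isotherm **with ligand
depletion** — necessary whenever the protein concentration is comparable to
the dissociation constant (for SiaP-type experiments, ~75 nM labeled protein
against sub-micromolar Kd):

    FB = ((P + L + Kd) − sqrt((P + L + Kd)² − 4·P·L)) / (2·P)

with P, L total concentrations (M). Titration signal is an affine map of the
fraction bound; the Kd fit profiles the two linear signal parameters out in
closed form and optimizes Kd on a log grid with golden-section refinement, so
each fit is deterministic and fast enough for residual-bootstrap confidence
intervals and coverage simulations.

Thermal-stability fits: a Boltzmann sigmoid with sloped baselines for the melt
temperature Tm, and a hyperbolic apparent-K model for the Tm-vs-ligand
thermal-shift curve. The latter is an apparent constant at the melting
transition, not the isothermal Kd — DSF-derived constants are expected to
differ from isothermal (e.g. MST) estimates because the measurement happens
at elevated temperature.

``fp_ratio`` implements the fluorescein labeling-ratio formula with the 0.35
A495 correction for fluorescein absorbance at 280 nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import FitError, NoBindingError, NoTransitionError

DEFAULT_BOOTSTRAP_SEED = 20240930


@dataclass
class TitrationTable:
    """A serial-dilution titration: total ligand (M) vs signal at fixed protein (M)."""

    ligand_total: np.ndarray
    signal: np.ndarray
    protein_total: float
    replicate: int = 0

    def __post_init__(self) -> None:
        self.ligand_total = np.asarray(self.ligand_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.ligand_total.shape != self.signal.shape:
            raise ValueError("ligand and signal lengths differ")
        if np.any(self.ligand_total < 0):
            raise ValueError("ligand concentrations must be >= 0")
        if self.protein_total <= 0:
            raise ValueError("protein concentration must be positive")


@dataclass
class KdFit:
    """A 1:1 depletion-isotherm fit: Kd (M), optional 95% CI, signal endpoints."""

    kd: float
    ci: tuple[float, float] | None
    s_free: float
    s_bound: float
    residual_norm: float


@dataclass
class MeltCurve:
    """Temperature (°C, strictly increasing) vs fluorescence."""

    temperature: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.temperature) < 10:
            raise ValueError("melt curve needs at least 10 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class TmFit:
    """Boltzmann melt fit: Tm (°C), transition slope factor k (°C), baselines."""

    tm: float
    slope_k: float
    pre_baseline: tuple[float, float]
    post_baseline: tuple[float, float]
    params: np.ndarray = field(repr=False, default=None)


@dataclass
class ThermalShiftFit:
    """Hyperbolic Tm(L) fit: apparent K (M), CI, Tm0 and max shift (°C)."""

    k_app: float
    ci: tuple[float, float] | None
    tm0: float
    dtm_max: float


def fraction_bound(p_total: float, l_total, kd: float):
    """Exact 1:1 fraction of protein bound, with ligand depletion.

    Accepts scalar or array ``l_total``; returns the same shape in [0, 1].
    """
    if p_total <= 0:
        raise ValueError("p_total must be positive")
    if kd <= 0:
        raise ValueError("kd must be positive")
    L = np.asarray(l_total, dtype=float)
    if np.any(L < 0):
        raise ValueError("l_total must be >= 0")
    s = p_total + L + kd
    disc = s * s - 4.0 * p_total * L
    fb = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * p_total)
    fb = np.clip(fb, 0.0, 1.0)
    return float(fb) if np.isscalar(l_total) else fb


def _profiled_ssr(log10_kd: float, L: np.ndarray, y: np.ndarray, p_total: float):
    """SSR at a trial Kd with the affine signal parameters profiled out."""
    fb = fraction_bound(p_total, L, 10.0 ** log10_kd)
    n = len(y)
    sf = fb.sum()
    sff = (fb * fb).sum()
    sy = y.sum()
    sfy = (fb * y).sum()
    det = n * sff - sf * sf
    if det <= 1e-300:
        # fb constant across the ladder (Kd far outside the design window)
        s0 = sy / n
        ds = 0.0
    else:
        ds = (n * sfy - sf * sy) / det
        s0 = (sy - ds * sf) / n
    resid = y - (s0 + ds * fb)
    return float((resid * resid).sum()), s0, ds


def _search_kd(L: np.ndarray, y: np.ndarray, p_total: float,
               log_lo: float, log_hi: float, n_grid: int = 60):
    grid = np.linspace(log_lo, log_hi, n_grid)
    ssrs = np.array([_profiled_ssr(g, L, y, p_total)[0] for g in grid])
    k = int(np.argmin(ssrs))
    lo = grid[max(0, k - 1)]
    hi = grid[min(n_grid - 1, k + 1)]
    res = minimize_scalar(lambda g: _profiled_ssr(g, L, y, p_total)[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    best_log = float(res.x)
    at_edge = k in (0, n_grid - 1)
    return best_log, at_edge


def fit_kd(data: TitrationTable, log_margin: float = 2.0) -> KdFit:
    """Fit Kd and signal endpoints to a titration by the depletion isotherm.

    Requires ≥ 6 distinct ligand concentrations spanning ≥ 2 orders of
    magnitude. Raises :class:`NoBindingError` when the fitted amplitude is
    indistinguishable from the residual noise. A warning is issued when the Kd
    lands at the search bound.
    """
    L = data.ligand_total
    y = data.signal
    pos = L[L > 0]
    if len(np.unique(L)) < 6:
        raise FitError("need at least 6 distinct ligand concentrations")
    if len(pos) == 0 or np.log10(pos.max() / pos.min()) < 2.0:
        raise FitError("ligand concentrations must span at least 2 orders of magnitude")
    log_lo = math.log10(pos.min()) - log_margin
    log_hi = math.log10(pos.max()) + log_margin
    best_log, at_edge = _search_kd(L, y, data.protein_total, log_lo, log_hi)
    ssr, s0, ds = _profiled_ssr(best_log, L, y, data.protein_total)
    n = len(y)
    resid_sd = math.sqrt(ssr / max(n - 3, 1))
    scale = max(abs(y).max(), 1.0)
    if abs(ds) < max(3.0 * resid_sd, 1e-9 * scale):
        raise NoBindingError("no binding detected: signal amplitude within noise")
    if at_edge:
        warnings.warn("fitted Kd is at the search bound; estimate unreliable")
    return KdFit(kd=10.0 ** best_log, ci=None, s_free=s0, s_bound=s0 + ds,
                 residual_norm=math.sqrt(ssr))


def bootstrap_ci(data: TitrationTable, fit: KdFit, n_boot: int = 1000,
                 seed: int = DEFAULT_BOOTSTRAP_SEED, level: float = 0.95
                 ) -> tuple[float, float]:
    """Residual-resampling bootstrap percentile CI for the fitted Kd.

    Deterministic for a fixed seed. Raises :class:`FitError` when more than
    10% of the bootstrap refits fail.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    rng = np.random.default_rng(seed)
    L = data.ligand_total
    p_total = data.protein_total
    fb = fraction_bound(p_total, L, fit.kd)
    fitted = fit.s_free + (fit.s_bound - fit.s_free) * fb
    resid = data.signal - fitted
    log_kd = math.log10(fit.kd)
    log_lo, log_hi = log_kd - 2.0, log_kd + 2.0
    estimates = []
    failures = 0
    for _ in range(n_boot):
        y_star = fitted + rng.choice(resid, size=len(resid), replace=True)
        try:
            best_log, _ = _search_kd(L, y_star, p_total, log_lo, log_hi, n_grid=31)
            estimates.append(10.0 ** best_log)
        except (FitError, FloatingPointError):
            failures += 1
    if failures > 0.1 * n_boot:
        raise FitError(f"{failures}/{n_boot} bootstrap refits failed")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [a, 1.0 - a])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Melt curves


def _boltzmann(T, b_pre, m_pre, b_post, m_post, tm, k):
    pre = b_pre + m_pre * T
    post = b_post + m_post * T
    return pre + (post - pre) / (1.0 + np.exp((tm - T) / k))


def tm_by_derivative(curve: MeltCurve) -> float:
    """Fallback Tm estimator: temperature at the maximum of smoothed dF/dT."""
    from scipy.signal import savgol_filter

    T = curve.temperature
    F = curve.fluorescence
    win = max(5, (len(T) // 10) | 1)
    smoothed = savgol_filter(F, window_length=min(win, len(T) - (1 - len(T) % 2)), polyorder=3)
    dF = np.gradient(smoothed, T)
    return float(T[int(np.argmax(dF))])


def fit_melt_tm(curve: MeltCurve) -> TmFit:
    """Fit a Boltzmann sigmoid with sloped baselines to a melt curve.

    F(T) = pre(T) + [post(T) − pre(T)] / (1 + exp((Tm − T)/k)). Raises
    :class:`NoTransitionError` for curves without an interior sigmoidal
    transition (e.g. purely linear traces).
    """
    from scipy.optimize import curve_fit
    from scipy.signal import savgol_filter

    T = curve.temperature
    F = curve.fluorescence
    win = max(5, (len(T) // 10) | 1)
    win = min(win, len(T) if len(T) % 2 else len(T) - 1)
    smoothed = savgol_filter(F, window_length=win, polyorder=3)
    dF = np.gradient(smoothed, T)
    peak = int(np.argmax(np.abs(dF)))
    peak_mag = abs(dF[peak])
    typical = np.median(np.abs(dF))
    interior = 0 < peak < len(T) - 1
    if not interior or peak_mag < 2.5 * max(typical, 1e-12):
        raise NoTransitionError("no interior sigmoidal transition in melt curve")
    tm0 = float(T[peak])
    k0 = 2.0
    n4 = max(3, len(T) // 4)
    m_pre0, b_pre0 = np.polyfit(T[:n4], F[:n4], 1)
    m_post0, b_post0 = np.polyfit(T[-n4:], F[-n4:], 1)
    p0 = [b_pre0, m_pre0, b_post0, m_post0, tm0, k0]
    bounds = ([-np.inf] * 4 + [T[0], 1e-3], [np.inf] * 4 + [T[-1], (T[-1] - T[0])])
    try:
        popt, _ = curve_fit(_boltzmann, T, F, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise NoTransitionError(f"Boltzmann fit failed: {exc}") from exc
    return TmFit(tm=float(popt[4]), slope_k=float(popt[5]),
                 pre_baseline=(float(popt[0]), float(popt[1])),
                 post_baseline=(float(popt[2]), float(popt[3])),
                 params=popt)


def delta_tm(fit: TmFit, reference: TmFit) -> float:
    """Melting-temperature shift (°C) of ``fit`` relative to ``reference``."""
    return fit.tm - reference.tm


# ---------------------------------------------------------------------------
# Thermal-shift apparent Kd


def fit_thermal_shift_kd(l_total, tm, n_boot: int = 500,
                         seed: int = DEFAULT_BOOTSTRAP_SEED) -> ThermalShiftFit:
    """Fit Tm(L) = Tm0 + ΔTm_max · L/(L + K_app) to a thermal-shift titration.

    ``K_app`` is an apparent constant at the melting transition, not the
    isothermal Kd. Requires ≥ 5 ligand concentrations including zero. The CI is
    a residual-resampling bootstrap (percentile 2.5/97.5).
    """
    L = np.asarray(l_total, dtype=float)
    y = np.asarray(tm, dtype=float)
    if len(np.unique(L)) < 5:
        raise FitError("need at least 5 distinct ligand concentrations")
    if not np.any(L == 0):
        raise FitError("a zero-ligand reference point is required")
    pos = L[L > 0]

    def profiled(log_k):
        x = L / (L + 10.0 ** log_k)
        X = np.column_stack([np.ones_like(L), x])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float((resid ** 2).sum()), beta

    log_lo = math.log10(pos.min()) - 2.0
    log_hi = math.log10(pos.max()) + 2.0
    grid = np.linspace(log_lo, log_hi, 60)
    ssrs = [profiled(g)[0] for g in grid]
    k = int(np.argmin(ssrs))
    res = minimize_scalar(lambda g: profiled(g)[0],
                          bounds=(grid[max(0, k - 1)], grid[min(len(grid) - 1, k + 1)]),
                          method="bounded", options={"xatol": 1e-10})
    best = float(res.x)
    ssr, beta = profiled(best)
    resid_sd = math.sqrt(ssr / max(len(y) - 3, 1))
    if abs(beta[1]) < max(3.0 * resid_sd, 1e-9):
        raise NoBindingError("no Tm trend with ligand concentration")
    # Bootstrap
    x = L / (L + 10.0 ** best)
    fitted = beta[0] + beta[1] * x
    residuals = y - fitted
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_boot):
        y_star = fitted + rng.choice(residuals, size=len(residuals), replace=True)

        def prof_star(log_k):
            xs = L / (L + 10.0 ** log_k)
            X = np.column_stack([np.ones_like(L), xs])
            b, *_ = np.linalg.lstsq(X, y_star, rcond=None)
            r = y_star - X @ b
            return float((r ** 2).sum())

        g = np.linspace(best - 2.0, best + 2.0, 31)
        s = [prof_star(v) for v in g]
        j = int(np.argmin(s))
        r2 = minimize_scalar(prof_star, bounds=(g[max(0, j - 1)], g[min(len(g) - 1, j + 1)]),
                             method="bounded", options={"xatol": 1e-8})
        estimates.append(10.0 ** float(r2.x))
    lo, hi = np.quantile(estimates, [0.025, 0.975])
    return ThermalShiftFit(k_app=10.0 ** best, ci=(float(lo), float(hi)),
                           tm0=float(beta[0]), dtm_max=float(beta[1]))


# ---------------------------------------------------------------------------
# Labeling ratio


def fp_ratio(a495: float, a280: float, mw: float, e0p1: float) -> tuple[float, float]:
    """Fluorophore/protein molar ratio from A495/A280 absorbances.

    C = (MW × E0.1%) / (389 × 195); F/P = (A495 × C) / (A280 − 0.35 × A495).
    The 0.35 factor corrects A280 for fluorescein absorbance. Raises on a
    non-positive corrected A280.
    """
    c = (mw * e0p1) / (389.0 * 195.0)
    denom = a280 - 0.35 * a495
    if denom <= 0:
        raise ValueError("corrected A280 (A280 - 0.35*A495) must be positive")
    return c, (a495 * c) / denom
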