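"""Steady-state kinetics: signal→rate conversion, Michaelis–Menten and
substrate-inhibition fits, fold changes and on/off switching analysis.

The two saturation models are

    Michaelis–Menten:      v = Vmax · S / (KM + S)
    substrate inhibition:  v = Vmax · S / (KM + S · (1 + S/Ki))

the latter the canonical uncompetitive form, which reduces to plain MM as
Ki → ∞ and peaks at S* = sqrt(KM · Ki).  Both fitters are scikit-learn
compatible regressors (``fit(S, v)`` / ``predict(S)``) with multi-start
nonlinear least squares, Jacobian-based standard errors and corrected-AIC
model comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "EPSILON_PNA_410",
    "absorbance_to_rate",
    "michaelis_menten",
    "substrate_inhibition",
    "RateSeries",
    "MMParams",
    "SIParams",
    "MichaelisMentenRegressor",
    "SubstrateInhibitionRegressor",
    "fit_michaelis_menten",
    "fit_substrate_inhibition",
    "fold_change",
    "SwitchingSeries",
    "SwitchingResult",
    "switching_dynamic_range",
    "aicc",
]

#: molar extinction coefficient of p-nitroaniline at 410 nm (M^-1 cm^-1)
EPSILON_PNA_410 = 7126.0


def absorbance_to_rate(
    slope_au_per_s: float,
    path_length_cm: float = 1.0,
    epsilon: float = EPSILON_PNA_410,
) -> float:
    """Convert an absorbance slope (AU/s) to a product formation rate (µM/s)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if path_length_cm <= 0:
        raise ValueError("path length must be positive")
    return slope_au_per_s / (epsilon * path_length_cm) * 1e6


def michaelis_menten(s, vmax, km):
    s = np.asarray(s, float)
    return vmax * s / (km + s)


def substrate_inhibition(s, vmax, km, ki):
    s = np.asarray(s, float)
    return vmax * s / (km + s * (1.0 + s / ki))


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion for a least-squares fit."""
    if n <= k + 1:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class RateSeries:
    """Aggregated saturation data: rates on a strictly increasing substrate grid."""

    substrate_conc: np.ndarray
    rate: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.substrate_conc = np.asarray(self.substrate_conc, float)
        self.rate = np.asarray(self.rate, float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, float)
            if self.sd.shape != self.rate.shape:
                raise ValueError("sd length must match rate length")
        if self.substrate_conc.shape != self.rate.shape:
            raise ValueError("substrate and rate lengths differ")
        if np.any(self.substrate_conc < 0):
            raise ValueError("substrate concentrations must be non-negative")
        if not np.all(np.diff(self.substrate_conc) > 0):
            raise ValueError("substrate concentrations must be strictly increasing")


@dataclass
class MMParams:
    K_M: float
    V_max: float
    K_M_se: float
    V_max_se: float
    k_cat: float | None = None
    k_cat_se: float | None = None
    enzyme_conc_nM: float | None = None
    converged: bool = True
    km_indeterminate: bool = False
    aicc: float = math.nan


@dataclass
class SIParams:
    V_max: float
    K_M: float
    K_i: float
    V_max_se: float
    K_M_se: float
    K_i_se: float
    converged: bool = True
    aicc: float = math.nan
    mm: MMParams | None = None
    preferred_model: str = "si"  # by corrected AIC against the nested MM fit

    @property
    def optimum_substrate(self) -> float:
        """Substrate concentration maximizing the fitted rate, sqrt(KM·Ki)."""
        return math.sqrt(self.K_M * self.K_i)


def _validate_sv(X, y):
    s = np.asarray(X, float).reshape(-1)
    v = np.asarray(y, float).reshape(-1)
    if s.shape != v.shape:
        raise ValueError("X and y must have the same length")
    if np.any(s < 0):
        raise ValueError("substrate concentrations must be non-negative")
    if np.any(~np.isfinite(s)) or np.any(~np.isfinite(v)):
        raise ValueError("non-finite values in input")
    return s, v


def _km_guess(s, v):
    vmax0 = float(v.max())
    if vmax0 <= 0:
        return max(float(np.median(s[s > 0])) if np.any(s > 0) else 1.0, 1e-9)
    half = vmax0 / 2.0
    order = np.argsort(s)
    s_o, v_o = s[order], v[order]
    above = np.nonzero(v_o >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        s0, s1, v0, v1 = s_o[i - 1], s_o[i], v_o[i - 1], v_o[i]
        if v1 != v0:
            return max(s0 + (half - v0) * (s1 - s0) / (v1 - v0), 1e-9)
    positive = s_o[s_o > 0]
    return max(float(np.median(positive)) if positive.size else 1.0, 1e-9)


class _SaturationFitMixin:
    """Shared multi-start least-squares machinery for the two rate laws."""

    def _multi_start_fit(self, s, v, p0, bounds, sigma):
        rng = np.random.default_rng(self.random_state)
        starts = [np.asarray(p0, float)]
        for _ in range(max(self.n_starts - 1, 0)):
            starts.append(np.asarray(p0) * np.exp(rng.normal(0.0, 0.7, len(p0))))
        best = None
        for start in starts:
            try:
                popt, pcov = curve_fit(
                    self._model, s, v, p0=start, bounds=bounds, sigma=sigma,
                    maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((v - self._model(s, *popt)) ** 2))
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
        if best is None:
            raise RuntimeError(
                f"{type(self).__name__}: no start converged "
                f"(n={len(s)}, Smax={s.max():.3g}, vmax={v.max():.3g})"
            )
        popt, pcov, rss = best
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(pcov))
        return popt, se, rss


class MichaelisMentenRegressor(_SaturationFitMixin, RegressorMixin, BaseEstimator):
    """Nonlinear least-squares Michaelis–Menten fit.

    Parameters
    ----------
    n_starts:
        Number of multi-start initializations (log-spaced perturbations of the
        data-driven guess), guarding against local minima.
    random_state:
        Seed for the start perturbations.
    enzyme_conc_nM:
        When given, ``kcat_ = Vmax_ / [E]`` is reported (rates in µM/s).

    Attributes (after ``fit``)
    --------------------------
    Vmax_, Km_, Vmax_se_, Km_se_, kcat_, kcat_se_, rss_, aicc_, converged_,
    km_indeterminate_ (KM beyond 10× the highest tested S, or a confidence
    interval spanning more than two orders of magnitude — reported "NA"-style).
    """

    _model = staticmethod(michaelis_menten)

    def __init__(self, n_starts: int = 5, random_state: int = 0,
                 enzyme_conc_nM: float | None = None):
        self.n_starts = n_starts
        self.random_state = random_state
        self.enzyme_conc_nM = enzyme_conc_nM

    def fit(self, X, y, sample_weight=None):
        s, v = _validate_sv(X, y)
        if np.unique(s).size < 4:
            raise ValueError("need rates at >= 4 distinct substrate concentrations")
        if np.any(v < 0) and np.all(v <= 0):
            raise ValueError("all rates are non-positive; nothing to fit")
        sigma = None
        if sample_weight is not None:
            w = np.asarray(sample_weight, float)
            sigma = 1.0 / np.sqrt(np.clip(w, 1e-12, None))
        p0 = [max(float(v.max()), 1e-9), _km_guess(s, v)]
        bounds = ([0.0, 0.0], [np.inf, np.inf])
        popt, se, rss = self._multi_start_fit(s, v, p0, bounds, sigma)
        self.Vmax_, self.Km_ = map(float, popt)
        self.Vmax_se_, self.Km_se_ = map(float, se)
        self.rss_ = rss
        self.n_obs_ = len(s)
        self.aicc_ = aicc(rss, len(s), 2)
        self.converged_ = True
        ci_hi = self.Km_ + 1.96 * self.Km_se_
        ci_lo = self.Km_ - 1.96 * self.Km_se_
        self.km_indeterminate_ = bool(
            self.Km_ > 10.0 * s.max()
            or (np.isfinite(self.Km_se_) and ci_lo > 0 and ci_hi / ci_lo > 100.0)
            or not np.isfinite(self.Km_se_)
        )
        if self.enzyme_conc_nM is not None:
            e_uM = self.enzyme_conc_nM * 1e-3
            self.kcat_ = self.Vmax_ / e_uM
            self.kcat_se_ = self.Vmax_se_ / e_uM
        else:
            self.kcat_ = None
            self.kcat_se_ = None
        return self

    def predict(self, X):
        s = np.asarray(X, float).reshape(-1)
        return michaelis_menten(s, self.Vmax_, self.Km_)


class SubstrateInhibitionRegressor(_SaturationFitMixin, RegressorMixin, BaseEstimator):
    """Uncompetitive substrate-inhibition fit, with nested plain-MM comparison.

    After ``fit``: ``Vmax_``, ``Km_``, ``Ki_`` (+ ``*_se_``), ``rss_``,
    ``aicc_``, and ``mm_`` — a :class:`MichaelisMentenRegressor` fitted to the
    same data — with ``preferred_model_`` chosen by corrected AIC (ties go to
    the simpler MM model).
    """

    _model = staticmethod(substrate_inhibition)

    def __init__(self, n_starts: int = 5, random_state: int = 0):
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        s, v = _validate_sv(X, y)
        if np.unique(s).size < 5:
            raise ValueError("need rates at >= 5 distinct substrate concentrations")
        sigma = None
        if sample_weight is not None:
            w = np.asarray(sample_weight, float)
            sigma = 1.0 / np.sqrt(np.clip(w, 1e-12, None))
        p0 = [max(float(v.max()), 1e-9), _km_guess(s, v), max(float(s.max()), 1e-6)]
        bounds = ([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf])
        popt, se, rss = self._multi_start_fit(s, v, p0, bounds, sigma)
        self.Vmax_, self.Km_, self.Ki_ = map(float, popt)
        self.Vmax_se_, self.Km_se_, self.Ki_se_ = map(float, se)
        self.rss_ = rss
        self.n_obs_ = len(s)
        self.aicc_ = aicc(rss, len(s), 3)
        self.converged_ = True
        self.mm_ = MichaelisMentenRegressor(
            n_starts=self.n_starts, random_state=self.random_state
        ).fit(s, v, sample_weight=sample_weight)
        self.preferred_model_ = "si" if self.aicc_ < self.mm_.aicc_ else "mm"
        return self

    def predict(self, X):
        s = np.asarray(X, float).reshape(-1)
        return substrate_inhibition(s, self.Vmax_, self.Km_, self.Ki_)


def fit_michaelis_menten(
    series: RateSeries,
    enzyme_conc_nM: float | None = None,
    n_starts: int = 5,
    random_state: int = 0,
) -> MMParams:
    """Fit v = Vmax·S/(KM+S) to a rate series; kcat when enzyme conc is known."""
    reg = MichaelisMentenRegressor(
        n_starts=n_starts, random_state=random_state, enzyme_conc_nM=enzyme_conc_nM
    )
    weights = None
    if series.sd is not None and np.all(series.sd > 0):
        weights = 1.0 / series.sd**2
    reg.fit(series.substrate_conc, series.rate, sample_weight=weights)
    return MMParams(
        K_M=reg.Km_, V_max=reg.Vmax_, K_M_se=reg.Km_se_, V_max_se=reg.Vmax_se_,
        k_cat=reg.kcat_, k_cat_se=reg.kcat_se_, enzyme_conc_nM=enzyme_conc_nM,
        converged=reg.converged_, km_indeterminate=reg.km_indeterminate_,
        aicc=reg.aicc_,
    )


def fit_substrate_inhibition(
    series: RateSeries, n_starts: int = 5, random_state: int = 0
) -> SIParams:
    """Fit the substrate-inhibition law and compare against plain MM by AICc."""
    reg = SubstrateInhibitionRegressor(n_starts=n_starts, random_state=random_state)
    weights = None
    if series.sd is not None and np.all(series.sd > 0):
        weights = 1.0 / series.sd**2
    reg.fit(series.substrate_conc, series.rate, sample_weight=weights)
    mm = reg.mm_
    return SIParams(
        V_max=reg.Vmax_, K_M=reg.Km_, K_i=reg.Ki_,
        V_max_se=reg.Vmax_se_, K_M_se=reg.Km_se_, K_i_se=reg.Ki_se_,
        converged=reg.converged_, aicc=reg.aicc_,
        mm=MMParams(
            K_M=mm.Km_, V_max=mm.Vmax_, K_M_se=mm.Km_se_, V_max_se=mm.Vmax_se_,
            converged=mm.converged_, km_indeterminate=mm.km_indeterminate_,
            aicc=mm.aicc_,
        ),
        preferred_model=reg.preferred_model_,
    )


def fold_change(rate_a: float, rate_b: float) -> float:
    """Ratio rate_a / rate_b (e.g. −metal over +metal at fixed substrate)."""
    if rate_b <= 0:
        raise ValueError(
            "denominator rate is not positive; report as '> x-fold' against the "
            "assay detection floor instead of a ratio"
        )
    return rate_a / rate_b


@dataclass
class SwitchingSeries:
    """Alternating on (chelator) / off (metal) activity rounds."""

    rounds: np.ndarray
    states: list[str]
    rates: np.ndarray
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rounds = np.asarray(self.rounds, int)
        self.rates = np.asarray(self.rates, float)
        if len(self.states) != self.rates.size or self.rounds.size != self.rates.size:
            raise ValueError("rounds, states and rates must have equal length")
        bad = set(self.states) - {"on", "off"}
        if bad:
            raise ValueError(f"states must be 'on' or 'off', got {sorted(bad)}")
        for a, b in zip(self.states, self.states[1:]):
            if a == b:
                raise ValueError("states must alternate between on and off")


@dataclass
class SwitchingResult:
    mean_on: float
    mean_off: float
    dynamic_range: float
    trend_slope: float
    relative_rates: np.ndarray = field(repr=False, default=None)
    infinite: bool = False


def switching_dynamic_range(series: SwitchingSeries) -> SwitchingResult:
    """Dynamic range and degradation trend of an on/off switching series.

    Rates are normalized so the highest relative rate is 1; the dynamic range
    is mean(on rounds) / mean(off rounds) of the normalized rates, and the
    trend slope is the OLS slope of on-round relative rates versus round index
    (a stability check: 0 means no loss of activity across cycles).
    """
    states = np.asarray(series.states)
    if not (np.any(states == "on") and np.any(states == "off")):
        raise ValueError("need at least one on round and one off round")
    peak = series.rates.max()
    if peak <= 0:
        raise ValueError("all rates are non-positive; cannot normalize")
    rel = series.rates / peak
    on = rel[states == "on"]
    off = rel[states == "off"]
    mean_on = float(on.mean())
    mean_off = float(off.mean())
    if mean_off == 0.0:
        dr, infinite = math.inf, True
    else:
        dr, infinite = mean_on / mean_off, False
    on_rounds = series.rounds[states == "on"].astype(float)
    if on_rounds.size > 1:
        trend = float(np.polyfit(on_rounds, on, 1)[0])
    else:
        trend = 0.0
    return SwitchingResult(mean_on, mean_off, float(dr), trend, rel, infinite)
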