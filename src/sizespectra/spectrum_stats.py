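"""Regressions on cumulative size-biomass spectra.

Per bootstrap replicate, grid bins holding less than a biomass cutoff
(base 1e-5 Gt per bin, an order of magnitude below the least massive
group's lower biomass bound) are dropped, the remainder is
log10-transformed, and two model families are fit: ordinary
least-squares power laws (slope beta on biomass, alpha on abundance)
and sums of 1-4 Gaussian curves (nonlinear least squares, multistart).
Model comparison uses R^2 and the small-sample corrected Akaike
information criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.optimize import least_squares

__all__ = [
    "NORMALIZATION_OFFSET",
    "filter_bins",
    "fit_power_law",
    "to_abundance",
    "to_normalized",
    "fit_mixture",
    "aicc",
    "LinearFit",
    "MixtureFit",
    "RegressionSummary",
    "summarize_linear",
    "summarize_mixture",
]

# log10(10^0.5 - 10^-0.5): offset between log abundance and log
# normalized biomass for one-decade size classes
NORMALIZATION_OFFSET = math.log10(10.0**0.5 - 10.0**-0.5)

BASE_CUTOFF = 1e-5


class EmptySpectrumError(ValueError):
    """No grid point survives the biomass cutoff."""


def filter_bins(
    x: np.ndarray,
    density: np.ndarray,
    cutoff: float = BASE_CUTOFF,
    bin_width: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop bins below the biomass cutoff; return (x, log10 values).

    With ``bin_width`` given, the curve is converted from density
    (Gt per log10 size) to per-bin total biomass (Gt) before the cutoff
    and log transform — the regression response of the base analysis,
    whose minimum retained value is then exactly log10(cutoff).
    Without it, the cutoff applies to the density values themselves.
    Bins exactly at the cutoff are retained (only strictly lower values
    are removed). The cutoff guards the log transform against unbounded
    negative values.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    x = np.asarray(x, dtype=float)
    values = np.asarray(density, dtype=float)
    if bin_width is not None:
        if not bin_width > 0:
            raise ValueError("bin_width must be > 0")
        values = values * bin_width
    keep = values >= cutoff
    if not keep.any():
        raise EmptySpectrumError("all bins fall below the biomass cutoff")
    return x[keep], np.log10(values[keep])


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r2: float
    rss: float
    n_points: int

    @property
    def aicc(self) -> float:
        return aicc(self.rss, self.n_points, k_params=3)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x) + self.intercept


def fit_power_law(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """OLS of log10 density (or abundance) on log10 size."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a power-law fit")
    res = sps.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        rss=float(np.dot(resid, resid)),
        n_points=int(x.size),
    )


def to_abundance(x: np.ndarray, log_density: np.ndarray) -> np.ndarray:
    """log10 abundance = log10 biomass density - log10 size."""
    return np.asarray(log_density) - np.asarray(x)


def to_normalized(x: np.ndarray, log_density: np.ndarray) -> np.ndarray:
    """log10 normalized biomass (one-decade classes).

    Equal to log10 abundance minus log10(10^0.5 - 10^-0.5) = 0.4543, so
    its regression slope is identical to the abundance slope.
    """
    return to_abundance(x, log_density) - NORMALIZATION_OFFSET


def aicc(rss: float, n_points: int, k_params: int) -> float:
    """Corrected Akaike information criterion for a least-squares fit.

    k_params counts the curve parameters plus one for the error
    variance. Undefined (raises) when n <= k + 1.
    """
    if n_points <= k_params + 1:
        raise ValueError("AICc undefined: n_points <= k_params + 1")
    if rss <= 0:
        raise ValueError("rss must be > 0")
    n, k = n_points, k_params
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class MixtureFit:
    """Sum of Gaussian curves y = sum_i a_i exp(-((x-b_i)/c_i)^2).

    Fit on the shifted response (minimum possible value mapped to 1);
    ``shift`` is recorded so predictions can be reported unshifted.
    """

    amplitudes: np.ndarray
    centers: np.ndarray
    widths: np.ndarray
    shift: float
    rss: float
    r2: float
    n_points: int

    @property
    def n_components(self) -> int:
        return len(self.amplitudes)

    @property
    def k_params(self) -> int:
        return 3 * self.n_components + 1

    @property
    def aicc(self) -> float:
        return aicc(self.rss, self.n_points, self.k_params)

    def predict_shifted(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for a, b, c in zip(self.amplitudes, self.centers, self.widths):
            out += a * np.exp(-(((x - b) / c) ** 2))
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_shifted(x) - self.shift


def _gauss_residual_factory(x: np.ndarray, y: np.ndarray, n: int):
    def residuals(theta: np.ndarray) -> np.ndarray:
        a = theta[0::3]
        b = theta[1::3]
        c = theta[2::3]
        pred = np.einsum(
            "k,ki->i", a, np.exp(-(((x[None, :] - b[:, None]) / c[:, None]) ** 2))
        )
        return pred - y

    def jacobian(theta: np.ndarray) -> np.ndarray:
        a = theta[0::3]
        b = theta[1::3]
        c = theta[2::3]
        u = (x[None, :] - b[:, None]) / c[:, None]
        e = np.exp(-(u**2))
        J = np.empty((x.size, theta.size))
        J[:, 0::3] = e.T
        J[:, 1::3] = (a[:, None] * e * 2.0 * u / c[:, None]).T
        J[:, 2::3] = (a[:, None] * e * 2.0 * u**2 / c[:, None]).T
        return J

    return residuals, jacobian


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    cw = np.cumsum(w)
    cw = cw / cw[-1]
    return np.interp(q, cw, x)


def _mixture_starts(
    x: np.ndarray, y: np.ndarray, n: int, n_starts: int, rng: np.random.Generator
) -> list[np.ndarray]:
    span = float(x.max() - x.min())
    amp0 = float(max(y.max(), 1e-3))
    w = np.clip(y, 0.0, None) + 1e-9
    base_centers = _weighted_quantile(x, w, (np.arange(n) + 0.5) / n)
    starts = []
    for s in range(n_starts):
        theta = np.empty(3 * n)
        if s == 0:
            centers = base_centers
            widths = np.full(n, span / (2.0 * n))
        else:
            centers = _weighted_quantile(x, w, rng.uniform(0.05, 0.95, size=n))
            widths = rng.uniform(0.05, 0.6, size=n) * span
        theta[0::3] = amp0 * rng.uniform(0.5, 1.0, size=n) if s else amp0
        theta[1::3] = np.sort(centers)
        theta[2::3] = widths
        starts.append(theta)
    return starts


def fit_mixture(
    x: np.ndarray,
    y_log_density: np.ndarray,
    n_components: int,
    cutoff: float = BASE_CUTOFF,
    n_starts: int = 10,
    warm_start: "MixtureFit | Sequence[float] | None" = None,
    seed: int = 0,
) -> MixtureFit:
    """Fit a sum of 1-4 Gaussian curves to the filtered log spectrum.

    The response is shifted by 1 - log10(cutoff) (+6 for the base
    cutoff) so its minimum possible value is 1, keeping amplitudes on a
    positive scale; R^2 and AICc are computed on the shifted fit, whose
    residuals equal the unshifted ones. Trust-region least squares with
    bounded parameters (a >= 0, widths > 0, centers inside the data
    range) and multistart; a warm start (e.g. the best fit with one
    fewer component, or a neighbouring replicate's fit) is tried first
    and guarantees the n-component RSS never exceeds the warm start's.
    """
    if not 1 <= n_components <= 4:
        raise ValueError("n_components must be in 1..4")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_log_density, dtype=float)
    if x.size < 3 * n_components + 2:
        raise ValueError("too few points for this many components")
    shift = 1.0 - math.log10(cutoff)
    ys = y + shift
    resid, jac = _gauss_residual_factory(x, ys, n_components)
    rng = np.random.default_rng(seed)

    lo = np.tile([0.0, float(x.min()) - 1.0, 1e-2], n_components)
    hi = np.tile(
        [float(ys.max()) * 3.0 + 10.0, float(x.max()) + 1.0, 4.0 * float(x.max() - x.min())],
        n_components,
    )

    starts = _mixture_starts(x, ys, n_components, n_starts, rng)
    if warm_start is not None:
        if isinstance(warm_start, MixtureFit):
            theta_w = np.empty(3 * warm_start.n_components)
            theta_w[0::3] = warm_start.amplitudes
            theta_w[1::3] = warm_start.centers
            theta_w[2::3] = warm_start.widths
        else:
            theta_w = np.asarray(warm_start, dtype=float)
        if theta_w.size < 3 * n_components:
            # grow by placing new components at the largest positive residual
            n_missing = (3 * n_components - theta_w.size) // 3
            pad = np.tile([0.0, float(x.mean()), 1.0], n_missing)
            r = -resid(np.concatenate([theta_w, pad]))
            xi_new = float(x[np.argmax(r)])
            amp_new = max(float(r.max()), 1e-3)
            theta_w = np.concatenate(
                [theta_w, np.tile([amp_new, xi_new, 1.0], n_missing)]
            )
        theta_w = np.clip(theta_w[: 3 * n_components], lo, hi)
        starts.insert(0, theta_w)

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lo, hi)
        try:
            sol = least_squares(
                resid, theta0, jac=jac, bounds=(lo, hi), xtol=1e-9, ftol=1e-9,
                max_nfev=150 * n_components,
            )
        except Exception:
            continue
        rss = float(np.dot(sol.fun, sol.fun))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("mixture fit failed on every start")
    rss, theta = best
    sst = float(np.dot(ys - ys.mean(), ys - ys.mean()))
    r2 = 1.0 - rss / sst if sst > 0 else float("nan")
    return MixtureFit(
        amplitudes=theta[0::3].copy(),
        centers=theta[1::3].copy(),
        widths=theta[2::3].copy(),
        shift=shift,
        rss=rss,
        r2=r2,
        n_points=int(x.size),
    )


@dataclass(frozen=True)
class RegressionSummary:
    """Cross-replicate summary of a regression family."""

    model: str
    mean: dict
    sd: dict
    n_replicates: int
    band_x: np.ndarray | None = None
    band_lower: np.ndarray | None = None
    band_upper: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "mean": {k: float(v) for k, v in self.mean.items()},
            "sd": {k: float(v) for k, v in self.sd.items()},
            "n_replicates": self.n_replicates,
        }


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def summarize_linear(
    fits: Sequence[LinearFit],
    band_x: np.ndarray | None = None,
    model: str = "linear",
) -> RegressionSummary:
    """Means/SDs of slope, intercept, R^2 and the 95% prediction band."""
    if len(fits) < 2:
        raise ValueError("need >= 2 replicate fits to summarize")
    mean, sd = {}, {}
    for key in ("slope", "intercept", "r2"):
        m, s = _mean_sd([getattr(f, key) for f in fits])
        mean[key], sd[key] = m, s
    lower = upper = None
    if band_x is not None:
        preds = np.stack([f.predict(band_x) for f in fits])
        lower, upper = np.percentile(preds, [2.5, 97.5], axis=0)
    return RegressionSummary(
        model=model, mean=mean, sd=sd, n_replicates=len(fits),
        band_x=band_x, band_lower=lower, band_upper=upper,
    )


def summarize_mixture(
    fits: Sequence[MixtureFit],
    band_x: np.ndarray | None = None,
) -> RegressionSummary:
    if len(fits) < 2:
        raise ValueError("need >= 2 replicate fits to summarize")
    mean, sd = {}, {}
    m, s = _mean_sd([f.r2 for f in fits])
    mean["r2"], sd["r2"] = m, s
    m, s = _mean_sd([f.aicc for f in fits])
    mean["aicc"], sd["aicc"] = m, s
    lower = upper = None
    if band_x is not None:
        preds = np.stack([f.predict(band_x) for f in fits])
        lower, upper = np.percentile(preds, [2.5, 97.5], axis=0)
    return RegressionSummary(
        model=f"gauss{fits[0].n_components}",
        mean=mean, sd=sd, n_replicates=len(fits),
        band_x=band_x, band_lower=lower, band_upper=upper,
    )
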