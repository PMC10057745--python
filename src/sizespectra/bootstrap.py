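"""Two-step bootstrap propagation of biomass and median-size uncertainty.

Step one fits a truncated GEV to each group's (min, median, max)
reference sizes. Step two treats that initial fit as the uncertainty
distribution of the group's median size: per replicate, a new median is
drawn from the initial fit by inverse-CDF sampling and the group's
biomass total is redrawn from a lognormal error model whose 95% bounds
are a factor lambda from the best estimate; the distribution is then
refit with the minimum and maximum targets held at the catalog values.

Randomness is organised as one root seed with per-(replicate, group)
substreams (numpy SeedSequence spawn keys), so any replicate/group cell
is reproducible in isolation and results do not depend on iteration
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .catalog import Catalog
from .gev import FitConfig, FitResult, TruncatedGEV, fit_quantiles, refit_batch

__all__ = [
    "sample_median",
    "sample_biomass",
    "BootstrapEnsemble",
    "run_bootstrap",
]

# an SSQ this large (residuals ~ a third of a decade each) means the
# refit wandered off; the replicate's median is redrawn
_REFIT_FAIL_SSQ = 0.3
_MAX_RETRIES = 5


def sample_median(dist: TruncatedGEV, rng: np.random.Generator, size=None):
    """Draw a median log10 size from a fitted truncated GEV."""
    return dist.sample(rng, size=size)


def log10_sd(fold_uncertainty: float) -> float:
    """Lognormal sigma (log10 space) for a 95% fold-uncertainty factor."""
    if fold_uncertainty < 1:
        raise ValueError("fold uncertainty must be >= 1")
    return math.log10(fold_uncertainty) / 1.96


def sample_biomass(
    biomass: float,
    fold_uncertainty: float,
    rng: np.random.Generator,
    size=None,
):
    """Draw a biomass total in Gt C.

    The draw is B * 10**z with z ~ Normal(0, (log10 lambda / 1.96)^2),
    so ~95% of draws fall inside [B/lambda, B*lambda].
    """
    if biomass <= 0:
        raise ValueError("biomass must be > 0")
    sd = log10_sd(fold_uncertainty)
    z = rng.normal(0.0, 1.0, size=size) * sd
    return biomass * 10.0**z


def _cell_rng(seed: int, replicate: int, group: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(replicate, group))
    return np.random.Generator(np.random.PCG64(ss))


@dataclass(frozen=True)
class BootstrapEnsemble:
    """All replicates of the two-step bootstrap for one catalog.

    Arrays are indexed (replicate, group); ``params`` carries the
    refitted (mu, sigma, xi) per cell while the truncation window stays
    at the initial fit's (held min/max targets).
    """

    catalog: Catalog
    fit_config: FitConfig
    seed: int
    n_boot: int
    initial_fits: tuple[FitResult, ...]
    biomass: np.ndarray  # (n_boot, n_groups) Gt C
    medians: np.ndarray  # (n_boot, n_groups) log10 g C
    params: np.ndarray  # (n_boot, n_groups, 3): mu, sigma, xi
    ssq: np.ndarray  # (n_boot, n_groups)
    n_retried: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.catalog)

    def dist(self, replicate: int, group: int) -> TruncatedGEV:
        """Refitted truncated GEV of one (replicate, group) cell."""
        init = self.initial_fits[group].dist
        mu, sigma, xi = self.params[replicate, group]
        return TruncatedGEV(
            mu=float(mu), sigma=float(sigma), xi=float(xi),
            lower=init.lower, upper=init.upper,
        )


def initial_fits(catalog: Catalog, config: FitConfig) -> tuple[FitResult, ...]:
    """Step-one multistart quantile fits for every group."""
    return tuple(
        fit_quantiles(g.log_min, g.log_median, g.log_max, config)
        for g in catalog
    )


def run_bootstrap(
    catalog: Catalog,
    config: FitConfig = FitConfig(),
    n_boot: int = 1000,
    seed: int = 0,
    resample_median: bool = True,
) -> BootstrapEnsemble:
    """Run the full two-step bootstrap over a catalog.

    Per replicate and group, the min/max quantile targets stay at the
    catalog values while the median target is replaced by a draw from
    the group's initial fit (unless ``resample_median`` is off, a test
    mode in which uncertainty comes from biomass alone). A replicate
    whose refit fails is retried with a fresh median draw from the same
    substream, at most five times, then raises.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    fits = initial_fits(catalog, config)
    n_groups = len(catalog)
    biomass = np.empty((n_boot, n_groups))
    medians = np.empty((n_boot, n_groups))
    params = np.empty((n_boot, n_groups, 3))
    ssq = np.empty((n_boot, n_groups))
    n_retried = 0

    for gi, group in enumerate(catalog):
        init = fits[gi].dist
        rngs = [_cell_rng(seed, r, gi) for r in range(n_boot)]
        u = np.array([rng.uniform() for rng in rngs])
        z = np.array([rng.normal() for rng in rngs])
        med = init.ppf(u) if resample_median else np.full(
            n_boot, float(init.ppf(config.p_mid))
        )
        # the refit's median target must respect min <= med <= max even
        # though the sampling window extends beyond the reported range
        med = np.clip(med, group.log_min, group.log_max)
        biomass[:, gi] = group.biomass * 10.0 ** (
            z * log10_sd(group.fold_uncertainty)
        )
        p, s = refit_batch(group.log_min, group.log_max, med, init, config)
        bad = ~np.isfinite(p).all(axis=1) | (s > _REFIT_FAIL_SSQ)
        retries = 0
        while bad.any() and resample_median and retries < _MAX_RETRIES:
            retries += 1
            n_retried += int(bad.sum())
            for r in np.where(bad)[0]:
                if retries > 1:
                    # redraw a fresh median from the same substream
                    med[r] = float(
                        np.clip(
                            init.ppf(rngs[r].uniform()),
                            group.log_min,
                            group.log_max,
                        )
                    )
                # full multistart rescue for the stubborn cell
                res = fit_quantiles(
                    group.log_min, float(med[r]), group.log_max, config,
                    warm_starts=[(init.mu, init.sigma, init.xi)],
                )
                p[r] = (res.dist.mu, res.dist.sigma, res.dist.xi)
                s[r] = res.ssq
            bad = ~np.isfinite(p).all(axis=1) | (s > _REFIT_FAIL_SSQ)
        if bad.any() and resample_median:
            raise RuntimeError(
                f"refit failed for group {group.name!r} in replicates "
                f"{np.where(bad)[0][:5].tolist()}... after {_MAX_RETRIES} retries"
            )
        medians[:, gi] = med
        params[:, gi, :] = p
        ssq[:, gi] = s

    return BootstrapEnsemble(
        catalog=catalog,
        fit_config=config,
        seed=seed,
        n_boot=n_boot,
        initial_fits=fits,
        biomass=biomass,
        medians=medians,
        params=params,
        ssq=ssq,
        n_retried=n_retried,
    )
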