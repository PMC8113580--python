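"""Gaussian fits to FRET histograms, dose–response curves, and group comparisons.

The fits are weighted least-squares curve fits of a sum of Gaussians to the
binned density (the Fityk-style workflow), not sample-based mixture
estimation: per-movie histograms are the unit of replication, which makes the
across-movie SEM the natural error bar.  The dose–response model is the
three-parameter logistic f(c) = fmax / (1 + (EC50/c)^h) applied to the area
of the low-FRET (activated-state) component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .traces import FretHistogram

__all__ = [
    "GaussianComponent",
    "GaussianFit",
    "GlobalFit",
    "DoseResponseFit",
    "UnidentifiableFitError",
    "fit_gaussians",
    "global_fit",
    "fit_dose_response",
    "compare_groups",
]

_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


class UnidentifiableFitError(ValueError):
    """Raised when the data cannot constrain the model (e.g. flat dose–response)."""


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian peak: mean and sd in FRET units, area as a density fraction."""

    mean: float
    sd: float
    area: float

    @property
    def fwhm(self) -> float:
        return _FWHM_FACTOR * self.sd


@dataclass
class GaussianFit:
    components: list[GaussianComponent]
    residual: float
    success: bool
    result: lmfit.minimizer.MinimizerResult | None = field(default=None, repr=False)


@dataclass
class GlobalFit:
    """Shared means/sds across a histogram series; per-histogram areas."""

    components: list[GaussianComponent]       # shared means/sds, total areas averaged
    areas: pd.DataFrame                       # rows: histograms, cols: component index
    residual: float
    success: bool
    result: lmfit.minimizer.MinimizerResult | None = field(default=None, repr=False)

    @property
    def n_shared_params(self) -> int:
        return 2 * len(self.components)


@dataclass
class DoseResponseFit:
    ec50: float
    hill: float
    fmax: float
    ec50_se: float
    hill_se: float
    fmax_se: float


def _gauss_density(x: np.ndarray, mean: float, sd: float, area: float) -> np.ndarray:
    return area / (sd * math.sqrt(2.0 * math.pi)) * np.exp(-0.5 * ((x - mean) / sd) ** 2)


def _make_params(k: int, means: np.ndarray, sds, areas,
                 mean_bounds=(0.0, 1.0), sd_bounds=(0.01, 0.2)) -> lmfit.Parameters:
    p = lmfit.Parameters()
    for i in range(k):
        p.add(f"mean_{i}", value=float(means[i]), min=mean_bounds[0], max=mean_bounds[1])
        p.add(f"sd_{i}", value=float(sds[i]), min=sd_bounds[0], max=sd_bounds[1])
        p.add(f"area_{i}", value=float(areas[i]), min=0.0, max=2.0)
    return p


def _quantile_means(h: FretHistogram, k: int) -> np.ndarray:
    """Initial component means from k quantiles of the binned density (descending)."""
    x = h.bin_centers
    w = np.clip(h.density, 0.0, None)
    if w.sum() <= 0:
        return np.linspace(0.7, 0.3, k)
    cdf = np.cumsum(w) / w.sum()
    qs = (np.arange(k) + 0.5) / k
    means = np.interp(qs, cdf, x)
    return np.clip(np.sort(means)[::-1], 0.0, 1.0)


def _eval_sum(params: lmfit.Parameters, x: np.ndarray, k: int,
              suffix: str = "") -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(k):
        y = y + _gauss_density(x, params[f"mean_{i}"].value, params[f"sd_{i}"].value,
                               params[f"area_{i}{suffix}"].value)
    return y


def fit_gaussians(
    h: FretHistogram,
    k: int = 3,
    init_means: np.ndarray | None = None,
    weights: str = "equal",
    n_restarts: int = 3,
    seed: int = 0,
) -> GaussianFit:
    """Weighted least-squares fit of a sum of ``k`` Gaussians to a histogram.

    Multi-start from k-quantile means plus random perturbations; components are
    returned ordered by descending mean (high / middle / low FRET).
    ``weights="poisson"`` weights residuals by 1/sqrt(max(density, floor)).
    """
    if k < 1 or k > 3:
        raise ValueError("k must be in 1..3")
    if k > np.count_nonzero(h.density):
        raise ValueError("k exceeds the number of occupied bins")
    x = h.bin_centers
    y = h.density
    if weights == "poisson":
        w = 1.0 / np.sqrt(np.clip(y, np.max(y) * 1e-3, None))
    else:
        w = np.ones_like(y)

    base_means = _quantile_means(h, k) if init_means is None else np.asarray(init_means, float)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        means = base_means if r == 0 else np.clip(
            base_means + rng.normal(0.0, 0.03, k), 0.0, 1.0)
        params = _make_params(k, means, [0.05] * k, [1.0 / k] * k)

        def _resid(p):
            return (_eval_sum(p, x, k) - y) * w

        res = lmfit.minimize(_resid, params, method="leastsq")
        if best is None or res.chisqr < best.chisqr:
            best = res
    comps = sorted(
        (GaussianComponent(best.params[f"mean_{i}"].value, best.params[f"sd_{i}"].value,
                           best.params[f"area_{i}"].value) for i in range(k)),
        key=lambda c: -c.mean)
    return GaussianFit(components=comps, residual=float(np.sqrt(best.chisqr / len(x))),
                       success=bool(best.success), result=best)


def global_fit(
    series: list[FretHistogram],
    k: int = 3,
    init_means: np.ndarray | None = None,
    share_sds: bool = True,
    n_restarts: int = 3,
    seed: int = 0,
) -> GlobalFit:
    """Joint Gaussian fit across a histogram series with shared means (and sds).

    Component means (and, by default, sds) are shared across all histograms;
    areas are free per histogram.  Shared-parameter count is 2k (k means + k
    sds); each histogram adds k free areas.
    """
    if len(series) < 3:
        raise ValueError("global fit requires at least 3 histograms")
    edges = series[0].bin_edges
    for h in series[1:]:
        if not np.allclose(h.bin_edges, edges):
            raise ValueError("histograms must share bin edges")
    x = series[0].bin_centers
    pooled = FretHistogram(bin_edges=edges,
                           density=np.mean([h.density for h in series], axis=0),
                           n_molecules=0)
    base_means = _quantile_means(pooled, k) if init_means is None else np.asarray(init_means, float)

    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        means = base_means if r == 0 else np.clip(
            base_means + rng.normal(0.0, 0.03, k), 0.0, 1.0)
        params = lmfit.Parameters()
        for i in range(k):
            params.add(f"mean_{i}", value=float(means[i]), min=0.0, max=1.0)
            params.add(f"sd_{i}", value=0.05, min=0.01, max=0.2)
            if not share_sds:
                for j in range(1, len(series)):
                    params.add(f"sd_{i}_h{j}", value=0.05, min=0.01, max=0.2)
        for j in range(len(series)):
            for i in range(k):
                params.add(f"area_{i}_h{j}", value=1.0 / k, min=0.0, max=2.0)

        def _resid(p):
            out = []
            for j, h in enumerate(series):
                y = np.zeros_like(x)
                for i in range(k):
                    sd_name = f"sd_{i}" if (share_sds or j == 0) else f"sd_{i}_h{j}"
                    y = y + _gauss_density(x, p[f"mean_{i}"].value, p[sd_name].value,
                                           p[f"area_{i}_h{j}"].value)
                out.append(y - h.density)
            return np.concatenate(out)

        res = lmfit.minimize(_resid, params, method="leastsq")
        if best is None or res.chisqr < best.chisqr:
            best = res

    order = np.argsort([-best.params[f"mean_{i}"].value for i in range(k)])
    areas = pd.DataFrame(
        [[best.params[f"area_{i}_h{j}"].value for i in order] for j in range(len(series))],
        columns=list(range(k)))
    comps = [GaussianComponent(best.params[f"mean_{i}"].value,
                               best.params[f"sd_{i}"].value,
                               float(areas[rank].mean()))
             for rank, i in enumerate(order)]
    return GlobalFit(components=comps, areas=areas,
                     residual=float(np.sqrt(best.chisqr / (len(x) * len(series)))),
                     success=bool(best.success), result=best)


def _hill(c: np.ndarray, ec50: float, h: float, fmax: float) -> np.ndarray:
    return fmax / (1.0 + (ec50 / c) ** h)


def fit_dose_response(conc: np.ndarray, occupancy: np.ndarray) -> DoseResponseFit:
    """Three-parameter logistic fit of activated-state occupancy vs concentration.

    Zero-concentration points cannot sit on a log axis; the 3-parameter form
    has zero baseline by construction, so they are excluded from the fitted
    abscissa (they constrain only the baseline, which is fixed at 0).
    """
    conc = np.asarray(conc, float)
    occupancy = np.asarray(occupancy, float)
    pos = conc > 0
    c, y = conc[pos], occupancy[pos]
    if len(c) < 4:
        raise ValueError("need at least 4 positive concentrations")
    ymax = y.max()
    if ymax <= 0 or (y.min() > 0.7 * ymax) or (ymax < 0.05):
        raise UnidentifiableFitError(
            "occupancies do not span the transition; EC50 is not identifiable")
    ec50_guess = float(np.interp(0.5 * ymax, np.sort(y), c[np.argsort(y)]))
    ec50_guess = min(max(ec50_guess, c.min()), c.max())
    popt, pcov = optimize.curve_fit(
        _hill, c, y, p0=[ec50_guess, 1.0, min(ymax, 1.0)],
        bounds=([1e-9, 1e-3, 1e-6], [np.inf, 50.0, 1.0]), maxfev=20000,
        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return DoseResponseFit(ec50=float(popt[0]), hill=float(popt[1]), fmax=float(popt[2]),
                           ec50_se=float(se[0]), hill_se=float(se[1]), fmax_se=float(se[2]))


def compare_groups(a, b, paired: bool = False) -> tuple[float, float]:
    """Student's two-tailed t test (pooled variance unpaired; paired on differences).

    Degenerate zero-variance comparisons with equal means return (0, 1) by
    convention.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal group sizes")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            return (0.0, 1.0) if np.allclose(d.mean(), 0.0) else (math.inf, 0.0)
        t, p = stats.ttest_rel(a, b)
    else:
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            return (0.0, 1.0) if np.allclose(a.mean(), b.mean()) else (math.inf, 0.0)
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
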