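"""Posterior summaries of the sampler output.

Reports per parameter the posterior mean and SD, the highest posterior
density (shortest) interval, the posterior probability of a positive
value, an autocorrelation-based effective sample size and a Geweke
drift statistic; densities can be exported as normalized grid tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .gibbs import McmcSamples

__all__ = ["summarize", "hpd_interval", "density_export", "diagnostics", "effective_sample_size", "geweke_z"]


def hpd_interval(x: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    k = max(int(np.ceil(prob * n)), 2)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def effective_sample_size(x: np.ndarray) -> float:
    """Autocorrelation-time ESS (arviz bulk estimator)."""
    import arviz as az

    x = np.asarray(x, float)
    if np.std(x) == 0:
        return np.nan
    return float(az.ess(x[None, :]))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Drift z-score between the first 10% and last 50% of the chain.

    Standard errors of the two segment means use the segment ESS, so
    autocorrelation within segments is accounted for.
    """
    x = np.asarray(x, float)
    a = x[: int(first * len(x))]
    b = x[int((1 - last) * len(x)) :]
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    se2 = 0.0
    for seg in (a, b):
        ess = effective_sample_size(seg)
        if not np.isfinite(ess) or ess <= 0:
            return np.nan
        se2 += np.var(seg) / ess
    return float((a.mean() - b.mean()) / np.sqrt(se2))


def summarize(
    samples: McmcSamples | pd.DataFrame, prob: float = 0.95, min_draws: int = 100
) -> pd.DataFrame:
    """Posterior summary table over all stored parameters."""
    draws = samples.draws if isinstance(samples, McmcSamples) else samples
    cols = [c for c in draws.columns if c != "iteration"]
    if len(draws) == 0:
        raise ValueError("empty chain")
    if len(draws) < min_draws:
        raise ValueError(f"need at least {min_draws} post-burn-in draws, have {len(draws)}")
    rows = []
    for c in cols:
        x = draws[c].to_numpy(float)
        x = x[np.isfinite(x)]
        lo, hi = hpd_interval(x, prob)
        rows.append(
            {
                "parameter": c,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                "hpd_low": lo,
                "hpd_high": hi,
                "p_gt0": float(np.mean(x > 0)),
                "ess": effective_sample_size(x),
                "geweke_z": geweke_z(x),
            }
        )
    out = pd.DataFrame(rows).set_index("parameter")
    inside = (out["mean"] >= out["hpd_low"]) & (out["mean"] <= out["hpd_high"])
    if not inside.all():
        warnings.warn(
            f"posterior mean outside the HPD interval for {list(out.index[~inside])} "
            "(expected only for strongly multimodal chains)",
            stacklevel=2,
        )
    return out


def density_export(
    x: np.ndarray, grid: np.ndarray | None = None, bw: float | None = None, n_grid: int = 512
) -> pd.DataFrame:
    """Kernel density of one parameter on a grid, trapezoid-normalized.

    Bandwidth defaults to Silverman's rule via the Gaussian KDE; a
    zero-variance chain is exported as a unit spike at its value.
    """
    from scipy.stats import gaussian_kde

    x = np.asarray(x, float)
    if x.size == 0:
        raise ValueError("empty samples")
    if np.std(x) == 0:
        warnings.warn("degenerate (zero-variance) samples: exporting a spike", stacklevel=2)
        v = float(x[0])
        return pd.DataFrame({"x": [v], "density": [np.inf]})
    kde = gaussian_kde(x, bw_method=bw)
    if grid is None:
        pad = 3 * x.std()
        grid = np.linspace(x.min() - pad, x.max() + pad, n_grid)
    dens = kde(grid)
    area = np.trapezoid(dens, grid)
    return pd.DataFrame({"x": grid, "density": dens / area})


def diagnostics(samples: McmcSamples | pd.DataFrame, min_draws: int = 200) -> pd.DataFrame:
    """Per-parameter ESS and Geweke z; NaN for degenerate chains."""
    draws = samples.draws if isinstance(samples, McmcSamples) else samples
    if len(draws) < min_draws:
        raise ValueError(f"need at least {min_draws} draws for diagnostics")
    cols = [c for c in draws.columns if c != "iteration"]
    rows = []
    for c in cols:
        x = draws[c].to_numpy(float)
        rows.append(
            {"parameter": c, "ess": effective_sample_size(x), "geweke_z": geweke_z(x)}
        )
    return pd.DataFrame(rows).set_index("parameter")
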