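"""Posterior summaries: HPD intervals, marginal modes, derived contrasts."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ContrastSummary", "hpd_interval", "marginal_mode", "derived_contrasts"]


@dataclass(frozen=True)
class ContrastSummary:
    """One derived quantity: point estimate plus 95% HPD bounds."""

    name: str
    map_estimate: float
    hpd_low: float
    hpd_high: float
    posterior_mean: float

    def __post_init__(self) -> None:
        if self.hpd_low > self.hpd_high:
            raise ValueError("hpd_low must not exceed hpd_high")


def hpd_interval(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws.

    Ties in window width are broken toward the left-most window so the
    result is deterministic.
    """
    arr = np.sort(np.asarray(draws, dtype=float).ravel())
    n = arr.size
    if n < 100:
        raise ValueError(f"need at least 100 draws for an HPD interval, got {n}")
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must lie in (0, 1]")
    m = int(math.ceil(mass * n))
    if m == n:
        return float(arr[0]), float(arr[-1])
    widths = arr[m - 1:] - arr[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first (left-most) minimum
    return float(arr[i]), float(arr[i + m - 1])


def marginal_mode(draws, grid_size: int = 512) -> float:
    """Mode of a 1-D marginal estimated by a Gaussian KDE on a grid.

    Used as the point estimate for derived quantities when no joint MAP
    is supplied; degenerate (zero-variance) samples return their value.
    """
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty sample")
    if np.ptp(arr) == 0:
        return float(arr[0])
    kde = stats.gaussian_kde(arr)
    grid = np.linspace(arr.min(), arr.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])


def _contrast_values(alpha, beta, sigma=None):
    """Per-draw (or scalar) contrast definitions; alpha/beta are (..., 2)."""
    a1, a2 = alpha[..., 0], alpha[..., 1]
    b1, b2 = beta[..., 0], beta[..., 1]
    out = {
        "copper_effect_community": b1,
        "copper_effect_sbw25": b2,
        "combined_copper_effect": b1 + b2,
        "type_difference_no_copper": a2 - a1,
        "type_difference_copper": (a2 + b2) - (a1 + b1),
        "convergence_reduction": (a2 - a1) - ((a2 + b2) - (a1 + b1)),
    }
    if sigma is not None and sigma.shape[-1] == 4:
        # canonical group order: 1 community/no-Cu, 2 community/Cu,
        # 3 SBW25/no-Cu, 4 SBW25/Cu; effect = copper minus no-copper
        out["sigma_copper_effect_community"] = sigma[..., 1] - sigma[..., 0]
        out["sigma_copper_effect_sbw25"] = sigma[..., 3] - sigma[..., 2]
    return out


def derived_contrasts(draws, map_params: dict | None = None) -> list[ContrastSummary]:
    """Posterior contrasts computed element-wise over MCMC draws.

    Returns the combined copper effect (beta_1 + beta_2), the type
    differences with and without copper, their difference (the convergence
    reduction, algebraically beta_1 - beta_2), and — when the fit carries
    per-group residual SDs — the copper effect on each isolate type's SD.

    Point estimates are the contrasts evaluated at ``map_params`` when a
    joint MAP is supplied, otherwise the KDE mode of each per-draw
    distribution.  95% bounds are HPD intervals over draws.
    """
    params = draws.params if hasattr(draws, "params") else draws
    for fam in ("alpha", "beta"):
        if fam not in params:
            raise ValueError(f"draws are missing the {fam!r} family")
    alpha = np.asarray(params["alpha"], dtype=float).reshape(-1, 2)
    beta = np.asarray(params["beta"], dtype=float).reshape(-1, 2)
    sigma = None
    if "sigma" in params:
        s = np.asarray(params["sigma"], dtype=float)
        sigma = s.reshape(-1, s.shape[-1])
        if sigma.shape[-1] != 4:
            sigma = None  # SD contrasts need per-group variances

    per_draw = _contrast_values(alpha, beta, sigma)
    if map_params is not None:
        ma = np.asarray(map_params["alpha"], dtype=float)
        mb = np.asarray(map_params["beta"], dtype=float)
        ms = None
        if "sigma" in map_params:
            ms = np.asarray(map_params["sigma"], dtype=float)
            if ms.shape[-1] != 4:
                ms = None
        point = _contrast_values(ma, mb, ms)
    else:
        point = None

    out = []
    for name, vals in per_draw.items():
        lo, hi = hpd_interval(vals)
        if point is not None and name in point:
            pe = float(point[name])
        else:
            pe = marginal_mode(vals)
        out.append(
            ContrastSummary(
                name=name,
                map_estimate=pe,
                hpd_low=lo,
                hpd_high=hi,
                posterior_mean=float(vals.mean()),
            )
        )
    return out
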