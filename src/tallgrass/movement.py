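"""Forward simulation from the mechanistic redistribution kernel.

The probability that an animal steps from location *a* to *b* in one fix
interval is

    f(b | a, X) = φ(a, b; θ) · ω(X_b; β) / ∫_D φ(a, c; θ) ω(X_c; β) dc

with φ an isotropic bivariate normal density (per-axis SD θ, metres) and
ω = exp(X β) the exponential habitat-selection weight over the six
covariates (elevation, slope, cos-aspect, protein, biomass,
protein×biomass). The simulator discretizes the landscape to raster cells
and samples exactly from the normalized cell-weight distribution, so it is
an exact generative oracle for the fitted model up to cell size. Steps that
would leave the fenced enclosure are handled by renormalizing over in-mask
cells. The kernel is truncated at 6θ (mass beyond < 1e-7).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rasters import RasterStack
from .seasons import period_of

FIX_INTERVAL = dt.timedelta(hours=4)
KERNEL_TRUNCATION_SD = 6.0


@dataclass
class MovementParams:
    """Ground-truth movement model: kernel SD θ (m) and selection β (6-vector)."""

    theta: float
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.beta.shape != (6,):
            raise ValueError("beta must have 6 components")
        if not np.isfinite(self.beta).all():
            raise ValueError("beta must be finite")


@dataclass
class Trajectory:
    """Ordered GPS fixes for one individual-season (4-h interval)."""

    individual_id: str
    fixes: pd.DataFrame  # columns: timestamp, x, y

    def __post_init__(self) -> None:
        t = self.fixes["timestamp"]
        if not t.is_monotonic_increasing or t.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")

    def to_csv(self, path) -> None:
        out = self.fixes.copy()
        out.insert(0, "id", self.individual_id)
        out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")

    @classmethod
    def from_csv(cls, path, individual_id: str | None = None) -> "Trajectory":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        if individual_id is not None:
            df = df[df["id"] == individual_id]
        ids = df["id"].unique()
        if len(ids) != 1:
            raise ValueError(f"expected one individual per trajectory, found {list(ids)}")
        return cls(individual_id=str(ids[0]), fixes=df[["timestamp", "x", "y"]].reset_index(drop=True))


def bivariate_normal_density(dist2: np.ndarray, theta: float) -> np.ndarray:
    """Isotropic bivariate-normal density at squared displacement ``dist2``."""
    return np.exp(-dist2 / (2.0 * theta * theta)) / (2.0 * np.pi * theta * theta)


def step_density(a, b, theta: float, beta, covariates_at_b, normalizer: float) -> float:
    """f(b | a, X) = φ(a, b; θ)·exp(X_b β) / normalizer."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(covariates_at_b, dtype=float)
    d2 = float(np.sum((b - a) ** 2))
    return float(bivariate_normal_density(d2, theta) * np.exp(x @ beta) / normalizer)


class _PeriodCache:
    """Per-period selection-weight grids exp(Xβ) (0 on nodata cells)."""

    def __init__(self, stack: RasterStack, beta: np.ndarray):
        self.cell_size = stack.cell_size
        self.xs = stack.elevation.x_centers()
        self.ys = stack.elevation.y_centers()
        self.w_sel: dict[int, np.ndarray] = {}
        for p in stack.periods:
            valid = stack.valid_mask(p)
            if not valid.any():
                raise ValueError(f"no valid cells in period {p}")
            logw = (
                beta[0] * stack.elevation.data
                + beta[1] * stack.slope.data
                + beta[2] * stack.cos_aspect.data
                + beta[3] * stack.protein[p].data
                + beta[4] * stack.biomass[p].data
                + beta[5] * stack.protein[p].data * stack.biomass[p].data
            )
            logw = np.where(valid, logw, -np.inf)
            logw -= logw[valid].max()  # overflow guard; cancels on normalization
            self.w_sel[p] = np.exp(logw)


def discretized_step_distribution(
    a, theta: float, beta, stack: RasterStack, period: int, cache: _PeriodCache | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact next-step distribution over in-mask cells from location ``a``.

    Returns (x, y, prob) for every candidate cell within the 6θ truncation
    window; prob sums to 1. This is both the simulator's sampling law and
    the exact-summation oracle for the Monte-Carlo-normalized likelihood.
    """
    if cache is None:
        cache = _PeriodCache(stack, np.asarray(beta, dtype=float))
    lim = KERNEL_TRUNCATION_SD * theta
    xs, ys = cache.xs, cache.ys
    c0, c1 = np.searchsorted(xs, [a[0] - lim, a[0] + lim])
    r0, r1 = np.searchsorted(ys, [a[1] - lim, a[1] + lim])
    w_sel = cache.w_sel[period][r0:r1, c0:c1]
    dx2 = (xs[c0:c1] - a[0]) ** 2
    dy2 = (ys[r0:r1] - a[1]) ** 2
    d2 = dy2[:, None] + dx2[None, :]
    w = np.where(d2 <= lim * lim, np.exp(-d2 / (2 * theta * theta)), 0.0) * w_sel
    keep = w > 0
    tot = w[keep].sum()
    if tot <= 0:
        raise ValueError("no candidate cell has positive weight (all nodata or beyond 6θ)")
    rr, cc = np.nonzero(keep)
    return xs[c0:c1][cc], ys[r0:r1][rr], w[keep] / tot


def simulate_trajectory(
    start: tuple[float, float],
    params: MovementParams,
    stack: RasterStack,
    n_steps: int,
    seed: int = 0,
    start_time: dt.datetime | None = None,
    individual_id: str = "B001",
) -> Trajectory:
    """Forward-simulate ``n_steps`` four-hour steps from the redistribution
    kernel, drawing each endpoint from the discretized f(b | a, X) over
    in-mask cells of the biweekly layer containing the step's timestamp."""
    if start_time is None:
        start_time = dt.datetime(stack.year, 4, 1, 0, 0)
    x0, y0 = float(start[0]), float(start[1])
    r, c = stack.elevation.index_of(x0, y0)
    inb = stack.elevation.in_bounds(x0, y0)
    if not inb or not stack.mask[int(r), int(c)]:
        raise ValueError("start location is outside the enclosure mask")
    rng = np.random.default_rng(seed)
    cache = _PeriodCache(stack, params.beta)
    times = [start_time + i * FIX_INTERVAL for i in range(n_steps + 1)]
    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    xs[0], ys[0] = x0, y0
    for i in range(n_steps):
        p = period_of(times[i + 1])
        xv, yv, prob = discretized_step_distribution(
            (xs[i], ys[i]), params.theta, params.beta, stack, p, cache=cache
        )
        j = int(np.searchsorted(np.cumsum(prob), rng.random()))
        j = min(j, len(prob) - 1)
        xs[i + 1], ys[i + 1] = xv[j], yv[j]
    fixes = pd.DataFrame({"timestamp": pd.to_datetime(times), "x": xs, "y": ys})
    return Trajectory(individual_id=individual_id, fixes=fixes)
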