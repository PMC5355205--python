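"""Joint estimation of the movement kernel and habitat preferences.

For each observed 4-h step a→b the likelihood contribution is

    f(b | a, X) = φ(a, b; θ) · exp(X_b β) / ∫_D φ(a, c; θ) exp(X_c β) dc

The denominator integral is approximated case–control style: each observed
step is paired with control endpoints drawn from a proposal density q and
importance-weighted,

    ∫_D φ ω dc  ≈  (p̂ / n) Σ_c φ(a, c; θ) exp(X_c β) / q(c)

where p̂ is the in-mask acceptance rate of the proposal (a parameter-free
per-step constant). The default proposal is the habitat-independent kernel
itself at a pilot SD θ₀ (the Rayleigh-moment estimate from the observed
step lengths), which keeps the Monte-Carlo variance of the log-denominator
small enough at 100 controls per step for unbiased joint estimation; a
uniform-on-disk proposal with R = 3 × the maximum observed step length is
also provided as a sensitivity diagnostic. θ and β are
estimated simultaneously by quasi-Newton minimization of the negative log
likelihood over (log θ, β) with z-standardized covariates; the covariance
matrix comes from the inverse numerical Hessian at the optimum and 95%
confidence intervals are estimate ± 1.96 × SE. No intercept appears in ω —
it cancels between numerator and denominator.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .movement import FIX_INTERVAL, Trajectory
from .rasters import COVARIATE_NAMES, RasterStack
from .seasons import period_of

CI_MULTIPLIER = 1.96
PARAM_NAMES = ("theta",) + COVARIATE_NAMES


# --------------------------------------------------------------------------
# steps and controls
# --------------------------------------------------------------------------

def build_steps(
    trajectory: Trajectory,
    delta: dt.timedelta = FIX_INTERVAL,
    tolerance: dt.timedelta = dt.timedelta(minutes=15),
) -> pd.DataFrame:
    """Consecutive-fix steps whose time gap is within ``tolerance`` of
    ``delta``. Gaps break the chain; no multi-interval steps are formed.

    Returns a table with columns x0, y0, t0, x1, y1, t1, length, period.
    """
    fixes = trajectory.fixes
    if len(fixes) < 2:
        import warnings

        warnings.warn("trajectory has fewer than 2 fixes; no steps built")
        return pd.DataFrame(columns=["x0", "y0", "t0", "x1", "y1", "t1", "length", "period"])
    t = fixes["timestamp"].to_numpy()
    gaps = pd.Series(t[1:] - t[:-1])
    ok = (gaps - delta).abs() <= tolerance
    i = np.nonzero(ok.to_numpy())[0]
    x = fixes["x"].to_numpy()
    y = fixes["y"].to_numpy()
    out = pd.DataFrame(
        {
            "x0": x[i],
            "y0": y[i],
            "t0": fixes["timestamp"].iloc[i].to_numpy(),
            "x1": x[i + 1],
            "y1": y[i + 1],
            "t1": fixes["timestamp"].iloc[i + 1].to_numpy(),
        }
    )
    out["length"] = np.hypot(out.x1 - out.x0, out.y1 - out.y0)
    out["period"] = [period_of(pd.Timestamp(v)) for v in out["t1"]]
    return out


@dataclass
class ControlSet:
    """Control endpoints for one observed step."""

    parent_xy: tuple[float, float]
    points: np.ndarray        # (n, 2)
    covariates: np.ndarray    # (n, 6)
    radius: float
    acceptance_rate: float
    effective_area: float     # exact area of disk ∩ valid cells, m²

    @property
    def n(self) -> int:
        return len(self.points)


def valid_area_in_disk(stack: RasterStack, period: int, center, radius: float) -> float:
    """Exact area (m²) of valid cells whose centers lie within the disk.

    Deterministic replacement for an acceptance-rate area estimate, whose
    sampling noise would otherwise dominate the Monte-Carlo denominator."""
    g = stack.elevation
    xs, ys = g.x_centers(), g.y_centers()
    c0, c1 = np.searchsorted(xs, [center[0] - radius, center[0] + radius])
    r0, r1 = np.searchsorted(ys, [center[1] - radius, center[1] + radius])
    d2 = (ys[r0:r1, None] - center[1]) ** 2 + (xs[None, c0:c1] - center[0]) ** 2
    inside = d2 <= radius * radius
    valid = stack.valid_mask(period)[r0:r1, c0:c1]
    return float((inside & valid).sum()) * g.cell_size**2


def extract_covariates(points: np.ndarray, stack: RasterStack, timestamp) -> np.ndarray:
    """Covariate rows for planar points from the biweekly layer containing
    ``timestamp``; rows hitting nodata come back NaN."""
    period = period_of(pd.Timestamp(timestamp))
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return stack.covariates_at(pts[:, 0], pts[:, 1], period)


def _draw_disk(rng: np.random.Generator, center_x, center_y, radius, size) -> tuple[np.ndarray, np.ndarray]:
    r = radius * np.sqrt(rng.random(size))
    ang = rng.random(size) * 2 * np.pi
    return center_x + r * np.cos(ang), center_y + r * np.sin(ang)


def sample_controls(
    step_xy: tuple[float, float],
    period: int,
    stack: RasterStack,
    n: int = 100,
    radius: float = 1000.0,
    seed: int | np.random.Generator = 0,
    max_attempt_factor: int = 200,
) -> ControlSet:
    """Draw exactly ``n`` valid control endpoints uniformly on the disk of
    radius R centred at the step's start, resampling out-of-mask/nodata
    draws. Errors out if the acceptance rate falls below 1%."""
    if radius <= 0:
        raise ValueError("control radius must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cx, cy = float(step_xy[0]), float(step_xy[1])
    got_x: list[np.ndarray] = []
    got_y: list[np.ndarray] = []
    got_cov: list[np.ndarray] = []
    total = 0
    collected = 0
    while collected < n:
        batch = max(n - collected, 32) * 2
        if total > max_attempt_factor * n:
            raise RuntimeError(
                f"control acceptance rate {collected / max(total, 1):.4f} below 1%: degenerate mask"
            )
        x, y = _draw_disk(rng, cx, cy, radius, batch)
        cov = stack.covariates_at(x, y, period)
        ok = np.isfinite(cov).all(axis=1)
        total += batch
        got_x.append(x[ok])
        got_y.append(y[ok])
        got_cov.append(cov[ok])
        collected += int(ok.sum())
    x = np.concatenate(got_x)[:n]
    y = np.concatenate(got_y)[:n]
    cov = np.vstack(got_cov)[:n]
    acceptance = collected / total
    if acceptance < 0.01:
        raise RuntimeError(f"control acceptance rate {acceptance:.4f} below 1%: degenerate mask")
    return ControlSet(
        parent_xy=(cx, cy),
        points=np.column_stack([x, y]),
        covariates=cov,
        radius=radius,
        acceptance_rate=acceptance,
        effective_area=valid_area_in_disk(stack, period, (cx, cy), radius),
    )


# --------------------------------------------------------------------------
# likelihood data
# --------------------------------------------------------------------------

@dataclass
class StepData:
    """Vectorized case–control data for one individual-year.

    ``log_q`` holds each control's proposal log-density (before mask
    rejection); ``log_accept`` the per-step log acceptance rate of the
    proposal. The Monte-Carlo denominator is then
    ``exp(log_accept) / m · Σ_c φ(a,c;θ) e^{X_c β} / q(c)``.
    """

    d2_case: np.ndarray       # (n,) squared case displacement
    x_case: np.ndarray        # (n, 6)
    d2_ctrl: np.ndarray       # (n, m)
    x_ctrl: np.ndarray        # (n, m, 6)
    log_q: np.ndarray         # (n, m) proposal log-density per control
    log_accept: np.ndarray    # (n,) log in-mask acceptance rate
    radius: float             # disk radius (uniform) or pilot θ₀ (kernel)
    seed: int
    sampler: str = "kernel"
    log_q_case: np.ndarray | None = None  # (n,) proposal log-density at cases
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.d2_case)

    @property
    def n_controls(self) -> int:
        return self.d2_ctrl.shape[1]

    def mean_step_length(self) -> float:
        return float(np.sqrt(self.d2_case).mean())


def prepare_step_data(
    steps: pd.DataFrame,
    stack: RasterStack,
    n_controls: int = 100,
    sampler: str = "kernel",
    radius: float | None = None,
    radius_rule: float = 3.0,
    pilot_theta: float | None = None,
    seed: int = 0,
    max_dropped_frac: float = 0.10,
) -> StepData:
    """Pair every valid step with ``n_controls`` importance-weighted controls.

    ``sampler="kernel"`` (default) draws controls from an isotropic normal
    at the pilot SD θ₀ (Rayleigh-moment estimate from the observed step
    lengths unless ``pilot_theta`` is given); ``sampler="disk"`` draws
    uniformly on the disk of radius R = ``radius_rule`` × the maximum
    observed step length (the R-sensitivity diagnostic). Out-of-mask/nodata
    draws are resampled and the acceptance rate recorded. Steps whose case
    endpoint hits nodata are dropped and counted; the run fails if more
    than ``max_dropped_frac`` of steps are dropped.
    """
    if len(steps) == 0:
        raise ValueError("no steps to prepare")
    if sampler not in ("kernel", "disk"):
        raise ValueError("sampler must be 'kernel' or 'disk'")
    if sampler == "kernel":
        if pilot_theta is None:
            pilot_theta = float(steps["length"].mean()) / np.sqrt(np.pi / 2.0)
        if pilot_theta <= 0:
            raise ValueError("pilot theta must be positive")
        scale = pilot_theta
    else:
        if radius is None:
            radius = radius_rule * float(steps["length"].max())
        if radius <= 0:
            raise ValueError("control radius must be positive")
        scale = radius
    rng = np.random.default_rng(seed)
    case_cov = np.full((len(steps), 6), np.nan)
    for p in sorted(steps["period"].unique()):
        sel = (steps["period"] == p).to_numpy()
        case_cov[sel] = stack.covariates_at(
            steps.loc[sel, "x1"].to_numpy(), steps.loc[sel, "y1"].to_numpy(), int(p)
        )
    keep = np.isfinite(case_cov).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped > max_dropped_frac * len(steps):
        raise RuntimeError(
            f"{n_dropped}/{len(steps)} steps dropped for nodata case endpoints (> {max_dropped_frac:.0%})"
        )
    kept = steps.loc[keep].reset_index(drop=True)
    case_cov = case_cov[keep]
    n = len(kept)
    m = n_controls

    d2_ctrl = np.empty((n, m))
    x_ctrl = np.empty((n, m, 6))
    log_accept = np.empty(n)
    for p in sorted(kept["period"].unique()):
        idx = np.nonzero((kept["period"] == p).to_numpy())[0]
        cx = kept["x0"].to_numpy()[idx]
        cy = kept["y0"].to_numpy()[idx]
        k = len(idx)
        px = np.empty((k, m))
        py = np.empty((k, m))
        cov = np.full((k, m, 6), np.nan)
        need = np.ones((k, m), dtype=bool)
        draws = np.zeros(k)
        total_drawn = 0
        total_ok = 0
        while need.any():
            if total_drawn > 100 * k * m and total_ok < 0.01 * total_drawn:
                raise RuntimeError(
                    f"control acceptance rate {total_ok / total_drawn:.4f} below 1%: degenerate mask"
                )
            rows, colsel = np.nonzero(need)
            if sampler == "kernel":
                nx = cx[rows] + scale * rng.standard_normal(len(rows))
                ny = cy[rows] + scale * rng.standard_normal(len(rows))
            else:
                nx, ny = _draw_disk(rng, cx[rows], cy[rows], scale, len(rows))
            c = stack.covariates_at(nx, ny, int(p))
            ok = np.isfinite(c).all(axis=1)
            np.add.at(draws, rows, 1.0)
            total_drawn += len(rows)
            total_ok += int(ok.sum())
            rok, cok = rows[ok], colsel[ok]
            px[rok, cok] = nx[ok]
            py[rok, cok] = ny[ok]
            cov[rok, cok] = c[ok]
            need[rok, cok] = False
        acceptance = m / draws
        if np.any(acceptance < 0.01):
            raise RuntimeError("control acceptance rate below 1%: degenerate mask")
        d2 = (px - cx[:, None]) ** 2 + (py - cy[:, None]) ** 2
        d2_ctrl[idx] = d2
        x_ctrl[idx] = cov
        if sampler == "disk":
            # exact disk ∩ mask area beats the noisy acceptance-rate estimate
            areas = np.array(
                [valid_area_in_disk(stack, int(p), (cx[j], cy[j]), scale) for j in range(k)]
            )
            log_accept[idx] = np.log(areas / (np.pi * scale**2))
        else:
            # parameter-free per-step constant; estimate suffices
            log_accept[idx] = np.log(acceptance)
    if sampler == "kernel":
        log_q = -d2_ctrl / (2.0 * scale**2) - np.log(2.0 * np.pi * scale**2)
    else:
        log_q = np.full((n, m), -np.log(np.pi * scale**2))

    d2_case = ((kept["x1"] - kept["x0"]) ** 2 + (kept["y1"] - kept["y0"]) ** 2).to_numpy()
    if sampler == "kernel":
        log_q_case = -d2_case / (2.0 * scale**2) - np.log(2.0 * np.pi * scale**2)
    else:
        log_q_case = np.full(n, -np.log(np.pi * scale**2))
    return StepData(
        d2_case=d2_case,
        x_case=case_cov,
        d2_ctrl=d2_ctrl,
        x_ctrl=x_ctrl,
        log_q=log_q,
        log_accept=log_accept,
        radius=scale,
        seed=seed,
        sampler=sampler,
        log_q_case=log_q_case,
        n_dropped=n_dropped,
        meta={"n_controls": m},
    )


# --------------------------------------------------------------------------
# likelihood and fitting
# --------------------------------------------------------------------------

def negative_log_likelihood(log_theta: float, beta, data: StepData) -> float:
    """NLL of the case–control approximated step-selection likelihood.

    NLL = −Σ_steps [ log φ(a,b;θ) + X_b β
                     − log( (p̂/m) Σ_c φ(a,c;θ) e^{X_c β} / q(c) ) ]

    with q the control proposal density and p̂ its in-mask acceptance rate
    (for the uniform-disk proposal this reduces to the effective-area form
    (A_eff/m) Σ φ e^{Xβ} with A_eff = πR²·p̂).
    """
    beta = np.asarray(beta, dtype=float)
    if not (np.isfinite(log_theta) and np.isfinite(beta).all()):
        return np.inf
    if not np.isfinite(data.x_case).all() or not np.isfinite(data.x_ctrl).all():
        bad = np.nonzero(~np.isfinite(data.x_case).all(axis=1))[0]
        raise ValueError(f"non-finite covariates (first bad step index: {bad[:1]})")
    theta2 = np.exp(2.0 * log_theta)
    log_norm = -np.log(2.0 * np.pi * theta2)
    log_phi_case = -data.d2_case / (2.0 * theta2) + log_norm
    lin_case = data.x_case @ beta
    log_w_ctrl = -data.d2_ctrl / (2.0 * theta2) + log_norm + data.x_ctrl @ beta - data.log_q
    log_den = data.log_accept - np.log(data.n_controls) + logsumexp(log_w_ctrl, axis=1)
    return float(-(log_phi_case + lin_case - log_den).sum())


def choice_set_negative_log_likelihood(log_theta: float, beta, data: StepData) -> float:
    """Sampled-alternatives conditional-logit NLL (case + controls).

    Each observed endpoint competes against its own controls in a finite
    choice set, every alternative j carrying the sampling correction
    −log q(j):

        NLL = −Σ_steps [ s_b − log Σ_{j ∈ {b} ∪ C} e^{s_j} ],
        s_j = −|j−a|²/(2θ²) + X_j β − log q(j)

    Unlike the raw Monte-Carlo integral approximation this estimator is
    consistent at a *fixed* number of controls (sampled-alternatives
    theory for conditional logit), so it is the default fitting objective.
    """
    beta = np.asarray(beta, dtype=float)
    if not (np.isfinite(log_theta) and np.isfinite(beta).all()):
        return np.inf
    if data.log_q_case is None:
        raise ValueError("StepData lacks log_q_case; rebuild with prepare_step_data")
    theta2 = np.exp(2.0 * log_theta)
    s_case = -data.d2_case / (2.0 * theta2) + data.x_case @ beta - data.log_q_case
    s_ctrl = -data.d2_ctrl / (2.0 * theta2) + data.x_ctrl @ beta - data.log_q
    s_all = np.concatenate([s_case[:, None], s_ctrl], axis=1)
    return float(-(s_case - logsumexp(s_all, axis=1)).sum())


def _num_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    k = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            if i == j:
                ei = np.zeros(k)
                ei[i] = h[i]
                H[i, i] = (f(x + ei) - 2 * f(x) + f(x - ei)) / h[i] ** 2
            else:
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h[i]
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return 0.5 * (H + H.T)


@dataclass
class FitResult:
    """Joint (θ, β) estimate for one individual-year, on original covariate scale."""

    theta_hat: float
    beta_hat: np.ndarray            # (6,)
    se: np.ndarray                  # (7,) ordered (theta, beta...)
    ci_low: np.ndarray              # (7,)
    ci_high: np.ndarray             # (7,)
    covariance: np.ndarray | None   # (7, 7) or None if singular
    converged: bool
    nll: float
    n_steps: int
    label: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def estimates(self) -> np.ndarray:
        return np.concatenate([[self.theta_hat], self.beta_hat])

    def beta_ci(self, name: str) -> tuple[float, float]:
        i = PARAM_NAMES.index(name)
        return float(self.ci_low[i]), float(self.ci_high[i])

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "theta_hat": float(self.theta_hat),
            "beta_hat": {n: float(v) for n, v in zip(COVARIATE_NAMES, self.beta_hat)},
            "se": {n: float(v) for n, v in zip(PARAM_NAMES, self.se)},
            "ci_low": {n: float(v) for n, v in zip(PARAM_NAMES, self.ci_low)},
            "ci_high": {n: float(v) for n, v in zip(PARAM_NAMES, self.ci_high)},
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "converged": bool(self.converged),
            "nll": float(self.nll),
            "n_steps": int(self.n_steps),
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def fit_step_selection(
    data: StepData,
    init: np.ndarray | None = None,
    label: str = "",
    maxiter: int = 500,
    objective: str = "choice_set",
) -> FitResult:
    """Maximize the step-selection likelihood over (log θ, β).

    ``objective`` selects the sampled-alternatives conditional-logit form
    (default, consistent at 100 controls) or the raw Monte-Carlo
    ``"integral"`` approximation. Covariates are z-standardized internally
    for conditioning and the coefficients (and covariance) are
    back-transformed to the original scale. CIs are estimate ± 1.96 SE from
    the inverse numerical Hessian.
    """
    if objective not in ("choice_set", "integral"):
        raise ValueError("objective must be 'choice_set' or 'integral'")
    if data.n_steps < 50:
        import warnings

        warnings.warn(f"only {data.n_steps} steps; estimates may be unstable")
    pooled = np.vstack([data.x_case, data.x_ctrl.reshape(-1, 6)])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd[sd == 0] = 1.0
    std_data = StepData(
        d2_case=data.d2_case,
        x_case=(data.x_case - mu) / sd,
        d2_ctrl=data.d2_ctrl,
        x_ctrl=(data.x_ctrl - mu) / sd,
        log_q=data.log_q,
        log_accept=data.log_accept,
        radius=data.radius,
        seed=data.seed,
        sampler=data.sampler,
        log_q_case=data.log_q_case,
    )
    nll_fn = choice_set_negative_log_likelihood if objective == "choice_set" else negative_log_likelihood

    def obj(p: np.ndarray) -> float:
        return nll_fn(p[0], p[1:], std_data)

    if init is None:
        theta0 = max(data.mean_step_length() / np.sqrt(np.pi / 2.0), data.radius / 1e4, 1.0)
        init = np.concatenate([[np.log(theta0)], np.zeros(6)])
    res = minimize(obj, init, method="L-BFGS-B", options={"maxiter": maxiter})
    opt = res.x
    theta_hat = float(np.exp(opt[0]))
    beta_std = opt[1:]
    beta_hat = beta_std / sd

    cov_orig = None
    se = np.full(7, np.nan)
    converged = bool(res.success)
    if converged:
        H = _num_hessian(obj, opt)
        try:
            cov_std = np.linalg.inv(H)
            if not np.all(np.isfinite(cov_std)) or np.any(np.diag(cov_std) <= 0):
                raise np.linalg.LinAlgError("non-PSD Hessian inverse")
            J = np.diag(np.concatenate([[theta_hat], 1.0 / sd]))
            cov_orig = J @ cov_std @ J
            cov_orig = 0.5 * (cov_orig + cov_orig.T)
            se = np.sqrt(np.diag(cov_orig))
        except np.linalg.LinAlgError:
            converged = converged and False
            cov_orig = None

    est = np.concatenate([[theta_hat], beta_hat])
    ci_low = est - CI_MULTIPLIER * se
    ci_high = est + CI_MULTIPLIER * se
    return FitResult(
        theta_hat=theta_hat,
        beta_hat=beta_hat,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        covariance=cov_orig,
        converged=converged,
        nll=float(res.fun),
        n_steps=data.n_steps,
        label=label,
        provenance={
            "sampler": data.sampler,
            "objective": objective,
            "proposal_scale": float(data.radius),
            "seed": int(data.seed),
            "n_dropped": int(data.n_dropped),
            "n_controls": int(data.n_controls),
            "standardization": {"mean": mu.tolist(), "sd": sd.tolist()},
            "optimizer": {"nit": int(res.nit), "message": str(res.message)},
        },
    )


# --------------------------------------------------------------------------
# selection-strategy classification
# --------------------------------------------------------------------------

def classify_strategy(fit: FitResult) -> str:
    """Rule-based classification of the forage selection strategy.

    All forms require significant positive protein selection. Form 1:
    biomass selection coupled to protein (significantly positive
    protein×biomass interaction, or significantly positive biomass).
    Form 2: high protein with avoidance of high biomass (biomass CI < 0, no
    positive interaction). Form 3: protein selection with indifference to
    biomass (biomass CI spans 0). 'none': protein CI spans 0.
    """
    if not fit.converged:
        raise ValueError("cannot classify an unconverged fit")
    p_lo, p_hi = fit.beta_ci("protein")
    b_lo, b_hi = fit.beta_ci("biomass")
    i_lo, i_hi = fit.beta_ci("protein_x_biomass")
    if p_lo <= 0:
        return "none"
    if i_lo > 0 or b_lo > 0:
        return "form1"
    if b_hi < 0:
        return "form2"
    return "form3"
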