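"""Constrained nonlinear least-squares fitting of activity-pH profiles.

Fits the polyprotic ionization models of :mod:`phspec.protonation` to
(pH, % activity) observations.  pKa ordering is enforced by an
increment reparameterization (``pKa_i = pKa_{i-1} + exp(delta_i)``) and
weight nonnegativity by a squared reparameterization, so the inner
optimiser runs unconstrained.  Multimodality of the larger models is
handled with a deterministic multi-start grid plus seeded jitter.
Lack-of-fit is diagnosed with an exact Wald-Wolfowitz runs test on the
residual signs, and nested/non-nested models are ranked by AICc
filtered on residual randomness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .protonation import ProtonationScheme

__all__ = [
    "ProfileDataset",
    "ProfileModel",
    "ProfileFit",
    "RunsTestResult",
    "ModelComparison",
    "fit_profile",
    "runs_test",
    "compare_models",
    "bootstrap_ci",
]

_MIN_INCREMENT = 1e-8
_COND_LIMIT = 1e8


@dataclass(frozen=True)
class ProfileDataset:
    """(pH, % activity) observations, optionally with per-point sd."""

    ph: np.ndarray
    activity: np.ndarray
    sd: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self):
        ph = np.asarray(self.ph, dtype=float)
        act = np.asarray(self.activity, dtype=float)
        if ph.ndim != 1 or ph.shape != act.shape:
            raise ValueError("ph and activity must be 1-D arrays of equal length")
        if not np.all(np.isfinite(ph)):
            raise ValueError("pH values must be finite")
        sd = self.sd
        if sd is not None:
            sd = np.asarray(sd, dtype=float)
            if sd.shape != ph.shape:
                raise ValueError("sd must match the data length")
            if np.any(sd <= 0):
                raise ValueError("sd values must be positive")
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "activity", act)
        object.__setattr__(self, "sd", sd)

    def __len__(self) -> int:
        return self.ph.size

    @classmethod
    def from_csv(cls, path, label: str = "") -> "ProfileDataset":
        df = pd.read_csv(path)
        sd = df["sd"].to_numpy() if "sd" in df.columns else None
        return cls(df["ph"].to_numpy(), df["activity"].to_numpy(), sd, label)

    def to_csv(self, path) -> None:
        cols = {"ph": self.ph, "activity": self.activity}
        if self.sd is not None:
            cols["sd"] = self.sd
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass(frozen=True)
class ProfileModel:
    """A linear scheme template: number of sites and which species are active.

    ``active`` marks the species (fully protonated first) whose weights
    are free parameters; the rest are pinned at zero activity.
    """

    n_sites: int
    active: tuple[bool, ...]
    name: str = "general"

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if len(self.active) != self.n_sites + 1:
            raise ValueError("active mask must have n_sites + 1 entries")
        if not any(self.active):
            raise ValueError("at least one species must be active")

    @property
    def n_active(self) -> int:
        return sum(self.active)

    @property
    def n_free(self) -> int:
        return self.n_sites + self.n_active

    @classmethod
    def eq1(cls) -> "ProfileModel":
        """Two pKas, single active middle species (free amplitude)."""
        return cls(2, (False, True, False), "eq1")

    @classmethod
    def eq2(cls) -> "ProfileModel":
        """Four pKas, three active inner species (x, y, z)."""
        return cls(4, (False, True, True, True, False), "eq2")

    @classmethod
    def eq3(cls) -> "ProfileModel":
        """Three pKas, two active inner species."""
        return cls(3, (False, True, True, False), "eq3")

    @classmethod
    def general(cls, n_sites: int, active_mask: Sequence[bool]) -> "ProfileModel":
        return cls(n_sites, tuple(bool(a) for a in active_mask))


@dataclass(frozen=True)
class RunsTestResult:
    """Outcome of a Wald-Wolfowitz residual-sign runs test."""

    p: float
    n_runs: int
    n_pos: int
    n_neg: int
    degenerate: bool = False
    exact: bool = True

    def __float__(self) -> float:
        return self.p


@dataclass
class ProfileFit:
    """A fitted activity-pH model with diagnostics."""

    model: ProfileModel
    scheme: ProtonationScheme
    pkas: np.ndarray
    weights: np.ndarray           # active-species weights only
    se_pkas: np.ndarray           # NaN when unidentifiable
    se_weights: np.ndarray
    r2: float
    sse: float
    residuals: np.ndarray
    runs: RunsTestResult
    converged: bool
    n_starts: int
    data: ProfileDataset

    @property
    def runs_p(self) -> float:
        return self.runs.p

    @property
    def fitted(self) -> np.ndarray:
        return self.data.activity - self.residuals

    @property
    def aicc(self) -> float:
        n = len(self.data)
        k = self.model.n_free + 1  # + residual variance
        if n - k - 1 <= 0:
            return np.inf
        return (
            n * np.log(max(self.sse / n, 1e-300))
            + 2 * k
            + 2 * k * (k + 1) / (n - k - 1)
        )

    def summary(self) -> pd.DataFrame:
        names = [f"pKa{i + 1}" for i in range(self.model.n_sites)]
        names += [
            f"w{j}" for j, a in enumerate(self.model.active) if a
        ]
        est = np.concatenate([self.pkas, self.weights])
        se = np.concatenate([self.se_pkas, self.se_weights])
        return pd.DataFrame({"parameter": names, "estimate": est, "se": se})


# ---------------------------------------------------------------------------
# model evaluation in unconstrained parameter space

def _unpack(t: np.ndarray, model: ProfileModel) -> tuple[np.ndarray, np.ndarray]:
    n = model.n_sites
    incs = np.maximum(np.exp(t[1:n]), _MIN_INCREMENT)
    pkas = t[0] + np.concatenate([[0.0], np.cumsum(incs)])
    w_active = t[n:] ** 2
    return pkas, w_active


def _pack(pkas: np.ndarray, w_active: np.ndarray) -> np.ndarray:
    diffs = np.maximum(np.diff(pkas), _MIN_INCREMENT)
    return np.concatenate([[pkas[0]], np.log(diffs), np.sqrt(np.maximum(w_active, 0.0))])


def _full_weights(w_active: np.ndarray, model: ProfileModel) -> np.ndarray:
    w = np.zeros(model.n_sites + 1)
    w[np.asarray(model.active)] = w_active
    return w


def _fractions_raw(pkas: np.ndarray, ph: np.ndarray) -> np.ndarray:
    # same partition function as species_fractions, without scheme validation
    exponents = np.concatenate(
        [np.zeros(ph.shape + (1,)), np.cumsum(ph[..., None] - pkas, axis=-1)],
        axis=-1,
    )
    exponents -= exponents.max(axis=-1, keepdims=True)
    pop = np.exp(np.log(10.0) * exponents)
    return pop / pop.sum(axis=-1, keepdims=True)


def _predict(pkas: np.ndarray, w_active: np.ndarray, model: ProfileModel,
             ph: np.ndarray) -> np.ndarray:
    return _fractions_raw(pkas, ph) @ _full_weights(w_active, model)


# ---------------------------------------------------------------------------
# starting values

def _pka_start_grid(model: ProfileModel, ph: np.ndarray) -> list[np.ndarray]:
    lo, hi = ph.min() + 0.3, ph.max() - 0.3
    grid = np.linspace(lo, hi, model.n_sites + 2)
    return [np.array(c) for c in combinations(grid, model.n_sites)]


def _nnls_weights(pkas: np.ndarray, model: ProfileModel, ph: np.ndarray,
                  y: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Weights are linear in the model: seed them by nonnegative LS."""
    frac = _fractions_raw(pkas, ph)[:, np.asarray(model.active)]
    w, _ = optimize.nnls(frac / sd[:, None], y / sd)
    return np.maximum(w, 1e-3 * max(y.max(), 1.0))


# ---------------------------------------------------------------------------
# public operations

def fit_profile(
    data: ProfileDataset,
    model: ProfileModel,
    n_starts: Optional[int] = None,
    seed: int = 0,
) -> ProfileFit:
    """Fit ``model`` to ``data`` by weighted multi-start least squares.

    Minimises ``sum(((obs - model) / sd)**2)`` (unit sd when absent) from
    a deterministic grid of ordered pKa starting vectors (plus seeded
    jitter when ``n_starts`` exceeds the grid), returning the best
    optimum.  Standard errors come from the Gauss-Newton Jacobian at the
    optimum; when the Jacobian condition number exceeds 1e8 the fit is
    flagged unidentifiable and SEs are NaN.
    """
    n = len(data)
    if n < 2 * model.n_free:
        raise ValueError(
            f"need at least {2 * model.n_free} points to fit {model.n_free} "
            f"parameters, got {n}"
        )
    y = data.activity
    if np.ptp(y) == 0:
        raise ValueError("all activities identical: SST = 0, nothing to fit")
    sd = data.sd if data.sd is not None else np.ones(n)
    ph = data.ph

    starts = _pka_start_grid(model, ph)
    if n_starts is not None and n_starts > len(starts):
        rng = np.random.default_rng(seed)
        base = list(starts)
        while len(starts) < n_starts:
            s = base[len(starts) % len(base)] + rng.normal(0.0, 0.5, model.n_sites)
            starts.append(np.sort(s))
    if n_starts is not None:
        starts = starts[:n_starts]

    def residual(t: np.ndarray) -> np.ndarray:
        pkas, w = _unpack(t, model)
        return (y - _predict(pkas, w, model, ph)) / sd

    best = None
    any_converged = False
    for pka0 in starts:
        w0 = _nnls_weights(pka0, model, ph, y, sd)
        t0 = _pack(pka0, w0)
        try:
            sol = optimize.least_squares(
                residual, t0, method="lm", ftol=1e-10, xtol=1e-12,
                max_nfev=2000,
            )
        except Exception:
            continue
        sse = float(2.0 * sol.cost)
        if best is None or sse < best[0]:
            best = (sse, sol)
        any_converged = any_converged or sol.success
    if best is None:
        raise RuntimeError("every optimisation start failed")
    sse_w, sol = best
    if not any_converged:
        warnings.warn("no optimisation start converged; returning best candidate")

    pkas, w_active = _unpack(sol.x, model)
    fitted = _predict(pkas, w_active, model, ph)
    residuals = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / sst

    se_pkas, se_w = _standard_errors(pkas, w_active, model, ph, sd, sse_w, n)
    runs = runs_test(residuals, min_points=0)

    # guarantee a valid scheme even if two pKas collapsed numerically
    safe_pkas = np.copy(pkas)
    for i in range(1, safe_pkas.size):
        if safe_pkas[i] <= safe_pkas[i - 1]:
            safe_pkas[i] = safe_pkas[i - 1] + _MIN_INCREMENT
    w_full = _full_weights(np.maximum(w_active, 0.0), model)
    if not np.any(w_full > 0):
        w_full[np.asarray(model.active)] = 1e-12
    scheme = ProtonationScheme(safe_pkas, w_full)

    return ProfileFit(
        model=model, scheme=scheme, pkas=pkas, weights=w_active,
        se_pkas=se_pkas, se_weights=se_w, r2=r2, sse=sse_w,
        residuals=residuals, runs=runs, converged=any_converged,
        n_starts=len(starts), data=data,
    )


def _standard_errors(pkas, w_active, model, ph, sd, sse, n):
    """Gauss-Newton SEs from a numeric Jacobian in natural parameters."""
    p = model.n_free
    theta = np.concatenate([pkas, w_active])

    def pred(th):
        return _predict(th[: model.n_sites], th[model.n_sites:], model, ph) / sd

    jac = np.empty((n, p))
    for j in range(p):
        h = 1e-6 * max(abs(theta[j]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        jac[:, j] = (pred(tp) - pred(tm)) / (2 * h)
    sv = np.linalg.svd(jac, compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > _COND_LIMIT or n <= p:
        se = np.full(p, np.nan)
    else:
        cov = np.linalg.inv(jac.T @ jac) * sse / (n - p)
        se = np.sqrt(np.diag(cov))
    return se[: model.n_sites], se[model.n_sites:]


# ---------------------------------------------------------------------------
# runs test

def _runs_pmf(n_pos: int, n_neg: int) -> dict[int, float]:
    """Exact pmf of the number of sign runs under random arrangement."""
    total = comb(n_pos + n_neg, n_pos)
    pmf: dict[int, float] = {}
    for r in range(2, n_pos + n_neg + 1):
        if r % 2 == 0:
            k = r // 2
            c = 2 * comb(n_pos - 1, k - 1) * comb(n_neg - 1, k - 1)
        else:
            k = (r - 1) // 2
            c = comb(n_pos - 1, k - 1) * comb(n_neg - 1, k) + comb(
                n_pos - 1, k
            ) * comb(n_neg - 1, k - 1)
        if c:
            pmf[r] = c / total
    return pmf


def runs_test(residuals, min_points: int = 5) -> RunsTestResult:
    """Wald-Wolfowitz runs test on residual signs (zeros dropped).

    Reports the directional tail probability of the observed run count:
    ``P(R <= r)`` when fewer runs than expected (clustered residuals,
    systematic lack of fit), ``P(R >= r)`` when more (alternation).
    Exact enumeration for n <= 20, normal approximation beyond.  A
    residual vector with no sign changes available (all zero, or all one
    sign) is degenerate and returns p = 1.
    """
    res = np.asarray(residuals, dtype=float)
    signs = np.sign(res[res != 0.0])
    m = signs.size
    if m == 0:
        return RunsTestResult(1.0, 0, 0, 0, degenerate=True)
    if m < min_points:
        raise ValueError(f"need at least {min_points} nonzero residuals, got {m}")
    n_pos = int(np.sum(signs > 0))
    n_neg = m - n_pos
    n_runs = int(1 + np.sum(signs[1:] != signs[:-1]))
    if n_pos == 0 or n_neg == 0:
        return RunsTestResult(1.0, n_runs, n_pos, n_neg, degenerate=True)

    mu = 1.0 + 2.0 * n_pos * n_neg / m
    if m <= 20:
        pmf = _runs_pmf(n_pos, n_neg)
        if n_runs <= mu:
            p = sum(v for r, v in pmf.items() if r <= n_runs)
        else:
            p = sum(v for r, v in pmf.items() if r >= n_runs)
        return RunsTestResult(min(p, 1.0), n_runs, n_pos, n_neg, exact=True)
    var = (
        2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - m)
        / (m**2 * (m - 1.0))
    )
    z = (n_runs - mu) / np.sqrt(var)
    p = stats.norm.cdf(z) if n_runs <= mu else stats.norm.sf(z)
    return RunsTestResult(float(min(p, 1.0)), n_runs, n_pos, n_neg, exact=False)


# ---------------------------------------------------------------------------
# model comparison

@dataclass
class ModelComparison:
    table: pd.DataFrame
    preferred: str


def compare_models(fits: Sequence[ProfileFit]) -> ModelComparison:
    """Rank candidate fits of the same dataset.

    Preferred model: lowest AICc among fits whose residual runs test does
    not reject randomness (p > 0.05); if every fit shows structured
    residuals, lowest AICc overall.  Ties go to the model with fewer
    free parameters.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0].data
    for f in fits[1:]:
        if not (
            np.array_equal(f.data.ph, ref.ph)
            and np.array_equal(f.data.activity, ref.activity)
        ):
            raise ValueError("fits were not computed on the same dataset")
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.model.name,
                "k": f.model.n_free,
                "sse": f.sse,
                "r2": f.r2,
                "runs_p": f.runs.p,
                "aicc": f.aicc,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["runs_p"] > 0.05]
    pool = ok if len(ok) else table
    idx = pool.sort_values(["aicc", "k"]).index[0]
    return ModelComparison(table=table, preferred=str(table.loc[idx, "model"]))


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_ci(
    data: ProfileDataset,
    model: ProfileModel,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
    fit: Optional[ProfileFit] = None,
) -> dict[str, np.ndarray]:
    """Residual-resampling bootstrap percentile intervals per parameter.

    Refits each resampled dataset starting from the point estimate (one
    start), which is adequate because resampled optima stay in the basin
    of the original fit.  Returns ``{"pkas": (n_sites, 2), "weights":
    (n_active, 2)}`` lower/upper bounds.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile intervals")
    if fit is None:
        fit = fit_profile(data, model, seed=seed)
    rng = np.random.default_rng(seed)
    sd = data.sd if data.sd is not None else np.ones(len(data))
    fitted = fit.fitted
    t_hat = _pack(np.sort(fit.pkas + np.arange(fit.pkas.size) * 1e-9), fit.weights)

    boots = np.empty((n_boot, model.n_free))
    for b in range(n_boot):
        y_star = fitted + rng.choice(fit.residuals, size=len(data), replace=True)

        def residual(t):
            pkas, w = _unpack(t, model)
            return (y_star - _predict(pkas, w, model, data.ph)) / sd

        sol = optimize.least_squares(
            residual, t_hat, method="lm", ftol=1e-10, xtol=1e-12, max_nfev=2000
        )
        pkas, w = _unpack(sol.x, model)
        boots[b] = np.concatenate([pkas, w])
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1.0 - alpha, axis=0)
    ci = np.stack([lo, hi], axis=1)
    return {"pkas": ci[: model.n_sites], "weights": ci[model.n_sites:]}
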