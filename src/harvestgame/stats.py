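"""Rank-based and quantile analyses of harvesting outcomes.

Implements the analysis battery applied to trait/outcome tables:

* Spearman rank correlation (mid-rank ties, t-approximation p-values);
* partial Spearman correlation controlling one covariate (correlate the
  residuals of rank-on-rank linear fits; df = n - 3);
* the Breusch-Pagan Lagrange-multiplier test of heteroskedasticity
  (LM = n * R^2 of the auxiliary regression of squared residuals);
* linear quantile regression by exact pinball-loss minimization (linear
  program), over the 0.05..0.95 grid in steps of 0.05, with z-scored
  predictors so coefficients read as outcome units per SD, and
  participant-resampling bootstrap percentile confidence intervals;
* the replenishment-experience control: per-participant mean drawn
  replenishment fraction over the first {1,2,3,5,10,20,50,70} rounds,
  rank-correlated against both outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .game import Trajectory

__all__ = [
    "CorrelationResult",
    "BPResult",
    "QuantileFit",
    "spearman",
    "partial_spearman",
    "breusch_pagan",
    "quantile_regression",
    "quantile_profile",
    "mean_replenishment_control",
    "DEFAULT_TAUS",
    "REPLENISHMENT_WINDOWS",
]

DEFAULT_TAUS: np.ndarray = np.round(np.arange(0.05, 0.951, 0.05), 2)
REPLENISHMENT_WINDOWS: tuple[int, ...] = (1, 2, 3, 5, 10, 20, 50, 70)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    df: int
    p_value: float
    n: int
    partial_flag: bool = False
    covariate_name: str | None = None


@dataclass(frozen=True)
class BPResult:
    statistic: float
    df: int
    p_value: float
    n: int


@dataclass
class QuantileFit:
    """One quantile regression fit: tau, slope(s), intercept, 95% CIs."""

    tau: float
    coef: np.ndarray
    intercept: float
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] == 1 and x.shape[1] != len(self.coef):
            x = x.T
        return self.intercept + x @ self.coef


def _rho_p_value(rho: float, n: int, df: int) -> float:
    """Two-sided p from the t approximation with the given df."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df))


def _check_pair(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    return x, y


def spearman(x, y) -> CorrelationResult:
    """Spearman's rank correlation: Pearson correlation of mid-ranks."""
    x, y = _check_pair(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    return CorrelationResult(rho=rho, df=n - 2, p_value=_rho_p_value(rho, n, n - 2),
                             n=n)


def partial_spearman(x, y, z, covariate_name: str = "z") -> CorrelationResult:
    """Rank correlation of x and y after removing a covariate's rank effect.

    All three vectors are rank-transformed; x-ranks and y-ranks are each
    residualized on z-ranks by least squares and the residuals correlated.
    Degrees of freedom drop to n - 3. A constant covariate degenerates to
    the plain Spearman correlation (with a warning).
    """
    x, y = _check_pair(x, y, 4)
    z = np.asarray(z, dtype=float)
    if z.shape != x.shape:
        raise ValueError("covariate must match x and y in length")
    if np.ptp(z) == 0:
        warnings.warn(
            "constant covariate: falling back to the plain Spearman correlation",
            stacklevel=2,
        )
        plain = spearman(x, y)
        return CorrelationResult(
            rho=plain.rho, df=plain.df, p_value=plain.p_value, n=plain.n,
            partial_flag=False, covariate_name=None,
        )
    rx, ry, rz = sps.rankdata(x), sps.rankdata(y), sps.rankdata(z)
    design = np.column_stack([np.ones_like(rz), rz])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    rho = float(np.corrcoef(res_x, res_y)[0, 1])
    n = len(x)
    return CorrelationResult(
        rho=rho, df=n - 3, p_value=_rho_p_value(rho, n, n - 3), n=n,
        partial_flag=True, covariate_name=covariate_name,
    )


def breusch_pagan(y, x) -> BPResult:
    """Breusch-Pagan LM test: do squared residuals depend on the predictors?

    Fits y on [1, x] by least squares, regresses the squared residuals on
    the same design, and reports LM = n * R^2 of that auxiliary fit against
    a chi-square with one df per predictor.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    if n <= k + 1:
        raise ValueError("need more observations than predictors plus one")
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid2 = (y - design @ beta) ** 2
    gamma, *_ = np.linalg.lstsq(design, resid2, rcond=None)
    fitted = design @ gamma
    ss_res = float(((resid2 - fitted) ** 2).sum())
    ss_tot = float(((resid2 - resid2.mean()) ** 2).sum())
    # squared residuals constant up to rounding: no heteroskedasticity signal
    degenerate = ss_tot <= 1e-24 * n * (1.0 + float(resid2.mean()) ** 2)
    r2 = 0.0 if degenerate else 1.0 - ss_res / ss_tot
    lm = n * r2
    return BPResult(statistic=float(lm), df=k, p_value=float(sps.chi2.sf(lm, k)),
                    n=n)


def pinball_loss(y, pred, tau: float) -> float:
    """Check loss rho_tau(u) = u * (tau - 1[u < 0]), summed."""
    u = np.asarray(y, dtype=float) - np.asarray(pred, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def _solve_pinball_lp(y: np.ndarray, design: np.ndarray, tau: float) -> np.ndarray:
    """Exact quantile fit: minimize the pinball loss as a linear program.

    The primal — minimize ``tau * sum(u) + (1 - tau) * sum(v)`` over free
    coefficients beta and residual parts ``u, v >= 0`` with
    ``design @ beta + u - v = y`` — is solved through its dual,
    ``max y'lam`` subject to ``design' lam = 0`` and
    ``lam in [tau - 1, tau]^n``, which has only p equality rows; the
    coefficients are the marginals of those equality constraints.
    """
    n, p = design.shape
    res = optimize.linprog(
        -y,
        A_eq=design.T,
        b_eq=np.zeros(p),
        bounds=[(tau - 1.0, tau)] * n,
        method="highs",
        options={"presolve": False},
    )
    if not res.success:
        raise RuntimeError(f"quantile LP failed at tau={tau}: {res.message}")
    return -np.asarray(res.eqlin.marginals)


def _balance_ok(resid: np.ndarray, tau: float, n: int) -> bool:
    # optimality (subgradient) condition of the pinball loss:
    # #(resid < 0)/n <= tau <= #(resid <= 0)/n
    neg = np.sum(resid < -1e-9) / n
    nonpos = np.sum(resid <= 1e-9) / n
    return neg <= tau <= nonpos


def quantile_regression(
    y,
    predictor,
    tau: float,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    normalize: bool = False,
) -> QuantileFit:
    """Linear quantile regression by exact pinball-loss minimization.

    ``predictor`` may be a vector or an (n, p) matrix; with
    ``normalize=True`` each column is z-scored first so coefficients read
    as outcome units per predictor SD. 95% confidence intervals come from a
    participant-resampling bootstrap (percentile method, ``n_boot``
    resamples, seeded); pass ``n_boot=0`` to skip them.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie strictly between 0 and 1")
    y = np.asarray(y, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if len(y) != n:
        raise ValueError("y and predictor must have equal length")
    if normalize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot normalize a constant predictor")
        x = (x - x.mean(axis=0)) / sd
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("degenerate design matrix")
    coefs = _solve_pinball_lp(y, design, tau)
    resid = y - design @ coefs
    if not _balance_ok(resid, tau, n):
        raise RuntimeError(f"quantile balance condition violated at tau={tau}")

    ci_low = ci_high = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, design.shape[1]))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boot[b] = _solve_pinball_lp(y[idx], design[idx], tau)
        lo = np.percentile(boot, 2.5, axis=0)
        hi = np.percentile(boot, 97.5, axis=0)
        ci_low, ci_high = lo[1:], hi[1:]
    return QuantileFit(
        tau=float(tau), coef=coefs[1:], intercept=float(coefs[0]),
        ci_low=ci_low, ci_high=ci_high, n=n,
    )


def quantile_profile(
    y,
    predictor,
    taus: Sequence[float] | None = None,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    normalize: bool = True,
) -> list[QuantileFit]:
    """One quantile fit per grid point (default 0.05..0.95 step 0.05)."""
    taus = DEFAULT_TAUS if taus is None else np.asarray(taus, dtype=float)
    seed_seq = (seed if isinstance(seed, np.random.SeedSequence)
                else np.random.SeedSequence(seed))
    seeds = seed_seq.spawn(len(taus))
    return [
        quantile_regression(y, predictor, tau, n_boot=n_boot, seed=s,
                            normalize=normalize)
        for tau, s in zip(taus, seeds)
    ]


def profile_to_frame(
    fits: Sequence[QuantileFit], predictor_names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tidy table of a quantile profile: tau, predictor, coef, ci bounds."""
    rows = []
    for fit in fits:
        p = len(fit.coef)
        names = predictor_names or [f"x{j}" for j in range(p)]
        for j in range(p):
            rows.append(
                {
                    "tau": fit.tau,
                    "predictor": names[j],
                    "coef": fit.coef[j],
                    "ci_low": None if fit.ci_low is None else fit.ci_low[j],
                    "ci_high": None if fit.ci_high is None else fit.ci_high[j],
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)


def mean_replenishment_control(
    trajectories: Sequence[Trajectory],
    outcomes: pd.DataFrame,
    windows: Sequence[int] = REPLENISHMENT_WINDOWS,
) -> pd.DataFrame:
    """Did luck in the replenishment draws drive the outcomes?

    For each participant, the mean drawn replenishment fraction over the
    first ``min(window, rounds_lasted)`` rounds is rank-correlated against
    both outcomes. On default cohorts these correlations are near zero:
    outcomes are driven by the agents' policies, not by their luck.
    Degenerate windows (zero variance in means, e.g. a noiseless
    replenishment rule) are flagged with ``rho`` left missing.
    """
    if len(trajectories) != len(outcomes):
        raise ValueError("one trajectory per outcome row required")
    keep = [i for i, t in enumerate(trajectories) if t.events]
    if len(keep) < len(trajectories):
        warnings.warn(
            f"excluding {len(trajectories) - len(keep)} empty trajectories",
            stacklevel=2,
        )
    rows = []
    for window in windows:
        means = np.array(
            [trajectories[i].replenish_fractions[:window].mean() for i in keep]
        )
        for outcome in ("rounds_lasted", "total_rewards"):
            vals = outcomes[outcome].to_numpy()[keep]
            if np.ptp(means) == 0 or np.ptp(vals) == 0:
                rows.append(
                    {"window": window, "outcome": outcome, "rho": np.nan,
                     "p_value": np.nan, "n": len(keep), "degenerate": True}
                )
                continue
            result = spearman(means, vals)
            rows.append(
                {"window": window, "outcome": outcome, "rho": result.rho,
                 "p_value": result.p_value, "n": result.n, "degenerate": False}
            )
    return pd.DataFrame(rows)


def plot_quantile_profile(fits: Sequence[QuantileFit], ax=None, label=None):
    """Coefficient-vs-quantile plot with 95% bands (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    taus = [f.tau for f in fits]
    coefs = [f.coef[0] for f in fits]
    ax.plot(taus, coefs, "o-", label=label)
    if fits[0].ci_low is not None:
        lo = [f.ci_low[0] for f in fits]
        hi = [f.ci_high[0] for f in fits]
        ax.fill_between(taus, lo, hi, alpha=0.25)
    ax.axhline(0.0, color="red", linestyle=":")
    ax.set_xlabel("quantile")
    ax.set_ylabel("coefficient (outcome units per SD)")
    return ax
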