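"""Maximum-likelihood inference of seeding influxes from clone frequencies.

Observed data are clone frequencies ``gamma_ij`` of clone ``i`` in tumor
sample ``j``.  Under the consecutive-seeding model each sample's frequency
vector is an independent Dirichlet draw with concentrations
``k_ij = gamma_bar_i * k_j``, where ``gamma_bar`` is the clone composition of
the source (primary) tumor and ``k_j`` the total seeding influx into sample
``j``.  The MLE satisfies the stationarity conditions

    sum_i gamma_bar_i * beta_ij = 0   for every sample j,
    sum_j k_j * beta_ij        = 0   for every clone i,

with ``beta_ij = ln(gamma_ij) - [psi(k_ij) - psi(k_j)]`` the sample bias of
the log-scaled frequencies.  When the primary composition is known, the first
family alone determines each ``k_j`` by a monotone one-dimensional root solve
in ``ln k_j``; otherwise the two families are solved jointly by block
coordinate ascent (both blocks are exact maximizations of a concave
objective, so the log-likelihood is nondecreasing across iterations).

Uncertainty: ``Var(ln k_hat_j) = sigma_j^2 = alpha/(N-1)`` with the regime
constant ``alpha`` between 1 (high KL divergence between sample and primary)
and 2 (low divergence).  The observed-information interpolation
``alpha = (N-1) / (k^2 I(k))`` with
``I(k) = sum_i gamma_bar_i^2 psi'(k gamma_bar_i) - psi'(k)`` reproduces both
limits exactly and is used by default; the KL-based fast approximation
``k_hat ~ (N-1)/(alpha D_KL)`` and its [1, 2] bracket are also exposed.

Usage (statsmodels flavor)::

    model = SeedingInfluxModel(freq_matrix, gamma_bar=None)  # joint MLE
    res = model.fit()
    print(res.summary())
    res.k_hat, res.conf_int(), res.kl, res.seeded_cells(rho=0.05, Y=1e8)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import digamma, gammaln, polygamma, xlogy

from .params import ClonalComposition, as_composition

__all__ = [
    "CohortMatrix",
    "SeedingInfluxModel",
    "SeedingInfluxResults",
    "ConvergenceError",
    "dirichlet_loglik",
    "kl_divergence",
    "beta_residuals",
    "influx_fast_approx",
    "information_alpha",
    "confidence_interval",
    "estimate_influx_known_primary",
    "estimate_joint",
    "seeded_cells_from_estimate",
]

logger = logging.getLogger(__name__)

DEFAULT_CAP = 1e3


class ConvergenceError(RuntimeError):
    """Joint estimation failed to converge; carries the last residuals."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


# ---------------------------------------------------------------------------
# data container


class CohortMatrix:
    """Clones x samples matrix of clone frequencies ``gamma_ij``.

    Each column is one tumor sample and must sum to one (renormalized with a
    logged warning when off by at most ``tol``; rejected when worse).
    """

    def __init__(self, freqs, clone_labels=None, sample_labels=None, tol=1e-6):
        freqs = np.asarray(freqs, dtype=float)
        if freqs.ndim != 2:
            raise ValueError("freqs must be a 2-D (clones x samples) matrix")
        if np.any(freqs < 0) or np.any(freqs > 1) or not np.all(np.isfinite(freqs)):
            raise ValueError("frequencies must be finite and lie in [0, 1]")
        sums = freqs.sum(axis=0)
        if np.any(sums <= 0):
            raise ValueError("every sample column must have positive total frequency")
        off = np.abs(sums - 1.0)
        if np.any(off > tol):
            bad = np.flatnonzero(off > tol)
            logger.warning(
                "renormalizing %d sample column(s) whose frequencies did not "
                "sum to 1 (max deviation %.3g)", bad.size, off.max(),
            )
        self.freqs = freqs / sums
        n, m = freqs.shape
        self.clone_labels = (
            list(clone_labels) if clone_labels is not None
            else [f"clone_{i}" for i in range(n)]
        )
        self.sample_labels = (
            list(sample_labels) if sample_labels is not None
            else [f"sample_{j}" for j in range(m)]
        )
        if len(self.clone_labels) != n or len(self.sample_labels) != m:
            raise ValueError("label lengths must match the matrix shape")

    @property
    def n_clones(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.freqs.shape[1]

    def sample(self, j: int) -> np.ndarray:
        return self.freqs[:, j]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, tol=1e-6) -> "CohortMatrix":
        return cls(
            df.to_numpy(dtype=float),
            clone_labels=list(df.index.astype(str)),
            sample_labels=list(df.columns.astype(str)),
            tol=tol,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freqs, index=self.clone_labels, columns=self.sample_labels
        )


def _as_cohort(data) -> CohortMatrix:
    if isinstance(data, CohortMatrix):
        return data
    if isinstance(data, pd.DataFrame):
        return CohortMatrix.from_dataframe(data)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return CohortMatrix(arr)


# ---------------------------------------------------------------------------
# likelihood primitives


def dirichlet_loglik(gamma_bar, k_j: float, sample) -> float:
    """Dirichlet log-density of one sample with concentrations ``k_j * gamma_bar``."""
    g_bar = as_composition(gamma_bar).freqs
    g = np.asarray(sample, dtype=float)
    if np.any(g <= 0):
        raise ValueError(
            "sample frequencies must be strictly positive; apply a zero policy first"
        )
    conc = k_j * g_bar
    return float(
        gammaln(k_j) - gammaln(conc).sum() + np.sum(xlogy(conc - 1.0, g))
    )


def kl_divergence(gamma_bar, sample) -> float:
    """``D_KL(gamma_bar || gamma_j) = sum_i gbar_i ln(gbar_i / gamma_ij)``."""
    g_bar = as_composition(gamma_bar).freqs
    g = np.asarray(sample, dtype=float)
    support = g_bar > 0
    if np.any(g[support] <= 0):
        raise ValueError(
            "sample has a zero frequency where the primary composition is "
            "positive; apply a zero policy first"
        )
    gb = g_bar[support]
    return float(np.sum(gb * np.log(gb / g[support])))


def beta_residuals(gamma_bar, k_j: float, sample) -> np.ndarray:
    """Per-clone sample bias ``beta_ij = ln(gamma_ij) - [psi(k_ij) - psi(k_j)]``."""
    g_bar = as_composition(gamma_bar).freqs
    g = np.asarray(sample, dtype=float)
    return np.log(g) - (digamma(k_j * g_bar) - digamma(k_j))


def _score_lnk(lnk: float, g_bar: np.ndarray, log_g: np.ndarray) -> float:
    """sum_i gbar_i beta_ij at ln k; monotone decreasing from +inf to -D_KL."""
    k = np.exp(lnk)
    return float(np.sum(g_bar * (log_g - digamma(k * g_bar))) + digamma(k))


def _solve_known_primary(g_bar: np.ndarray, sample: np.ndarray, cap: float):
    """Root of the known-primary stationarity condition on ln k.

    Returns (k_hat, degenerate): the score decreases monotonically from +inf
    (k -> 0) to -D_KL (k -> inf), so a root exists iff D_KL > 0; samples
    (nearly) identical to the primary push the root beyond any bound and are
    capped with a degenerate flag.
    """
    log_g = np.log(sample)
    dkl = float(np.sum(g_bar * (np.log(g_bar) - log_g)))
    if dkl <= 0:
        return cap, True
    lo, hi = np.log(1e-8), np.log(cap)
    if _score_lnk(hi, g_bar, log_g) > 0:  # still climbing at the cap
        return cap, True
    while _score_lnk(lo, g_bar, log_g) < 0:  # pragma: no cover - tiny k guard
        lo -= 5.0
        if lo < -60:
            return np.exp(lo), True
    lnk = brentq(_score_lnk, lo, hi, args=(g_bar, log_g), xtol=1e-13, rtol=1e-15)
    return float(np.exp(lnk)), False


def information_alpha(gamma_bar, k_hat: float) -> float:
    """Regime constant ``alpha = (N-1) / (k^2 I(k))`` from the observed
    curvature of the Dirichlet log-likelihood in ``ln k``.

    ``I(k) = sum_i gbar_i^2 psi'(k gbar_i) - psi'(k)`` is the Fisher
    information for ``k``; the ratio tends to 1 as ``k -> 0`` (high
    divergence) and to 2 as ``k -> inf`` (low divergence), matching the two
    regime extremes, and is clipped to [1, 2].
    """
    g_bar = as_composition(gamma_bar).freqs
    n = g_bar.size
    if n < 2:
        raise ValueError("alpha requires at least two clones")
    info = float(
        np.sum(g_bar**2 * polygamma(1, k_hat * g_bar)) - polygamma(1, k_hat)
    )
    if info <= 0:
        return 2.0
    return float(np.clip((n - 1) / (k_hat**2 * info), 1.0, 2.0))


def influx_fast_approx(gamma_bar, sample):
    """Fast KL approximation ``k_hat ~ (N-1)/(alpha D_KL)``.

    Returns ``(k_approx, (k_low, k_high))`` where the bracket uses the two
    regime extremes alpha=2 (low bound) and alpha=1 (high bound).  The point
    value interpolates alpha log-linearly in D_KL between the stated regime
    boundaries ``N^2 min_i gbar_i`` (low divergence, alpha=2) and ``N``
    (high divergence, alpha=1).
    """
    g_bar = as_composition(gamma_bar).freqs
    n = g_bar.size
    dkl = kl_divergence(g_bar, sample)
    if dkl <= 0:
        raise ValueError("zero KL divergence: the influx estimate diverges")
    lo_bound = n**2 * float(g_bar.min())
    hi_bound = float(n)
    low, high = sorted((lo_bound, hi_bound))
    if dkl <= low:
        alpha = 2.0
    elif dkl >= high:
        alpha = 1.0
    elif high == low:  # pragma: no cover - degenerate window
        alpha = 1.5
    else:
        frac = (np.log(dkl) - np.log(low)) / (np.log(high) - np.log(low))
        alpha = 2.0 - frac
    k_approx = (n - 1) / (alpha * dkl)
    bracket = ((n - 1) / (2.0 * dkl), (n - 1) / dkl)
    return float(k_approx), bracket


def confidence_interval(k_hat: float, n_clones: int, alpha: float,
                        level: float = 0.95):
    """Multiplicative CI ``k_hat * exp(+- z sigma)`` with ``sigma^2 = alpha/(N-1)``."""
    if n_clones < 2:
        raise ValueError("confidence interval requires at least two clones")
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    sigma = np.sqrt(alpha / (n_clones - 1))
    return float(k_hat * np.exp(-z * sigma)), float(k_hat * np.exp(z * sigma))


# ---------------------------------------------------------------------------
# zero handling


def apply_zero_policy(freqs: np.ndarray, policy: str = "floor"):
    """Make all frequencies strictly positive, column by column.

    ``floor``: zeros are set to half the smallest nonzero frequency in that
    sample and the column is renormalized (the least-informative completion
    that preserves normalization).  ``error``: raise.  ``drop`` is handled at
    the cohort level (rows absent from every sample are removed there).
    """
    out = np.array(freqs, dtype=float, copy=True)
    n_floored = 0
    for j in range(out.shape[1]):
        col = out[:, j]
        zeros = col == 0.0
        if not zeros.any():
            continue
        if policy == "error":
            raise ValueError(
                f"sample column {j} contains zero frequencies "
                "(zero_policy='error')"
            )
        eps = 0.5 * col[~zeros].min()
        col[zeros] = eps
        out[:, j] = col / col.sum()
        n_floored += int(zeros.sum())
    if n_floored:
        logger.warning(
            "floored %d zero frequencies to half the per-sample minimum "
            "and renormalized", n_floored,
        )
    return out


# ---------------------------------------------------------------------------
# Model / Results


class SeedingInfluxModel:
    """MLE of per-sample seeding influxes from a clone-frequency matrix.

    Parameters
    ----------
    cohort : CohortMatrix, DataFrame or (clones x samples) array
        Observed clone frequencies; columns are tumor samples.
    gamma_bar : array-like, optional
        Known clone composition of the primary tumor.  When omitted the
        composition is estimated jointly with the influxes (requires at
        least two samples).
    zero_policy : {"floor", "drop", "error"}
        How zero frequencies are made strictly positive before evaluating
        ``ln gamma_ij``.  ``drop`` removes clones absent from *every* sample,
        then floors any remaining per-sample zeros.
    cap : float
        Influx value returned (with a degenerate flag) when the estimate
        diverges, i.e. when a sample is (nearly) identical to the primary
        composition.
    """

    def __init__(self, cohort, gamma_bar=None, zero_policy="floor",
                 cap=DEFAULT_CAP):
        if zero_policy not in ("floor", "drop", "error"):
            raise ValueError("zero_policy must be 'floor', 'drop' or 'error'")
        self.cohort = _as_cohort(cohort)
        if self.cohort.n_clones < 2:
            raise ValueError("inference requires at least two clones")
        self.zero_policy = zero_policy
        self.cap = float(cap)

        freqs = self.cohort.freqs
        clone_labels = list(self.cohort.clone_labels)
        if zero_policy == "drop":
            keep = freqs.sum(axis=1) > 0
            if keep.sum() < 2:
                raise ValueError("fewer than two clones present in the cohort")
            if not keep.all():
                logger.warning(
                    "dropping %d clone(s) absent from every sample",
                    int((~keep).sum()),
                )
            freqs = freqs[keep] / freqs[keep].sum(axis=0)
            clone_labels = [c for c, k in zip(clone_labels, keep) if k]
        self._freqs = apply_zero_policy(
            freqs, "error" if zero_policy == "error" else "floor"
        )
        self._clone_labels = clone_labels

        if gamma_bar is not None:
            g = as_composition(gamma_bar).freqs
            if g.size != self._freqs.shape[0]:
                raise ValueError(
                    "gamma_bar must have one entry per (retained) clone"
                )
            if np.any(g <= 0):
                raise ValueError("gamma_bar entries must be strictly positive")
            self.gamma_bar = g
        else:
            self.gamma_bar = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SeedingInfluxModel":
        return cls(CohortMatrix.from_dataframe(df), **kwargs)

    # -- likelihood pieces --------------------------------------------

    def loglike(self, gamma_bar: np.ndarray, k: np.ndarray) -> float:
        return float(
            sum(
                dirichlet_loglik(gamma_bar, k[j], self._freqs[:, j])
                for j in range(self._freqs.shape[1])
            )
        )

    def _solve_all_k(self, g_bar: np.ndarray):
        m = self._freqs.shape[1]
        k = np.empty(m)
        degen = np.zeros(m, dtype=bool)
        for j in range(m):
            k[j], degen[j] = _solve_known_primary(
                g_bar, self._freqs[:, j], self.cap
            )
        return k, degen

    def _update_gamma_bar(self, k: np.ndarray) -> np.ndarray:
        """Exact maximizer of the log-likelihood over the simplex, k fixed.

        The objective is concave in gamma_bar; the interior KKT conditions
        ``sum_j k_j [ln g_ij - psi(k_j gbar_i)] = mu`` are solved by a nested
        root search: for a trial multiplier mu each gbar_i is the root of a
        decreasing scalar function, and mu is adjusted until the gbar_i sum
        to one.
        """
        log_g = np.log(self._freqs)  # (n, m)
        a = log_g @ k  # sum_j k_j ln gamma_ij, per clone
        k_total = float(k.sum())

        def gbar_of_mu(mu):
            out = np.empty(a.size)
            for i in range(a.size):
                def h(x, i=i):
                    return a[i] - float(np.sum(k * digamma(k * x))) - mu
                lo, hi = 1e-12, 1.0
                if h(hi) >= 0:
                    out[i] = hi
                    continue
                while h(lo) < 0:  # pragma: no cover - extreme underflow guard
                    lo *= 1e-3
                    if lo < 1e-300:
                        break
                out[i] = brentq(h, lo, hi, xtol=1e-15, rtol=1e-15)
            return out

        # sum_i gbar_i(mu) decreases in mu; bracket the root
        mu_lo = float(a.min() - np.sum(k * digamma(k)) - 10.0)
        mu_hi = float(a.max() - np.sum(k * digamma(k * 1e-12)))
        while gbar_of_mu(mu_lo).sum() < 1.0:  # pragma: no cover
            mu_lo -= 20.0
        while gbar_of_mu(mu_hi).sum() > 1.0:  # pragma: no cover
            mu_hi += 20.0
        mu = brentq(lambda m_: gbar_of_mu(m_).sum() - 1.0, mu_lo, mu_hi,
                    xtol=1e-13, rtol=1e-15)
        g = gbar_of_mu(mu)
        return g / g.sum()

    # -- fitting -------------------------------------------------------

    def fit(self, maxiter: int = 500, tol: float = 1e-10) -> "SeedingInfluxResults":
        freqs = self._freqs
        n, m = freqs.shape
        if self.gamma_bar is not None:
            g_bar = self.gamma_bar
            k, degen = self._solve_all_k(g_bar)
            history = [self.loglike(g_bar, k)]
            converged, n_iter = True, 1
        else:
            if m < 2:
                raise ValueError(
                    "joint estimation of the primary composition requires at "
                    "least two samples; pass gamma_bar for a single sample"
                )
            g_bar = freqs.mean(axis=1)
            g_bar = g_bar / g_bar.sum()
            history = []
            converged = False
            k = degen = None
            for n_iter in range(1, maxiter + 1):
                k, degen = self._solve_all_k(g_bar)
                g_bar = self._update_gamma_bar(k)
                ll = self.loglike(g_bar, k)
                history.append(ll)
                if len(history) > 1:
                    prev = history[-2]
                    if abs(ll - prev) <= tol * (abs(prev) + 1.0):
                        converged = True
                        break
            if not converged:
                resid = self._residuals(g_bar, k)
                raise ConvergenceError(
                    f"joint estimation did not converge in {maxiter} "
                    f"iterations (last max residuals: clone "
                    f"{resid['max_clone_residual']:.3g}, sample "
                    f"{resid['max_sample_residual']:.3g})",
                    residuals=resid,
                )
            # final k solve against the converged composition, then a Newton
            # polish of the full stationarity system (block ascent plateaus
            # in the objective while the gradients are still ~1e-3)
            k, degen = self._solve_all_k(g_bar)
            g_bar, k = self._polish(g_bar, k, degen)
            history.append(self.loglike(g_bar, k))

        alpha = np.array([information_alpha(g_bar, kj) for kj in k])
        sigma2 = alpha / (n - 1)
        kl = np.array([kl_divergence(g_bar, freqs[:, j]) for j in range(m)])
        residuals = self._residuals(g_bar, k)
        return SeedingInfluxResults(
            model=self,
            k_hat=k,
            gamma_bar=g_bar,
            alpha=alpha,
            sigma2=sigma2,
            kl=kl,
            degenerate=degen,
            residuals=residuals,
            loglike=history[-1],
            objective_history=np.asarray(history),
            converged=converged,
            n_iter=n_iter,
        )

    def _polish(self, g_bar: np.ndarray, k: np.ndarray, degen: np.ndarray):
        """Newton solve of the joint stationarity system from the block-ascent
        point: sample conditions for every non-capped sample, the KKT
        conditions for gamma_bar (with an explicit simplex multiplier), and
        the normalization.  Capped (degenerate) influxes stay pinned."""
        from scipy.optimize import root

        freqs = self._freqs
        log_g = np.log(freqs)
        free = ~degen
        m_free = int(free.sum())
        n = g_bar.size
        k_fixed = k.copy()

        def system(x):
            kf = np.exp(x[:m_free])
            g = x[m_free:m_free + n]
            mu = x[-1]
            kk = k_fixed.copy()
            kk[free] = kf
            beta = log_g - (digamma(np.outer(g, kk)) - digamma(kk)[None, :])
            f_samples = g @ beta[:, free]
            # d loglike / d gbar_i - mu
            f_clones = log_g @ kk - digamma(np.outer(g, kk)) @ kk - mu
            return np.concatenate([f_samples, f_clones, [g.sum() - 1.0]])

        mu0 = float(np.mean(log_g @ k - digamma(np.outer(g_bar, k)) @ k))
        x0 = np.concatenate([np.log(k[free]), g_bar, [mu0]])
        sol = root(system, x0, method="hybr", tol=1e-13)
        g_new = sol.x[m_free:m_free + n]
        if (not sol.success or np.any(g_new <= 0)
                or abs(g_new.sum() - 1.0) > 1e-8):
            logger.warning("stationarity polish failed; keeping block-ascent fit")
            return g_bar, k
        k_new = k_fixed.copy()
        k_new[free] = np.exp(sol.x[:m_free])
        return g_new / g_new.sum(), k_new

    def _residuals(self, g_bar: np.ndarray, k: np.ndarray) -> dict:
        n, m = self._freqs.shape
        beta = np.empty((n, m))
        for j in range(m):
            beta[:, j] = beta_residuals(g_bar, k[j], self._freqs[:, j])
        sample_resid = g_bar @ beta  # one per sample j
        clone_resid = beta @ k  # one per clone i
        return {
            "beta": beta,
            "sample_residuals": sample_resid,
            "clone_residuals": clone_resid,
            "max_sample_residual": float(np.abs(sample_resid).max()),
            "max_clone_residual": float(np.abs(clone_resid).max()),
        }


@dataclass
class SeedingInfluxResults:
    """Estimates, uncertainties and diagnostics from :class:`SeedingInfluxModel`.

    ``k_hat[j]`` is the MLE total seeding influx into sample ``j`` (cells per
    generation); ``sigma2[j] = alpha_j/(N-1)`` its log-scale variance;
    ``kl[j]`` the KL divergence of the sample from the (known or estimated)
    primary composition.  Degenerate entries mark samples whose estimate
    diverged (composition ~ identical to the primary) and was capped.
    """

    model: SeedingInfluxModel
    k_hat: np.ndarray
    gamma_bar: np.ndarray
    alpha: np.ndarray
    sigma2: np.ndarray
    kl: np.ndarray
    degenerate: np.ndarray
    residuals: dict
    loglike: float
    objective_history: np.ndarray
    converged: bool
    n_iter: int
    level: float = field(default=0.95)

    @property
    def sample_labels(self):
        return self.model.cohort.sample_labels

    @property
    def clone_labels(self):
        return self.model._clone_labels

    @property
    def n_clones(self) -> int:
        return self.gamma_bar.size

    def conf_int(self, level: float | None = None) -> pd.DataFrame:
        level = self.level if level is None else level
        bounds = [
            confidence_interval(kj, self.n_clones, aj, level)
            for kj, aj in zip(self.k_hat, self.alpha)
        ]
        return pd.DataFrame(
            bounds, index=self.sample_labels, columns=["ci_low", "ci_high"]
        )

    @property
    def ci_low(self) -> np.ndarray:
        return self.conf_int().to_numpy()[:, 0]

    @property
    def ci_high(self) -> np.ndarray:
        return self.conf_int().to_numpy()[:, 1]

    def seeded_cells(self, rho: float, detect_size) -> pd.DataFrame:
        """Per-sample surviving seeded cells ``X_j = k_j [ln(rho Y) - psi(k_j)]``.

        Degenerate (capped) estimates are excluded from the cohort mean/SD
        but reported row-wise with their flag.
        """
        ry = float(rho) * float(detect_size)
        if ry <= 1.0:
            raise ValueError("requires rho * Y > 1")
        x = self.k_hat * (np.log(ry) - digamma(self.k_hat))
        df = pd.DataFrame(
            {"k_hat": self.k_hat, "seeded_cells": x, "degenerate": self.degenerate},
            index=self.sample_labels,
        )
        ok = ~self.degenerate
        df.attrs["mean"] = float(x[ok].mean()) if ok.any() else float("nan")
        df.attrs["sd"] = float(x[ok].std(ddof=1)) if ok.sum() > 1 else float("nan")
        return df

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "k_hat": self.k_hat,
                "ci_low": ci["ci_low"],
                "ci_high": ci["ci_high"],
                "sigma2": self.sigma2,
                "alpha": self.alpha,
                "kl_divergence": self.kl,
                "degenerate": self.degenerate,
            },
            index=self.sample_labels,
        )

    def summary(self) -> str:
        lines = [
            "Consecutive-seeding influx estimates (Dirichlet MLE)",
            "=" * 64,
            f"samples: {len(self.sample_labels)}   clones: {self.n_clones}   "
            f"log-likelihood: {self.loglike:.4f}",
            f"primary composition "
            f"{'known' if self.model.gamma_bar is not None else 'jointly estimated'}; "
            f"converged in {self.n_iter} iteration(s)",
            "max stationarity residuals: "
            f"sample {self.residuals['max_sample_residual']:.2e}"
            + (
                f", clone {self.residuals['max_clone_residual']:.2e}"
                if self.model.gamma_bar is None
                else "  (clone conditions apply to joint fits only)"
            ),
            "-" * 64,
            self.to_frame().to_string(float_format=lambda v: f"{v:.4g}"),
            "-" * 64,
            "gamma_bar: "
            + ", ".join(
                f"{c}={g:.4g}" for c, g in zip(self.clone_labels, self.gamma_bar)
            ),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers


def estimate_influx_known_primary(gamma_bar, cohort, zero_policy="floor",
                                  cap=DEFAULT_CAP) -> SeedingInfluxResults:
    """Per-sample influx MLEs with a known primary composition."""
    return SeedingInfluxModel(
        cohort, gamma_bar=gamma_bar, zero_policy=zero_policy, cap=cap
    ).fit()


def estimate_joint(cohort, zero_policy="floor", cap=DEFAULT_CAP,
                   maxiter=500, tol=1e-10) -> SeedingInfluxResults:
    """Joint MLE of the primary composition and all per-sample influxes."""
    return SeedingInfluxModel(
        cohort, gamma_bar=None, zero_policy=zero_policy, cap=cap
    ).fit(maxiter=maxiter, tol=tol)


def seeded_cells_from_estimate(estimate: SeedingInfluxResults, rho: float,
                               detect_size) -> pd.DataFrame:
    """Apply ``X = k [ln(rho Y) - psi(k)]`` to fitted influxes."""
    return estimate.seeded_cells(rho, detect_size)
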