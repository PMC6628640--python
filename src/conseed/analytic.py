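"""Closed-form predictions of the consecutive-seeding model.

For a metastasis consecutively seeded with per-clone influxes ``k_i`` (total
``k``), lineage survival probability ``rho`` and net growth rate ``r``:

* the mean size of clone ``i`` at time ``t`` is ``(k_i/rho)(e^{rt} - 1)``;
* the stochastic clone size at fixed ``t`` is negative-binomially
  distributed, ``y_i(t) ~ NBin(k_i, q_i(t))`` with
  ``q_i(t) = k_i/(ybar_i(t) + k_i)``;
* at the detection size ``Y`` the clone cell counts ``(Y_1, ..., Y_N)``
  jointly follow a Dirichlet-multinomial law (a Polya urn with double
  replacement), and the clone frequencies ``gamma_i = Y_i/Y`` follow a
  Dirichlet distribution with concentrations ``k_i``;
* clonal diversity (Simpson index) is transferred from source to metastasis
  in mean proportion ``k/(1+k)``, and M equally seeded metastases have
  fixation index ``F_ST = (1 - 1/M)/(1+k)``;
* the expected number of migrated cells that found a surviving lineage
  before detection is ``Xbar = k [ln(rho Y) - psi(k)]``.

Every binomial-coefficient ratio is evaluated as a difference of log-gamma
values, so detection sizes up to ``1e9`` and non-integer influxes are exact
to double precision; no factorial is ever formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, xlogy
from scipy.stats import beta as beta_dist

from .params import ClonalComposition, DetectionSpec, SeedingModel, as_composition

__all__ = [
    "CloneSizeLaw",
    "CompositionLaw",
    "mean_clone_size",
    "clone_size_law",
    "clone_size_pmf",
    "detected_composition_pmf",
    "mean_num_clones",
    "polyclonality_probability",
    "threshold_polyclonality_probability",
    "polyclonality_small_k_approx",
    "monoclonality_boundary_influx",
    "composition_law",
    "composition_logpdf",
    "simpson_diversity",
    "effective_clone_number",
    "diversity_transfer_ratio",
    "fixation_index",
    "expected_seeded_cells",
    "mean_detection_time",
    "self_seeding_first_event_fraction",
    "predict_table",
]


def _log_binom(a, b):
    """log C(a, b) = lgamma(a+1) - lgamma(b+1) - lgamma(a-b+1), real a."""
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


# ---------------------------------------------------------------------------
# clone size at fixed time


@dataclass(frozen=True)
class CloneSizeLaw:
    """Negative-binomial law of one clone's size at a fixed time.

    ``shape`` is the (possibly non-integer) influx ``k_i`` and ``q`` the
    failure probability ``k_i / (ybar + k_i)``; the mean is
    ``shape (1-q)/q = ybar``.
    """

    shape: float
    q: float

    def __post_init__(self):
        if not self.shape > 0:
            raise ValueError("shape (influx k_i) must be positive")
        if not (0.0 < self.q <= 1.0):
            raise ValueError("q must lie in (0, 1]")

    @property
    def mean_size(self) -> float:
        return self.shape * (1.0 - self.q) / self.q

    def logpmf(self, y):
        y = np.asarray(y, dtype=float)
        k, q = self.shape, self.q
        return (
            gammaln(y + k)
            - gammaln(y + 1.0)
            - gammaln(k)
            + k * np.log(q)
            + xlogy(y, 1.0 - q)
        )

    def pmf(self, y):
        return np.exp(self.logpmf(y))


def mean_clone_size(model: SeedingModel, clone: int, t) -> float:
    """Mean size ``ybar_i(t) = (k_i/rho)(e^{rt} - 1)`` of clone ``i`` at day ``t``.

    Solves the mean dynamics ``ybar' = r ybar + lambda_i`` from ``ybar(0)=0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    ki = model.influx[clone]
    out = (ki / model.survival_prob) * np.expm1(model.net_growth * t)
    return float(out) if out.ndim == 0 else out


def clone_size_law(model: SeedingModel, clone: int, t: float) -> CloneSizeLaw:
    """The NBin(k_i, q_i(t)) law of clone ``i``'s size at day ``t``."""
    ki = float(model.influx[clone])
    ybar = mean_clone_size(model, clone, t)
    return CloneSizeLaw(shape=ki, q=ki / (ybar + ki))


def clone_size_pmf(law: CloneSizeLaw, y) -> np.ndarray:
    """P(y_i(t) = y) for integer cell counts ``y >= 0``."""
    y_arr = np.asarray(y)
    if np.any(y_arr < 0) or not np.allclose(y_arr, np.round(y_arr)):
        raise ValueError("y must be a nonnegative integer count")
    out = law.pmf(np.asarray(y_arr, dtype=float))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# detected composition (Polya urn / Dirichlet-multinomial)


def detected_composition_pmf(model: SeedingModel, counts) -> float:
    """Joint probability of detected clone cell counts ``(Y_1, ..., Y_N)``.

    Dirichlet-multinomial:
    ``P = prod_i C(Y_i + k_i - 1, Y_i) / C(Y + k - 1, Y)``, evaluated in log
    space.  ``counts`` must sum to the detection size Y.
    """
    counts = np.atleast_1d(np.asarray(counts, dtype=float))
    if counts.size != model.n_clones:
        raise ValueError("counts must have one entry per clone")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    ki = model.influx
    if np.any((ki == 0) & (counts > 0)):
        return 0.0
    k = model.total_influx
    y_tot = counts.sum()
    pos = ki > 0
    log_num = np.sum(_log_binom(counts[pos] + ki[pos] - 1.0, counts[pos]))
    log_den = _log_binom(y_tot + k - 1.0, y_tot)
    return float(np.exp(log_num - log_den))


def mean_num_clones(model: SeedingModel, spec: DetectionSpec) -> float:
    """Mean number of clones present (nonzero size) at detection.

    ``nbar = N - sum_i C(Y + k - k_i - 1, Y) / C(Y + k - 1, Y)``.
    Requires ``min_cell_fraction == 0`` (counts any nonzero clone).
    """
    if spec.min_cell_fraction != 0:
        raise ValueError(
            "mean_num_clones counts clones of any nonzero size; "
            "set min_cell_fraction=0 or use the simulator for thresholded calls"
        )
    ki = model.influx
    k = model.total_influx
    y = float(spec.detect_size)
    log_den = _log_binom(y + k - 1.0, y)
    absent = np.exp(_log_binom(y + k - ki - 1.0, y) - log_den)
    return float(model.n_clones - absent.sum())


def polyclonality_probability(model: SeedingModel, spec: DetectionSpec) -> float:
    """Probability that more than one clone has nonzero size at detection.

    ``P(n>1) = 1 - sum_i C(Y + k_i - 1, Y) / C(Y + k - 1, Y)``.  With a
    nonzero ``min_cell_fraction`` the thresholded analogue is computed by
    :func:`threshold_polyclonality_probability` instead.
    """
    if spec.min_cell_fraction != 0:
        return threshold_polyclonality_probability(model, spec)
    ki = model.influx
    if model.n_clones == 1:
        return 0.0
    k = model.total_influx
    y = float(spec.detect_size)
    log_den = _log_binom(y + k - 1.0, y)
    pos = ki > 0
    mono = np.exp(_log_binom(y + ki[pos] - 1.0, y) - log_den)
    return float(min(max(1.0 - mono.sum(), 0.0), 1.0))


def threshold_polyclonality_probability(
    model: SeedingModel,
    spec: DetectionSpec,
    n_draws: int = 100_000,
    seed: int | None = 0,
) -> float:
    """Probability that >= 2 clones exceed the minimum cell fraction.

    Exact via the Beta marginal for two clones; Monte Carlo over the
    Dirichlet composition law otherwise (the detection size only enters
    through the large-Y composition limit).
    """
    f = spec.min_cell_fraction
    ki = model.influx
    k = model.total_influx
    if f == 0:
        return polyclonality_probability(model, spec)
    if model.n_clones == 1:
        return 0.0
    if model.n_clones == 2:
        # both clones >= f  <=>  gamma_1 in [f, 1-f]
        m = beta_dist(ki[0], ki[1])
        return float(max(m.cdf(1.0 - f) - m.cdf(f), 0.0))
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(ki, size=n_draws)
    return float(np.mean((draws >= f).sum(axis=1) >= 2))


def polyclonality_small_k_approx(k: float, n_clones: int, detect_size) -> float:
    """Small-influx approximation ``P(n>1) ~ 1 - kappa! Y^{-kappa}``.

    Assumes N clones with equal influx ``k/N``; ``kappa = k (1 - 1/N)`` is
    the clone-adjusted influx.  Valid for ``k << N``.
    """
    if k >= n_clones:
        warnings.warn(
            "small-k approximation is only valid for total influx k << N",
            RuntimeWarning,
            stacklevel=2,
        )
    kappa = k * (1.0 - 1.0 / n_clones)
    y = float(detect_size)
    p = 1.0 - np.exp(gammaln(kappa + 1.0) - kappa * np.log(y))
    return float(min(max(p, 0.0), 1.0))


def monoclonality_boundary_influx(detect_size) -> float:
    """Clone-adjusted influx ``kappa = 1/log2(Y)`` at which mono- and
    polyclonality are equally likely under the small-k approximation."""
    return float(1.0 / np.log2(float(detect_size)))


# ---------------------------------------------------------------------------
# composition law (Dirichlet) and diversity


@dataclass(frozen=True)
class CompositionLaw:
    """Dirichlet law of the detected clone frequencies.

    Concentration parameters are the per-clone influxes ``k_i``; the mean
    frequency of clone ``i`` is ``k_i/k`` and its marginal is
    ``Beta(k gbar_i, k (1 - gbar_i))`` with variance
    ``gbar_i (1 - gbar_i)/(1 + k)``.
    """

    influx: np.ndarray

    def __post_init__(self):
        arr = np.atleast_1d(np.asarray(self.influx, dtype=float))
        if np.any(arr <= 0):
            raise ValueError(
                "all concentration parameters k_i must be positive "
                "for density evaluation"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "influx", arr)

    @property
    def total_influx(self) -> float:
        return float(self.influx.sum())

    @property
    def mean(self) -> np.ndarray:
        return self.influx / self.total_influx

    @property
    def variance(self) -> np.ndarray:
        g = self.mean
        return g * (1.0 - g) / (1.0 + self.total_influx)

    def marginal(self, clone: int):
        """Beta marginal of one clone's frequency."""
        k = self.total_influx
        ki = self.influx[clone]
        return beta_dist(ki, k - ki)

    def rvs(self, size: int, seed=None) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return rng.dirichlet(self.influx, size=size)


def composition_law(model: SeedingModel) -> CompositionLaw:
    return CompositionLaw(influx=model.influx)


def composition_logpdf(law: CompositionLaw, freqs) -> float:
    """Dirichlet log-density of a clone-frequency vector.

    Returns ``+inf`` (with a warning) at a boundary frequency whose
    concentration is below one, where the density diverges; ``-inf`` at a
    boundary with concentration above one.
    """
    comp = as_composition(freqs)
    g = comp.freqs
    ki = law.influx
    if g.size != ki.size:
        raise ValueError("composition and law must have the same number of clones")
    at_boundary = g == 0.0
    if np.any(at_boundary):
        if np.any(ki[at_boundary] < 1.0):
            warnings.warn(
                "density diverges at a zero frequency with concentration < 1",
                RuntimeWarning,
                stacklevel=2,
            )
            return float("inf")
        if np.any(ki[at_boundary] > 1.0):
            return float("-inf")
    logc = gammaln(ki.sum()) - gammaln(ki).sum()
    return float(logc + np.sum(xlogy(ki - 1.0, g)))


def simpson_diversity(freqs) -> float:
    """Simpson index ``D = 1 - sum_i gamma_i^2``: the probability that two
    randomly drawn cells descend from different clones."""
    comp = as_composition(freqs)
    return float(1.0 - np.sum(comp.freqs**2))


def effective_clone_number(diversity: float) -> float:
    """Effective number of equally abundant clones, ``1/(1 - D)``."""
    if not (0.0 <= diversity < 1.0):
        raise ValueError("diversity must lie in [0, 1)")
    return 1.0 / (1.0 - diversity)


def diversity_transfer_ratio(model: SeedingModel | float) -> float:
    """Mean fraction of source-tumor clonal diversity transferred to the
    metastasis: ``Dbar_2 / D_1 = k/(1+k) = lambda/(b+lambda)``."""
    k = model.total_influx if isinstance(model, SeedingModel) else float(model)
    if k < 0:
        raise ValueError("total influx must be nonnegative")
    return k / (1.0 + k)


def fixation_index(model: SeedingModel | float, n_mets: int) -> float:
    """Fixation index ``F_ST = (1 - 1/M) / (1 + k)`` of M equally seeded
    metastases; tends to ``1/(1+k)`` for many metastases."""
    if n_mets < 1:
        raise ValueError("n_mets must be >= 1")
    k = model.total_influx if isinstance(model, SeedingModel) else float(model)
    return (1.0 - 1.0 / n_mets) / (1.0 + k)


def expected_seeded_cells(model: SeedingModel | float, spec: DetectionSpec,
                          survival_prob: float | None = None) -> float:
    """Expected number of migrated cells founding surviving lineages before
    detection: ``Xbar = k [ln(rho Y) - psi(k)]``.

    Accepts a model (rho taken from it) or a bare total influx ``k`` with an
    explicit ``survival_prob``.  Requires ``rho Y > 1``.
    """
    if isinstance(model, SeedingModel):
        k = model.total_influx
        rho = model.survival_prob
    else:
        k = float(model)
        if survival_prob is None:
            raise ValueError("survival_prob is required when passing a bare influx")
        rho = float(survival_prob)
    if k <= 0:
        return 0.0
    ry = rho * spec.detect_size
    if ry <= 1.0:
        raise ValueError(
            f"detection is not meaningful for rho*Y = {ry!r} <= 1 "
            "(fewer than one surviving cell at detection)"
        )
    return float(k * (np.log(ry) - digamma(k)))


def mean_detection_time(model: SeedingModel, spec: DetectionSpec) -> float:
    """Mean time to reach the detection size,
    ``Tbar = [ln(rho Y) - psi(k)] / r`` days (from ``Xbar = rho lambda Tbar``)."""
    xbar = expected_seeded_cells(model, spec)
    return xbar / (model.survival_prob * float(np.sum(model.seed_rates)))


def self_seeding_first_event_fraction(k: float) -> float:
    """Typical size fraction of a source metastasis when it first seeds a
    surviving downstream lineage.

    Surviving seeding events from an exponentially growing source form an
    inhomogeneous Poisson process whose integrated rate, as a function of the
    source's size fraction f of its mature size, is ``k f``; the geometric
    mean of the first-event fraction is ``exp(-euler_gamma)/k ~ 0.5615/k``,
    capped at 1 (the statement is relative to the mature size).
    """
    if not k > 0:
        raise ValueError("total influx k must be positive")
    return float(min(np.exp(-np.euler_gamma) / k, 1.0))


# ---------------------------------------------------------------------------
# prediction table (CLI backend)


def predict_table(model: SeedingModel, detect_sizes, n_mets: int = 2,
                  min_cell_fraction: float = 0.0):
    """Tidy table of the headline predictions over a grid of detection sizes.

    Returns a pandas DataFrame with one row per Y: mean clone number,
    polyclonality probability (thresholded if requested), diversity transfer
    ratio, fixation index, expected surviving seeded cells and mean detection
    time.
    """
    import pandas as pd

    rows = []
    for y in np.atleast_1d(detect_sizes):
        spec0 = DetectionSpec(detect_size=int(y))
        row = {
            "Y": int(y),
            "k_total": model.total_influx,
            "mean_n_clones": mean_num_clones(model, spec0),
            "p_polyclonal": polyclonality_probability(model, spec0),
            "diversity_transfer": diversity_transfer_ratio(model),
            "fst": fixation_index(model, n_mets),
            "expected_seeded_cells": expected_seeded_cells(model, spec0),
            "mean_detection_time_days": mean_detection_time(model, spec0),
        }
        if min_cell_fraction > 0:
            spec_f = DetectionSpec(int(y), min_cell_fraction)
            row["p_polyclonal_thresholded"] = threshold_polyclonality_probability(
                model, spec_f
            )
        rows.append(row)
    return pd.DataFrame(rows)
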