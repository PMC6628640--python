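"""Model parameterizations for consecutive seeding of a metastasis.

A metastasis is modelled as a multitype continuous-time branching process
with immigration: cells of clone ``i`` arrive from the source tumor at a
constant seeding rate ``lambda_i`` (cells/day) and then divide at rate ``b``
and die at rate ``d`` (``b > d``, supercritical growth).  All results of the
neutral model depend on the rates only through three derived quantities,

* the seeding influx per generation ``k_i = lambda_i / b`` (dimensionless),
* the lineage survival probability ``rho = 1 - d/b``,
* the net growth rate ``r = b - d`` (1/day),

so the model can be specified either way; the two parameterizations are
bijective and both are exposed here.  In scaled time units where ``b = 1``
the influx equals the seeding rate and the survival probability equals the
net growth rate.

Rates are stored per day; scaled-unit views are computed on demand and never
stored, so there is a single source of truth for units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numbers

import numpy as np

__all__ = ["SeedingModel", "DetectionSpec", "ClonalComposition"]

_ROUNDTRIP_RTOL = 1e-12


def _as_rate_vector(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr


@dataclass(frozen=True)
class SeedingModel:
    """Per-tumor parameters of the consecutive-seeding process.

    Construct with :meth:`from_rates` (``lambda_i, b, d``) or
    :meth:`from_scaled` (``k_i, rho, r``).  Clones are indexed 0-based
    internally; attach labels at the I/O layer, never here.

    Attributes
    ----------
    seed_rates : ndarray
        Per-clone seeding rates ``lambda_i`` in cells/day.
    birth_rate, death_rate : float
        Cell division and death rates in the metastasis (1/day), shared by
        all clones (neutral model).
    """

    seed_rates: np.ndarray
    birth_rate: float
    death_rate: float

    def __post_init__(self):
        rates = _as_rate_vector(self.seed_rates, "seed_rates")
        object.__setattr__(self, "seed_rates", rates)
        b = float(self.birth_rate)
        d = float(self.death_rate)
        object.__setattr__(self, "birth_rate", b)
        object.__setattr__(self, "death_rate", d)
        if not (b > 0 and np.isfinite(b)):
            raise ValueError("birth_rate must be positive and finite")
        if not (d >= 0 and np.isfinite(d)):
            raise ValueError("death_rate must be nonnegative and finite")
        if not b > d:
            raise ValueError(
                "subcritical growth: requires birth_rate > death_rate "
                f"(got b={b!r} <= d={d!r}); no metastasis can reach detection"
            )
        if not np.any(rates > 0):
            raise ValueError(
                "all seed rates are zero: no metastasis can ever be seeded"
            )
        rates.setflags(write=False)

    # -- constructors --------------------------------------------------

    @classmethod
    def from_rates(cls, seed_rates, birth_rate, death_rate=0.0) -> "SeedingModel":
        """Build from the raw rates ``(lambda_i, b, d)``."""
        return cls(seed_rates=seed_rates, birth_rate=birth_rate, death_rate=death_rate)

    @classmethod
    def from_scaled(cls, influx, survival_prob, net_growth) -> "SeedingModel":
        """Build from the scaled parameters ``(k_i, rho, r)``.

        Inverts ``k_i = lambda_i/b``, ``rho = 1 - d/b``, ``r = b - d``:
        ``b = r/rho``, ``d = r (1/rho - 1)``, ``lambda_i = k_i b``.
        """
        rho = float(survival_prob)
        r = float(net_growth)
        if not (0.0 < rho <= 1.0):
            raise ValueError(f"survival_prob must lie in (0, 1], got {rho!r}")
        if not (r > 0 and np.isfinite(r)):
            raise ValueError(f"net_growth must be positive, got {r!r}")
        k = _as_rate_vector(influx, "influx")
        b = r / rho
        d = r * (1.0 / rho - 1.0)
        return cls(seed_rates=k * b, birth_rate=b, death_rate=d)

    # -- derived scaled parameters ------------------------------------

    @property
    def n_clones(self) -> int:
        return int(self.seed_rates.size)

    @property
    def influx(self) -> np.ndarray:
        """Per-clone seeding influx ``k_i = lambda_i / b`` (cells/generation)."""
        return self.seed_rates / self.birth_rate

    @property
    def total_influx(self) -> float:
        """Total seeding influx ``k = sum_i k_i``."""
        return float(np.sum(self.influx))

    @property
    def survival_prob(self) -> float:
        """Probability ``rho = 1 - d/b`` that a seeded cell's lineage survives."""
        return 1.0 - self.death_rate / self.birth_rate

    @property
    def net_growth(self) -> float:
        """Net growth rate ``r = b - d`` (1/day)."""
        return self.birth_rate - self.death_rate

    @property
    def migrant_fractions(self) -> np.ndarray:
        """Mean clone frequencies among migrants, ``gamma_bar_i = k_i / k``."""
        k = self.influx
        return k / k.sum()

    # -- serialization -------------------------------------------------

    _RATE_KEYS = ("seed_rates", "birth_rate", "death_rate")
    _SCALED_KEYS = ("influx", "survival_prob", "net_growth")

    @classmethod
    def from_config(cls, config: dict) -> "SeedingModel":
        """Build from a flat key-value mapping.

        Exactly one of the two parameter triples must be present:
        ``seed_rates``/``birth_rate``/``death_rate`` or
        ``influx``/``survival_prob``/``net_growth``.
        """
        has_rates = any(k in config for k in cls._RATE_KEYS)
        has_scaled = any(k in config for k in cls._SCALED_KEYS)
        if has_rates and has_scaled:
            raise ValueError(
                "config mixes the rate and scaled parameter triples; give exactly one"
            )
        if has_rates:
            missing = [k for k in cls._RATE_KEYS if k not in config]
            if missing:
                raise ValueError(f"config missing keys: {missing}")
            return cls.from_rates(
                config["seed_rates"], config["birth_rate"], config["death_rate"]
            )
        if has_scaled:
            missing = [k for k in cls._SCALED_KEYS if k not in config]
            if missing:
                raise ValueError(f"config missing keys: {missing}")
            return cls.from_scaled(
                config["influx"], config["survival_prob"], config["net_growth"]
            )
        raise ValueError(
            "config must contain either seed_rates/birth_rate/death_rate "
            "or influx/survival_prob/net_growth"
        )

    def to_config(self, scaled: bool = False) -> dict:
        if scaled:
            return {
                "influx": [float(x) for x in self.influx],
                "survival_prob": self.survival_prob,
                "net_growth": self.net_growth,
            }
        return {
            "seed_rates": [float(x) for x in self.seed_rates],
            "birth_rate": self.birth_rate,
            "death_rate": self.death_rate,
        }


@dataclass(frozen=True)
class DetectionSpec:
    """When a metastasis is evaluated and when a clone is called present.

    ``detect_size`` is the total cell count Y at which the metastasis is
    examined (growth is stopped at the first time the total size reaches Y).
    ``min_cell_fraction`` is the clonality-call threshold: a clone is called
    present when its cell fraction is at least this value (0 means "any
    nonzero size"; bulk-sequencing studies typically use 0.05).
    """

    detect_size: int
    min_cell_fraction: float = 0.0

    def __post_init__(self):
        y = self.detect_size
        if not isinstance(y, numbers.Integral) or isinstance(y, bool):
            if isinstance(y, numbers.Real) and float(y).is_integer():
                y = int(y)
            else:
                raise ValueError(f"detect_size must be an integer, got {y!r}")
        object.__setattr__(self, "detect_size", int(y))
        if self.detect_size < 1:
            raise ValueError("detect_size must be >= 1")
        f = float(self.min_cell_fraction)
        if not (0.0 <= f < 1.0):
            raise ValueError("min_cell_fraction must lie in [0, 1)")
        object.__setattr__(self, "min_cell_fraction", f)


@dataclass(frozen=True)
class ClonalComposition:
    """A clone-frequency vector for one tumor (entries sum to one)."""

    freqs: np.ndarray
    _SUM_TOL: float = field(default=1e-9, repr=False)

    def __post_init__(self):
        arr = np.atleast_1d(np.asarray(self.freqs, dtype=float))
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("freqs must be a non-empty 1-D vector")
        if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
            raise ValueError("frequencies must lie in [0, 1]")
        total = arr.sum()
        if abs(total - 1.0) > self._SUM_TOL:
            raise ValueError(f"frequencies must sum to 1 (got {total!r})")
        arr = arr / total
        arr.setflags(write=False)
        object.__setattr__(self, "freqs", arr)

    @property
    def n_clones(self) -> int:
        return int(self.freqs.size)

    def __len__(self) -> int:
        return self.n_clones

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.freqs, dtype=dtype)


def as_composition(x) -> ClonalComposition:
    """Coerce an array-like or ClonalComposition to a ClonalComposition."""
    if isinstance(x, ClonalComposition):
        return x
    return ClonalComposition(np.asarray(x, dtype=float))
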