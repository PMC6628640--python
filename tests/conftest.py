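"""Shared fixtures and independent oracles.

The urn oracle enumerates the Polya sampling-with-double-replacement chain
state by state (a dynamic program over count vectors), with no reference to
any closed-form distribution, so it is an independent check of the
Dirichlet-multinomial layer.
"""

from collections import defaultdict

import numpy as np
import pytest

from conseed import DetectionSpec, SeedingModel


def urn_composition_probs(ks, total):
    """Exact law of the clone counts after ``total`` urn draws.

    Sequentially adds cells: given counts ``c`` after ``m`` draws, the next
    cell is clone ``i`` with probability ``(c_i + k_i) / (m + k)``.  Returns
    a dict mapping count tuples to probabilities.
    """
    ks = [float(k) for k in ks]
    k_tot = sum(ks)
    n = len(ks)
    states = {tuple([0] * n): 1.0}
    for m in range(total):
        new = defaultdict(float)
        for counts, p in states.items():
            for i in range(n):
                pi = (counts[i] + ks[i]) / (m + k_tot)
                nxt = list(counts)
                nxt[i] += 1
                new[tuple(nxt)] += p * pi
        states = dict(new)
    return states


def urn_mean_clones(ks, total):
    probs = urn_composition_probs(ks, total)
    return sum(p * sum(1 for c in counts if c > 0) for counts, p in probs.items())


def urn_polyclonal_prob(ks, total):
    probs = urn_composition_probs(ks, total)
    return sum(p for counts, p in probs.items()
               if sum(1 for c in counts if c > 0) > 1)


@pytest.fixture(scope="session")
def urn():
    """Namespace fixture exposing the urn oracle functions."""

    class _Urn:
        composition_probs = staticmethod(urn_composition_probs)
        mean_clones = staticmethod(urn_mean_clones)
        polyclonal_prob = staticmethod(urn_polyclonal_prob)

    return _Urn


@pytest.fixture(scope="session")
def table1_model():
    """Typical parameter values: r = 0.0125/day, rho = 5%, lambda = 0.15."""
    return SeedingModel.from_rates([0.15], birth_rate=0.25, death_rate=0.2375)


@pytest.fixture(scope="session")
def fig2_model():
    """Three clones with influxes 0.02/0.03/0.05, rho = 5%, r = 0.0125/day."""
    return SeedingModel.from_scaled([0.02, 0.03, 0.05],
                                    survival_prob=0.05, net_growth=0.0125)


@pytest.fixture()
def spec_small():
    return DetectionSpec(detect_size=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
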