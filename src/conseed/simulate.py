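"""Stochastic realizations of metastasis growth under consecutive seeding.

The engine is an exact Gillespie simulation of the multitype branching
process with immigration: clone-``i`` cells immigrate at constant rate
``lambda_i``; every cell divides at rate ``b`` and dies at rate ``d``.
Growth stops at the first event after which the total size reaches the
detection size ``Y``.  Every immigration event opens a tagged lineage, so
both the lineages extant at detection and the seeding events whose lineage
survives long-run (the quantity ``X``; an extant lineage of ``s`` cells
escapes future extinction with probability ``1 - (d/b)^s``) are tracked
exactly.

Two modes are provided:

``exact``
    Event-by-event simulation of every cell.  Cost grows linearly with
    ``Y``; intended for ``Y`` up to ~1e4-1e5.

``hybrid``
    Small lineages are simulated exactly; once a lineage reaches
    ``promote_size`` cells its *remaining* stochasticity is replaced by its
    limiting growth law.  For a linear birth-death process each of the
    ``n`` current cells contributes an independent martingale weight
    ``W = 0`` with probability ``1 - rho``, else ``Exp(1/rho)``, and the
    lineage grows as ``(sum W) e^{r t}``; the promotion therefore samples
    ``B ~ Binomial(n, rho)`` surviving roots and a ``Gamma(B, 1/rho)``
    weight.  ``B = 0`` occurs with exactly the lineage's true extinction
    probability ``(d/b)^n``, in which case the lineage is kept stochastic
    but conditioned on extinction (birth and death rates swapped, the exact
    conditional law), so doomed cells still linger in the population.
    Immigration and all small lineages remain fully stochastic.  This
    preserves the large-``Y`` composition law exactly and is validated
    against the exact mode in the test suite.

Kernels are numba-compiled; replicate streams are derived from one master
seed and results are bit-reproducible for a fixed seed and event budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import DetectionSpec, SeedingModel

__all__ = [
    "SimResult",
    "SimCohort",
    "CohortSummary",
    "EventBudgetError",
    "simulate_metastasis",
    "simulate_cohort",
    "simulate_clone_sizes_at",
    "simulate_first_seeding_fraction",
    "call_clonality",
    "cohort_sensitivity",
]

DEFAULT_MAX_EVENTS = 100_000_000
DEFAULT_PROMOTE_SIZE = 64


class EventBudgetError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _sim_one(lam, b, d, y_detect, hybrid, promote_size, max_events, seed,
             traj_dt, traj_buf_t, traj_buf_y):
    """One realization to detection.  Returns (counts, t, n_seed,
    n_established, n_extant, n_events, status, n_traj); status 1 = event
    budget exceeded."""
    np.random.seed(seed)
    n_clones = lam.size
    lam_tot = lam.sum()
    r = b - d
    rho = 1.0 - d / b

    cap = 64
    lin_clone = np.zeros(cap, np.int64)
    lin_size = np.zeros(cap, np.int64)
    lin_doomed = np.zeros(cap, np.uint8)
    nlin = 0
    n_alive = 0
    s_cells = 0  # total stochastic cells
    det_w = np.zeros(n_clones)  # deterministic weights of promoted lineages
    t = 0.0
    n_seed = 0
    n_promoted = 0
    events = 0
    status = 0

    record = traj_dt > 0.0
    n_traj = 0
    next_rec = 0.0

    while True:
        d_tot = det_w.sum()
        if s_cells + d_tot >= y_detect:
            break
        rate = lam_tot + (b + d) * s_cells
        tau = np.random.exponential(1.0 / rate)
        if d_tot > 0.0:
            # deterministic pool may cross the detection size mid-interval
            if s_cells + d_tot * np.exp(r * tau) >= y_detect:
                t_cross = np.log((y_detect - s_cells) / d_tot) / r
                if t_cross <= tau:
                    t += t_cross
                    for i in range(n_clones):
                        det_w[i] *= np.exp(r * t_cross)
                    break
            for i in range(n_clones):
                det_w[i] *= np.exp(r * tau)
        t += tau
        events += 1
        if events > max_events:
            status = 1
            break

        if record and t >= next_rec and n_traj < traj_buf_t.size:
            traj_buf_t[n_traj] = t
            for i in range(n_clones):
                traj_buf_y[n_traj, i] = det_w[i]
            for j in range(nlin):
                if lin_size[j] > 0:
                    traj_buf_y[n_traj, lin_clone[j]] += lin_size[j]
            n_traj += 1
            next_rec = t + traj_dt

        u = np.random.uniform(0.0, rate)
        if u < lam_tot:
            # immigration: open a new tagged lineage of one cell
            acc = 0.0
            clone = n_clones - 1
            for i in range(n_clones):
                acc += lam[i]
                if u < acc:
                    clone = i
                    break
            if nlin == cap:
                new_cap = cap * 2
                nc = np.zeros(new_cap, np.int64)
                ns = np.zeros(new_cap, np.int64)
                nd = np.zeros(new_cap, np.uint8)
                nc[:cap] = lin_clone
                ns[:cap] = lin_size
                nd[:cap] = lin_doomed
                lin_clone, lin_size, lin_doomed = nc, ns, nd
                cap = new_cap
            lin_clone[nlin] = clone
            lin_size[nlin] = 1
            lin_doomed[nlin] = 0
            nlin += 1
            n_alive += 1
            s_cells += 1
            n_seed += 1
        else:
            u -= lam_tot
            acc = 0.0
            done = False
            for j in range(nlin):
                sz = lin_size[j]
                if sz == 0:
                    continue
                if lin_doomed[j] == 1:
                    # extinction-conditioned birth-death: rates swapped
                    w_birth = d * sz
                    w_death = b * sz
                else:
                    w_birth = b * sz
                    w_death = d * sz
                if u < acc + w_birth:
                    lin_size[j] = sz + 1
                    s_cells += 1
                    if (hybrid and lin_doomed[j] == 0
                            and lin_size[j] >= promote_size):
                        n_now = lin_size[j]
                        n_surv_roots = np.random.binomial(n_now, rho)
                        if n_surv_roots == 0:
                            # true extinction probability (d/b)^n: keep the
                            # lineage stochastic, conditioned on dying out
                            lin_doomed[j] = 1
                        else:
                            w = np.random.gamma(n_surv_roots, 1.0 / rho)
                            det_w[lin_clone[j]] += w
                            n_promoted += 1
                            s_cells -= n_now
                            lin_size[j] = 0
                            n_alive -= 1
                    done = True
                    break
                acc += w_birth
                if u < acc + w_death:
                    lin_size[j] = sz - 1
                    s_cells -= 1
                    if lin_size[j] == 0:
                        n_alive -= 1
                    done = True
                    break
                acc += w_death
            if not done and n_alive > 0:
                # float roundoff fell off the end: apply a death to the
                # last alive lineage (probability ~ machine epsilon)
                for j in range(nlin - 1, -1, -1):
                    if lin_size[j] > 0:
                        lin_size[j] -= 1
                        s_cells -= 1
                        if lin_size[j] == 0:
                            n_alive -= 1
                        break
            # compact tombstones occasionally
            if nlin > 128 and n_alive * 2 < nlin:
                w_idx = 0
                for j in range(nlin):
                    if lin_size[j] > 0:
                        lin_clone[w_idx] = lin_clone[j]
                        lin_size[w_idx] = lin_size[j]
                        lin_doomed[w_idx] = lin_doomed[j]
                        w_idx += 1
                nlin = w_idx

    counts = det_w.copy()
    n_extant = n_promoted
    n_established = n_promoted
    death_per_birth = d / b
    for j in range(nlin):
        if lin_size[j] > 0:
            counts[lin_clone[j]] += lin_size[j]
            n_extant += 1
            if lin_doomed[j] == 0:
                # the lineage's future is independent of its past: it
                # escapes extinction with probability 1 - (d/b)^size
                p_surv = 1.0 - death_per_birth ** lin_size[j]
                if np.random.uniform(0.0, 1.0) < p_surv:
                    n_established += 1
    return counts, t, n_seed, n_established, n_extant, events, status, n_traj


@njit(cache=True)
def _sim_cohort(lam, b, d, y_detect, hybrid, promote_size, max_events, seeds):
    n_reps = seeds.size
    n_clones = lam.size
    counts = np.empty((n_reps, n_clones))
    times = np.empty(n_reps)
    n_seed = np.empty(n_reps, np.int64)
    n_surv = np.empty(n_reps, np.int64)
    n_ext = np.empty(n_reps, np.int64)
    dummy_t = np.empty(0)
    dummy_y = np.empty((0, n_clones))
    status = 0
    for rep in range(n_reps):
        c, t, ns, nv, ne, _, st, _ = _sim_one(
            lam, b, d, y_detect, hybrid, promote_size, max_events,
            seeds[rep], -1.0, dummy_t, dummy_y,
        )
        if st != 0:
            status = st
            break
        counts[rep] = c
        times[rep] = t
        n_seed[rep] = ns
        n_surv[rep] = nv
        n_ext[rep] = ne
    return counts, times, n_seed, n_surv, n_ext, status


@njit(cache=True)
def _sim_fixed_time(lam, b, d, t_end, max_events, seed):
    """Exact simulation to a fixed time (no detection stop); per-clone counts."""
    np.random.seed(seed)
    n_clones = lam.size
    lam_tot = lam.sum()
    counts = np.zeros(n_clones, np.int64)
    s_cells = 0
    t = 0.0
    events = 0
    while True:
        rate = lam_tot + (b + d) * s_cells
        tau = np.random.exponential(1.0 / rate)
        if t + tau > t_end:
            break
        t += tau
        events += 1
        if events > max_events:
            return counts, 1
        u = np.random.uniform(0.0, rate)
        if u < lam_tot:
            acc = 0.0
            for i in range(n_clones):
                acc += lam[i]
                if u < acc:
                    counts[i] += 1
                    break
            s_cells += 1
        else:
            u = (u - lam_tot) / (b + d)
            # pick a clone proportional to size; birth vs death by rate split
            acc = 0.0
            for i in range(n_clones):
                acc += counts[i]
                if u < acc:
                    if np.random.uniform(0.0, b + d) < b:
                        counts[i] += 1
                        s_cells += 1
                    else:
                        counts[i] -= 1
                        s_cells -= 1
                    break
    return counts, 0


@njit(cache=True)
def _first_seed_fractions(k, r, f_start, n_reps, seeds):
    """Size fraction of an exponentially growing source tumor at its first
    surviving seeding event, by thinning an inhomogeneous Poisson process.

    The surviving-seed rate at time t is a(t) = k * r * f(t) where
    f(t) = f_start * e^{r t} is the source's size fraction of its mature
    size; simulation starts when the source is a fraction ``f_start`` of
    mature size and continues past maturity (f > 1) until the first event.
    """
    out = np.empty(n_reps)
    window = np.log(2.0) / r
    for rep in range(n_reps):
        np.random.seed(seeds[rep])
        t = 0.0
        f0 = f_start
        while True:
            # majorant over [t, t + window): rate at the window end
            m_rate = k * r * f0 * 2.0
            dt = np.random.exponential(1.0 / m_rate)
            if dt >= window:
                t += window
                f0 *= 2.0
                continue
            f_cand = f0 * np.exp(r * dt)
            if np.random.uniform(0.0, 1.0) < f_cand / (f0 * 2.0):
                out[rep] = f_cand
                break
            t += dt
            f0 = f_cand
    return out


# ---------------------------------------------------------------------------
# results containers


@dataclass
class SimResult:
    """One simulated metastasis at detection.

    ``clone_counts`` are integers in exact mode; in hybrid mode promoted
    lineages contribute real-valued sizes.  ``n_surviving_seeds`` counts the
    immigration events whose lineage survives long-run (realizes X: extant
    lineages at detection escape future extinction with probability
    ``1 - (d/b)^size``); ``n_extant_lineages`` counts all lineages with at
    least one cell at detection, doomed or not.
    """

    clone_counts: np.ndarray
    detect_time: float
    n_seed_events: int
    n_surviving_seeds: int
    n_extant_lineages: int
    mode: str
    trajectory: tuple | None = None

    @property
    def total_size(self) -> float:
        return float(self.clone_counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.clone_counts / self.clone_counts.sum()

    def clonality(self, spec: DetectionSpec):
        return call_clonality(self, spec)


@dataclass
class CohortSummary:
    """Monte-Carlo summary of a simulated cohort (means with standard errors)."""

    n_reps: int
    mean_n_clones: float
    se_n_clones: float
    p_polyclonal: float
    se_p_polyclonal: float
    mean_simpson: float
    se_simpson: float
    mean_frequencies: np.ndarray
    se_frequencies: np.ndarray
    mean_surviving_seeds: float
    se_surviving_seeds: float
    mean_seed_events: float
    mean_detect_time: float
    se_detect_time: float

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "mean_n_clones": self.mean_n_clones,
            "se_n_clones": self.se_n_clones,
            "p_polyclonal": self.p_polyclonal,
            "se_p_polyclonal": self.se_p_polyclonal,
            "mean_simpson": self.mean_simpson,
            "se_simpson": self.se_simpson,
            "mean_frequencies": [float(x) for x in self.mean_frequencies],
            "se_frequencies": [float(x) for x in self.se_frequencies],
            "mean_surviving_seeds": self.mean_surviving_seeds,
            "se_surviving_seeds": self.se_surviving_seeds,
            "mean_seed_events": self.mean_seed_events,
            "mean_detect_time": self.mean_detect_time,
            "se_detect_time": self.se_detect_time,
        }


class SimCohort:
    """Column-wise storage of many replicates, indexable as SimResults."""

    def __init__(self, counts, times, n_seed, n_surv, n_extant, mode, spec):
        self.counts = counts
        self.times = times
        self.n_seed = n_seed
        self.n_surv = n_surv
        self.n_extant = n_extant
        self.mode = mode
        self.spec = spec

    def __len__(self):
        return self.counts.shape[0]

    def __getitem__(self, i) -> SimResult:
        return SimResult(
            clone_counts=self.counts[i],
            detect_time=float(self.times[i]),
            n_seed_events=int(self.n_seed[i]),
            n_surviving_seeds=int(self.n_surv[i]),
            n_extant_lineages=int(self.n_extant[i]),
            mode=self.mode,
        )

    def presence(self, min_cell_fraction: float | None = None) -> np.ndarray:
        """Boolean (reps x clones) presence calls."""
        f = (self.spec.min_cell_fraction if min_cell_fraction is None
             else min_cell_fraction)
        if f > 0:
            freqs = self.counts / self.counts.sum(axis=1, keepdims=True)
            return freqs >= f
        return self.counts > 0

    @property
    def summary(self) -> CohortSummary:
        n_reps = len(self)
        present = self.presence()
        n_clones_per = present.sum(axis=1)
        poly = (n_clones_per > 1).astype(float)
        freqs = self.counts / self.counts.sum(axis=1, keepdims=True)
        simpson = 1.0 - np.sum(freqs**2, axis=1)

        def mse(x):
            x = np.asarray(x, dtype=float)
            se = x.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else 0.0
            return float(x.mean()), float(se)

        mn, se_n = mse(n_clones_per)
        mp, se_p = mse(poly)
        ms, se_s = mse(simpson)
        mx, se_x = mse(self.n_surv)
        mt, se_t = mse(self.times)
        fr_m = freqs.mean(axis=0)
        fr_se = (freqs.std(axis=0, ddof=1) / np.sqrt(n_reps)
                 if n_reps > 1 else np.zeros_like(fr_m))
        return CohortSummary(
            n_reps=n_reps,
            mean_n_clones=mn, se_n_clones=se_n,
            p_polyclonal=mp, se_p_polyclonal=se_p,
            mean_simpson=ms, se_simpson=se_s,
            mean_frequencies=fr_m, se_frequencies=fr_se,
            mean_surviving_seeds=mx, se_surviving_seeds=se_x,
            mean_seed_events=float(np.mean(self.n_seed)),
            mean_detect_time=mt, se_detect_time=se_t,
        )


# ---------------------------------------------------------------------------
# public API


def _check_model(model: SeedingModel):
    if model.total_influx <= 0:
        raise ValueError("total seeding influx must be positive")


def _rep_seeds(seed, n_reps: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_reps).astype(np.int64)


def simulate_metastasis(model: SeedingModel, spec: DetectionSpec, seed,
                        mode: str = "exact",
                        promote_size: int = DEFAULT_PROMOTE_SIZE,
                        max_events: int = DEFAULT_MAX_EVENTS,
                        trajectory_every: float | None = None) -> SimResult:
    """Simulate one metastasis to detection.

    ``trajectory_every`` (days) optionally records a sampled (time,
    per-clone size) path.
    """
    _check_model(model)
    if mode not in ("exact", "hybrid"):
        raise ValueError("mode must be 'exact' or 'hybrid'")
    hybrid = mode == "hybrid"
    n = model.n_clones
    if trajectory_every:
        n_buf = 65536
        buf_t = np.empty(n_buf)
        buf_y = np.empty((n_buf, n))
        dt = float(trajectory_every)
    else:
        buf_t = np.empty(0)
        buf_y = np.empty((0, n))
        dt = -1.0
    rep_seed = int(_rep_seeds(seed, 1)[0])
    counts, t, n_seed, n_surv, n_ext, _, status, n_traj = _sim_one(
        model.seed_rates, model.birth_rate, model.death_rate,
        float(spec.detect_size), hybrid, promote_size, max_events,
        rep_seed, dt, buf_t, buf_y,
    )
    if status == 1:
        raise EventBudgetError(
            f"simulation exceeded the event budget of {max_events} events "
            f"before reaching detection size {spec.detect_size}"
        )
    traj = ((buf_t[:n_traj].copy(), buf_y[:n_traj].copy())
            if trajectory_every else None)
    return SimResult(clone_counts=counts, detect_time=float(t),
                     n_seed_events=int(n_seed),
                     n_surviving_seeds=int(n_surv),
                     n_extant_lineages=int(n_ext), mode=mode,
                     trajectory=traj)


def simulate_cohort(model: SeedingModel, spec: DetectionSpec, n_reps: int,
                    seed, mode: str = "exact",
                    promote_size: int = DEFAULT_PROMOTE_SIZE,
                    max_events: int = DEFAULT_MAX_EVENTS) -> SimCohort:
    """Simulate ``n_reps`` independent metastases.

    Replicate streams are derived deterministically from the master seed.
    """
    _check_model(model)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if mode not in ("exact", "hybrid"):
        raise ValueError("mode must be 'exact' or 'hybrid'")
    seeds = _rep_seeds(seed, n_reps)
    counts, times, n_seed, n_surv, n_ext, status = _sim_cohort(
        model.seed_rates, model.birth_rate, model.death_rate,
        float(spec.detect_size), mode == "hybrid", promote_size,
        max_events, seeds,
    )
    if status == 1:
        raise EventBudgetError(
            f"a replicate exceeded the event budget of {max_events} events"
        )
    return SimCohort(counts, times, n_seed, n_surv, n_ext, mode, spec)


def simulate_clone_sizes_at(model: SeedingModel, t: float, n_reps: int,
                            seed, max_events: int = DEFAULT_MAX_EVENTS):
    """Exact per-clone sizes at a fixed time (no detection stop), for
    checking the negative-binomial clone-size law."""
    _check_model(model)
    seeds = _rep_seeds(seed, n_reps)
    out = np.empty((n_reps, model.n_clones), dtype=np.int64)
    for rep in range(n_reps):
        counts, status = _sim_fixed_time(
            model.seed_rates, model.birth_rate, model.death_rate,
            float(t), max_events, seeds[rep],
        )
        if status:
            raise EventBudgetError(
                f"fixed-time simulation exceeded {max_events} events"
            )
        out[rep] = counts
    return out


def simulate_first_seeding_fraction(k: float, n_reps: int, seed,
                                    net_growth: float = 0.0125,
                                    f_start: float | None = None) -> np.ndarray:
    """Source-tumor size fractions at the first surviving downstream seeding.

    Surviving seeding events form an inhomogeneous Poisson process whose
    rate grows with the exponentially growing source and is normalized so
    the surviving influx at the source's mature size equals ``k`` per
    generation; returns the per-replicate fraction of mature size at the
    first event (may exceed 1 when the first seeding happens after the
    source matures).  The geometric mean of these fractions is the
    ``exp(-euler_gamma)/k ~ 56%/k`` headline quantity.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if f_start is None:
        f_start = min(1e-7 / k, 1e-7)
    seeds = _rep_seeds(seed, n_reps)
    return _first_seed_fractions(float(k), float(net_growth), float(f_start),
                                 n_reps, seeds)


def call_clonality(result: SimResult, spec: DetectionSpec):
    """Clone presence calls and clone count under a detection threshold.

    A clone is present when its cell fraction is at least
    ``min_cell_fraction`` (strictly positive size when the threshold is 0).
    """
    counts = result.clone_counts
    if spec.min_cell_fraction > 0:
        present = counts / counts.sum() >= spec.min_cell_fraction
    else:
        present = counts > 0
    return present, int(present.sum())


def cohort_sensitivity(cohort: SimCohort, spec: DetectionSpec) -> float:
    """Fraction of truly polyclonal metastases detected as polyclonal under
    the threshold of ``spec`` (truth = more than one clone of nonzero size)."""
    truly = cohort.presence(0.0).sum(axis=1) > 1
    if not truly.any():
        return float("nan")
    detected = cohort.presence(spec.min_cell_fraction).sum(axis=1) > 1
    return float(detected[truly].mean())
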