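"""Random compartmental systems and an independent particle oracle.

The generator draws structurally valid random systems (non-negative
transfers, positive release somewhere, invertible matrix) for property
tests.  The particle oracle simulates individual carbon "atoms" through
the continuous-time Markov chain defined by the columns of ``B`` —
entry pool drawn proportional to the inputs, jumps and release drawn
from the transfer and release rates — and records entry/exit times.  It
shares no code with the analytic transit-time machinery, so agreement
between the empirical exit-age distribution and the closed-form or
propagated densities is a genuine cross-check.

Time-dependent systems are simulated on a grid of regime breakpoints
with the forcing held at its mid-interval value inside each regime
(exact for piecewise-constant forcing aligned with the breakpoints;
a first-order approximation otherwise).  Entries follow the
correspondingly discretized inhomogeneous Poisson process of rate
``||u(t)||``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .core import CompartmentalError, CompartmentalSystem, validate_compartmental
from .nonautonomous import TimeDependentSystem

__all__ = ["RandomSystemSpec", "random_system", "ParticleEnsemble", "particle_oracle"]

_MAX_RETRIES = 50
_MAX_ROUNDS = 100_000


@dataclass(frozen=True)
class RandomSystemSpec:
    """Parameters of the random-system generator.

    ``connectivity`` is the probability of each off-diagonal transfer
    being present; ``rate_scale`` (yr^-1) centres the log-uniform spread
    of per-pool loss rates (half a decade either side).
    """

    n: int = 3
    connectivity: float = 0.5
    rate_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one pool")
        if not 0.0 <= self.connectivity <= 1.0:
            raise ValueError("connectivity must be a probability")
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")


def random_system(spec: RandomSystemSpec) -> CompartmentalSystem:
    """Draw a valid, invertible random compartmental system (reproducible)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    for _ in range(_MAX_RETRIES):
        k = spec.rate_scale * 10.0 ** rng.uniform(-0.5, 0.5, size=n)
        B = np.diag(-k)
        for j in range(n):
            targets = [i for i in range(n) if i != j and rng.random() < spec.connectivity]
            # split pool j's loss rate between transfers and release
            frac = rng.dirichlet(np.ones(len(targets) + 1))
            for f, i in zip(frac[:-1], targets):
                B[i, j] = f * k[j]
        u = np.where(rng.random(n) < 0.7, rng.uniform(0.5, 2.0, size=n), 0.0)
        if not np.any(u > 0):
            u[rng.integers(n)] = 1.0
        report = validate_compartmental(B, require_invertible=True)
        if report.ok and np.linalg.cond(B) < 1e8:
            return CompartmentalSystem(B=B, u=u)
    raise CompartmentalError("random-system generator exhausted retries")


@dataclass
class ParticleEnsemble:
    """Entry/exit record of simulated carbon atoms.

    ``exit_times`` is NaN for particles still inside the system at the
    end of the simulated span (censored).
    """

    entry_times: NDArray[np.float64]
    exit_times: NDArray[np.float64]
    entry_pools: NDArray[np.int64]

    @property
    def exit_ages(self) -> NDArray[np.float64]:
        """Exit time minus entry time (NaN while censored)."""
        return self.exit_times - self.entry_times

    @property
    def exited(self) -> NDArray[np.bool_]:
        return ~np.isnan(self.exit_times)

    def ages_in_window(self, t_lo: float, t_hi: float) -> NDArray[np.float64]:
        """Exit ages of particles released within ``[t_lo, t_hi]``."""
        m = self.exited & (self.exit_times >= t_lo) & (self.exit_times <= t_hi)
        return self.exit_ages[m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entry_time": self.entry_times,
                "exit_time": self.exit_times,
                "exit_age": self.exit_ages,
                "entry_pool": self.entry_pools,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _simulate_regimes(
    rng: np.random.Generator,
    pools: NDArray[np.int64],
    times: NDArray[np.float64],
    edges: NDArray[np.float64],
    mats: list[NDArray[np.float64]],
) -> NDArray[np.float64]:
    """March particles through piecewise-constant CTMC regimes.

    ``edges`` are regime boundaries (len(mats) + 1, last may be inf);
    particles enter at ``times`` in pools ``pools``; returns exit times
    (NaN if still inside at the final edge).
    """
    n_part = len(pools)
    pool = pools.copy()
    t = times.copy()
    exit_time = np.full(n_part, np.nan)
    alive = np.ones(n_part, dtype=bool)
    for r, Bm in enumerate(mats):
        hi = edges[r + 1]
        in_regime = alive & (t < hi) & (t >= edges[r] - 1e-12)
        k = -np.diag(Bm)
        if np.any(k <= 0):
            # a pool with zero loss rate traps particles for the whole regime
            k = np.where(k <= 0, np.inf, k)
        P_move = Bm - np.diag(np.diag(Bm))  # transfer rates, column j -> row i
        release = -Bm.sum(axis=0)
        rounds = 0
        while np.any(in_regime):
            rounds += 1
            if rounds > _MAX_ROUNDS:
                raise RuntimeError("particle simulation did not converge (rate bound too small?)")
            idx = np.nonzero(in_regime)[0]
            kj = k[pool[idx]]
            wait = rng.exponential(1.0 / kj)
            t_new = t[idx] + wait
            crossed = t_new >= hi
            # particles that cross carry their pool into the next regime
            t[idx[crossed]] = hi
            in_regime[idx[crossed]] = False
            ev = idx[~crossed]
            if len(ev):
                t[ev] = t_new[~crossed]
                pj = pool[ev]
                # release with probability z_j / k_j, otherwise jump
                rel_prob = release[pj] / k[pj]
                u01 = rng.random(len(ev))
                out = u01 < rel_prob
                exit_time[ev[out]] = t[ev[out]]
                alive[ev[out]] = False
                in_regime[ev[out]] = False
                movers = ev[~out]
                pm = pool[movers].copy()  # snapshot: pool is mutated below
                for j in np.unique(pm):
                    sel = movers[pm == j]
                    w = P_move[:, j]
                    pool[sel] = rng.choice(len(w), size=len(sel), p=w / w.sum())
    return exit_time


def particle_oracle(
    system: CompartmentalSystem | TimeDependentSystem,
    n_particles: int,
    seed: int,
    t_span: tuple[float, float] | None = None,
    *,
    breakpoints: NDArray[np.float64] | None = None,
) -> ParticleEnsemble:
    """Monte-Carlo oracle for transit-time distributions.

    For an autonomous :class:`CompartmentalSystem` all particles enter at
    time 0 (pool drawn proportional to ``u``) and their exit times are
    equilibrium transit-time draws.  For a :class:`TimeDependentSystem`
    pass ``t_span``; entries are drawn from the input-flux-weighted
    inhomogeneous Poisson profile over the span and particles evolve
    through the (discretized) time-dependent chain.  Start the span well
    before any output window so the pre-existing carbon is represented.
    """
    rng = np.random.default_rng(seed)
    if isinstance(system, CompartmentalSystem):
        pools = rng.choice(system.n, size=n_particles, p=system.u / system.total_input)
        entry = np.zeros(n_particles)
        exit_time = _simulate_regimes(rng, pools, entry, np.array([0.0, np.inf]), [system.B])
        return ParticleEnsemble(entry_times=entry, exit_times=exit_time, entry_pools=pools)

    tds = system
    if t_span is None:
        raise ValueError("t_span is required for time-dependent systems")
    lo, hi = float(t_span[0]), float(t_span[1])
    if breakpoints is None:
        breakpoints = np.arange(lo, hi + 0.5, 1.0)
    edges = np.unique(np.clip(np.asarray(breakpoints, dtype=float), lo, hi))
    if edges[0] > lo:
        edges = np.concatenate([[lo], edges])
    if edges[-1] < hi:
        edges = np.concatenate([edges, [hi]])
    mids = 0.5 * (edges[:-1] + edges[1:])
    mats = [np.asarray(tds.B_t(m), dtype=float) for m in mids]
    u_mid = np.array([tds.u_t(m) for m in mids])
    # distribute entries across regimes by input mass, uniformly within each
    w = u_mid.sum(axis=1) * np.diff(edges)
    counts = rng.multinomial(n_particles, w / w.sum())
    entry = np.concatenate([rng.uniform(edges[r], edges[r + 1], size=c) for r, c in enumerate(counts)])
    pools = np.concatenate(
        [rng.choice(tds.n, size=c, p=u_mid[r] / u_mid[r].sum()) for r, c in enumerate(counts)]
    ).astype(np.int64)
    order = np.argsort(entry)
    entry, pools = entry[order], pools[order]
    exit_time = _simulate_regimes(rng, pools, entry, edges, mats)
    return ParticleEnsemble(entry_times=entry, exit_times=exit_time, entry_pools=pools)
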