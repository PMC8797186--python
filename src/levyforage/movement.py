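"""Truncated power-law move lengths and the digital organism's random walk.

A digital organism (DO) draws integer move lengths from a truncated discrete
power law

    P(l) ∝ l**(-u),   1 <= l <= n/2,

moves cell by cell along one of the four axis directions, and *truncates* the
current move the moment it arrives on a cell holding resources.  Exponents
1 < u < 3 give Lévy-like (heavy-tailed) movement, u >= 3 Brownian-like
movement dominated by unit steps, and u near or below 1 ballistic movement.
Any real u, including u <= 0, is legal: evolution is free to wander there.

Bookkeeping per timestep t (a move of length l takes ceil(l/s) timesteps at
speed s):

* ``xi``        cumulative resources encountered since birth,
* ``alpha_xi``  running sum of xi over timesteps (power for the
  lifespan-averaged energy),
* ``d``         cumulative cells traversed,
* ``alpha_d``   running sum of d over timesteps.

All four counters are pure integers, which is what makes search costs exactly
post-hoc applicable (see :mod:`levyforage.energetics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

import numpy as np

from ._kernels import walk_kernel, xs64_stream
from .environment import Environment

MOVE_TABLE_SIZE = 10_000
DIRECTION_ANGLES = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)
# heading code -> (di, dj); 0 = +j, pi/2 = -i, pi = -j, 3pi/2 = +i
HEADING_STEPS = ((0, 1), (-1, 0), (0, -1), (1, 0))


def truncated_power_law_pmf(u: float, l_min: int, l_max: int) -> np.ndarray:
    """Normalized pmf of the truncated discrete power law on [l_min, l_max].

    ``pmf[k]`` is the probability of length ``l_min + k``.  u may be any real:
    u = 0 is uniform and u < 0 puts increasing mass on long moves.
    """
    if not 1 <= l_min <= l_max:
        raise ValueError(
            f"invalid support: need 1 <= l_min <= l_max, got [{l_min}, {l_max}]"
        )
    lengths = np.arange(l_min, l_max + 1, dtype=np.float64)
    weights = lengths ** (-float(u))
    return weights / weights.sum()


def sample_move_lengths(
    u: float, l_min: int, l_max: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. draws from the truncated power law via inverse CDF."""
    cdf = np.cumsum(truncated_power_law_pmf(u, l_min, l_max))
    out = l_min + np.searchsorted(cdf, rng.random(size), side="right")
    return np.minimum(out, l_max).astype(np.int64)


def build_move_table(
    u: float, n: int, size: int = MOVE_TABLE_SIZE,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """The DO's table S: ``size`` pre-sampled lengths on [1, n // 2]."""
    if n < 2:
        raise ValueError(f"need n >= 2 for a non-degenerate support, got n={n}")
    rng = np.random.default_rng(rng)
    return sample_move_lengths(u, 1, n // 2, size, rng)


def sample_direction(rng: np.random.Generator) -> float:
    """One of the four axis headings {0, pi/2, pi, 3pi/2}, uniformly."""
    return DIRECTION_ANGLES[int(rng.integers(0, 4))]


@dataclass
class MoveLengthDistribution:
    """Exponent, support, pmf and the pre-sampled move-length table S."""

    u: float
    l_min: int
    l_max: int
    pmf: np.ndarray
    S: np.ndarray

    @classmethod
    def build(
        cls, u: float, n: int, size: int = MOVE_TABLE_SIZE,
        rng: np.random.Generator | None = None,
    ) -> "MoveLengthDistribution":
        l_max = n // 2
        return cls(
            u=float(u),
            l_min=1,
            l_max=l_max,
            pmf=truncated_power_law_pmf(u, 1, l_max),
            S=build_move_table(u, n, size, rng),
        )


@dataclass
class LifespanRecord:
    """Terminal counters of one completed lifespan; all energies derive here."""

    u: float
    xi: int
    alpha_xi: int
    d: int
    alpha_d: int
    lam: int
    s: int

    CSV_COLUMNS = ("u", "xi", "alpha_xi", "d", "alpha_d", "lambda", "s", "seed")


@dataclass
class DigitalOrganism:
    """Walker state: move-length table plus position, lifespan budget and counters."""

    dist: MoveLengthDistribution
    lam: int
    s: int = 1
    position: tuple[int, int] | None = None
    t: int = 0
    xi: int = 0
    alpha_xi: int = 0
    d: int = 0
    alpha_d: int = 0


def run_lifespan(
    org: DigitalOrganism,
    env: Environment,
    rng: np.random.Generator,
    record_trace: bool = False,
):
    """Walk ``org`` through ``env`` for its whole lifespan.

    The organism starts at a uniform random cell (unless ``org.position`` is
    preset), then repeats: draw a length uniformly from S and a heading from
    the four axis directions; advance one cell per unit of speed, wrapping on
    the torus; on arrival at a non-empty cell, add its count to ``xi`` and end
    the move there.  Each timestep covers at most ``s`` cells of a single move
    and closes by accumulating ``alpha_xi += xi`` and ``alpha_d += d``.

    Returns the :class:`LifespanRecord`; with ``record_trace=True`` returns
    ``(record, (e_log, d_log))`` where index t of each log holds that
    timestep's resources found and cells traversed (index 0 is zero).
    """
    if org.t != 0:
        raise ValueError("organism has already lived: t must be 0")
    S = np.asarray(org.dist.S, dtype=np.int64)
    if S.size == 0:
        raise ValueError("invalid organism: empty move-length table S")
    if org.lam < 1:
        raise ValueError(f"lifespan must be >= 1, got {org.lam}")
    if org.s < 1:
        raise ValueError(f"speed must be >= 1, got {org.s}")
    if org.position is None:
        i0 = int(rng.integers(0, env.n))
        j0 = int(rng.integers(0, env.n))
    else:
        i0, j0 = org.position
    seed = np.uint64(rng.integers(1, 2**63, dtype=np.int64))
    if record_trace:
        e_log = np.zeros(org.lam + 1, dtype=np.int64)
        d_log = np.zeros(org.lam + 1, dtype=np.int64)
    else:
        e_log = np.zeros(1, dtype=np.int64)
        d_log = np.zeros(1, dtype=np.int64)
    xi, axi, d, ad, i, j = walk_kernel(
        env.grid, np.int64(env.n), S, np.int64(org.lam), np.int64(org.s),
        np.int64(i0), np.int64(j0), seed, e_log, d_log, record_trace,
    )
    org.t = org.lam
    org.xi, org.alpha_xi, org.d, org.alpha_d = int(xi), int(axi), int(d), int(ad)
    org.position = (int(i), int(j))
    rec = LifespanRecord(
        u=org.dist.u, xi=int(xi), alpha_xi=int(axi), d=int(d), alpha_d=int(ad),
        lam=org.lam, s=org.s,
    )
    if record_trace:
        return rec, (e_log, d_log)
    return rec


# ---------------------------------------------------------------------------
# Pure-Python reference walker: the independent oracle for walk_kernel.
# ---------------------------------------------------------------------------

def draws_from_table(S: Iterable[int], seed: int) -> Iterator[tuple[int, int]]:
    """Yield (length, heading) pairs exactly as walk_kernel draws them.

    Replays the kernel's xorshift64* stream so a reference walk and a kernel
    walk from the same seed follow identical trajectories.
    """
    S = list(S)
    stream = xs64_stream(seed)
    while True:
        length = S[next(stream) % len(S)]
        heading = next(stream) % 4
        yield int(length), int(heading)


def walk_reference(
    grid: np.ndarray,
    n: int,
    lam: int,
    s: int,
    start: tuple[int, int],
    draws: Iterator[tuple[int, int]] | Callable[[], tuple[int, int]],
):
    """Slow, transparent re-implementation of the lifespan walk.

    ``draws`` supplies (length, heading) per move — an iterator (e.g.
    :func:`draws_from_table`, or a scripted list) or a zero-arg callable.
    Returns ``(record_tuple, e_log, d_log)`` with
    ``record_tuple = (xi, alpha_xi, d, alpha_d)``.
    """
    next_draw = draws if callable(draws) else lambda it=iter(draws): next(it)
    i, j = start
    xi = axi = d = ad = 0
    remaining = 0
    di = dj = 0
    e_log = [0] * (lam + 1)
    d_log = [0] * (lam + 1)
    for t in range(1, lam + 1):
        if remaining == 0:
            length, heading = next_draw()
            di, dj = HEADING_STEPS[heading]
            remaining = length
        found = 0
        delta = 0
        for _ in range(min(s, remaining)):
            i = (i + di) % n
            j = (j + dj) % n
            delta += 1
            remaining -= 1
            e = int(grid[i, j])
            if e > 0:
                found = e
                remaining = 0
                break
        xi += found
        d += delta
        axi += xi
        ad += d
        e_log[t] = found
        d_log[t] = delta
    return (xi, axi, d, ad), e_log, d_log
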