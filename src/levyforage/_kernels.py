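"""Numba-compiled inner loop of the truncated random walk.

The kernel advances a forager cell by cell on the torus for a full lifespan,
drawing move lengths uniformly from a pre-sampled table ``S`` and directions
from the four axis-aligned headings.  Randomness comes from an explicit
xorshift64* stream so the identical trajectory can be reproduced by the pure
Python reference walker in :mod:`levyforage.movement` — the two are compared
exactly in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_M = np.uint64(0x2545F4914F6CDD1D)  # xorshift64* output multiplier


@njit(cache=True, inline="always")
def _xs64_next(state):
    # xorshift64*: state update; caller multiplies by _M for the output value
    state ^= state >> np.uint64(12)
    state ^= state << np.uint64(25)
    state ^= state >> np.uint64(27)
    return state


def xs64_stream(seed: int):
    """Python generator replaying the kernel's xorshift64* output stream."""
    mask = (1 << 64) - 1
    state = int(seed) & mask
    if state == 0:
        state = 1
    mult = int(_M)
    while True:
        state ^= state >> 12
        state = (state ^ (state << 25)) & mask
        state ^= state >> 27
        yield (state * mult) & mask


@njit(cache=True)
def walk_kernel(grid, n, S, lam, s, i0, j0, seed, e_log, d_log, record):
    """Run one lifespan; returns (xi, alpha_xi, d, alpha_d, i, j).

    grid : (n, n) int64 resource counts (read-only, resources revisitable)
    S    : int64 move-length table, drawn from uniformly with replacement
    lam  : lifespan in timesteps; s : speed in cells per timestep
    seed : nonzero uint64 xorshift64* state
    e_log, d_log : int64 arrays of length lam+1 filled with per-timestep
        resources found and cells traversed when ``record`` is true
        (index 0 stays 0); pass length-1 dummies otherwise.
    """
    state = seed
    if state == np.uint64(0):
        state = np.uint64(1)
    size = np.uint64(len(S))
    i = i0
    j = j0
    xi = np.int64(0)
    axi = np.int64(0)
    d = np.int64(0)
    ad = np.int64(0)
    remaining = np.int64(0)
    di = np.int64(0)
    dj = np.int64(0)
    for t in range(1, lam + 1):
        if remaining == 0:
            state = _xs64_next(state)
            idx = (state * _M) % size
            length = S[idx]
            state = _xs64_next(state)
            heading = (state * _M) % np.uint64(4)
            if heading == np.uint64(0):    # angle 0      -> +j
                di, dj = np.int64(0), np.int64(1)
            elif heading == np.uint64(1):  # angle pi/2   -> -i
                di, dj = np.int64(-1), np.int64(0)
            elif heading == np.uint64(2):  # angle pi     -> -j
                di, dj = np.int64(0), np.int64(-1)
            else:                          # angle 3pi/2  -> +i
                di, dj = np.int64(1), np.int64(0)
            remaining = length
        found = np.int64(0)
        delta = np.int64(0)
        budget = s if s < remaining else remaining
        for _c in range(budget):
            i = (i + di) % n
            j = (j + dj) % n
            delta += 1
            remaining -= 1
            e = grid[i, j]
            if e > 0:
                # truncation: collect and end the move on the resource cell
                found = e
                remaining = np.int64(0)
                break
        xi += found
        d += delta
        axi += xi
        ad += d
        if record:
            e_log[t] = found
            d_log[t] = delta
    return xi, axi, d, ad, i, j
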