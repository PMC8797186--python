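"""Energy accounting: end-of-lifespan and lifespan-averaged fitness.

A forager's energy at timestep t is

    eps_{t+1} = eps_t + e_t - chi * delta_t,    eps_0 = 0,

where e_t is the resources found and delta_t the cells traversed in timestep
t, and chi >= 0 is a constant search cost per cell.  Because the update is
linear, both fitness summaries are exact functions of four terminal counters,
so cost can be applied *post hoc* to a zero-cost run:

    eps_EOL = xi_lam - chi * d_lam                     (semelparity proxy)
    eps_AOL = alpha_xi_lam / lam - chi * alpha_d_lam / lam   (iteroparity proxy)

The :func:`stepwise_energy_oracle` accumulates the per-timestep recursion
directly and must agree with the post-hoc formulas exactly — pass
``fractions.Fraction`` costs to check this at integer-arithmetic precision.
A forager with energy <= 0 under the metric in use is considered dead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .movement import LifespanRecord


@dataclass
class EnergyResult:
    """Both energies at one search cost, plus the survival flag per metric."""

    chi: float
    e_eol: float
    e_aol: float
    alive_eol: bool
    alive_aol: bool


def energy_eol(rec: LifespanRecord, chi) -> float:
    """End-of-lifespan energy: ``xi - chi * d``.  chi = 0 gives xi itself."""
    _check_chi(chi)
    return rec.xi - chi * rec.d


def energy_aol(rec: LifespanRecord, chi) -> float:
    """Lifespan-averaged energy: ``(alpha_xi - chi * alpha_d) / lam``.

    At speed 1 this reduces to ``alpha_xi/lam - chi (lam+1)/2`` since the
    distance sum is the triangular number lam(lam+1)/2.
    """
    _check_chi(chi)
    if rec.lam == 0:
        raise ZeroDivisionError("undefined average: lifespan lam must be >= 1")
    return (rec.alpha_xi - chi * rec.alpha_d) / rec.lam


def evaluate(rec: LifespanRecord, chi) -> EnergyResult:
    eol = energy_eol(rec, chi)
    aol = energy_aol(rec, chi)
    return EnergyResult(chi=chi, e_eol=eol, e_aol=aol,
                        alive_eol=eol > 0, alive_aol=aol > 0)


def _check_chi(chi) -> None:
    if chi < 0:
        raise ValueError(f"search cost chi must be >= 0, got {chi}")


def stepwise_energy_oracle(event_log, chi, lam: int):
    """Accumulate the energy recursion timestep by timestep.

    ``event_log`` is a sequence of ``(t, e_t, delta_t)`` triples covering
    every timestep t = 0..lam exactly once.  Returns ``(eps_EOL, eps_AOL)``
    where eps_AOL = (1/lam) * sum_{t=0..lam} eps_t.

    This is the slow, definitional route; the post-hoc formulas above must
    match it exactly.
    """
    if lam < 1:
        raise ZeroDivisionError("undefined average: lifespan lam must be >= 1")
    steps = {}
    for t, e_t, delta_t in event_log:
        if t == 0 and (e_t or delta_t):
            raise ValueError("t = 0 precedes the first move: e_0 = delta_0 = 0")
        steps[t] = (e_t, delta_t)
    if set(steps) != set(range(lam + 1)):
        raise ValueError(f"incomplete log: need one entry per timestep 0..{lam}")
    eps = chi * 0  # accumulators inherit chi's numeric type (Fraction stays exact)
    total = chi * 0  # sum of eps_t over t = 0..lam (eps_0 = 0)
    for t in range(1, lam + 1):
        e_t, delta_t = steps[t]
        eps = eps + e_t - chi * delta_t
        total = total + eps
    return eps, total / lam


def stepwise_from_logs(e_log: Sequence[int], d_log: Sequence[int], chi, lam: int):
    """Convenience wrapper over dense per-timestep logs (index = t)."""
    if len(e_log) < lam + 1 or len(d_log) < lam + 1:
        raise ValueError(f"incomplete log: need entries for t = 0..{lam}")
    log = [(t, e_log[t], d_log[t]) for t in range(lam + 1)]
    return stepwise_energy_oracle(log, chi, lam)


# ---------------------------------------------------------------------------
# Closed forms for idealized encounter schedules (speed 1, zero cost).
# ---------------------------------------------------------------------------

def _check_spacing(n: int, k: int) -> None:
    if k < 1:
        raise ValueError(f"spacing k must be >= 1, got {k}")
    if n % k != 0:
        raise ValueError(f"spacing k={k} must divide total distance n={n}")


def evenly_spaced_closed_form(n: int, k: int) -> tuple[float, float, float]:
    """Energies of a walker meeting one resource every k of n steps.

    eps_EOL = n/k;  eps_AOL = (n+2)/(2k) - 1/2.  Returns (eps_EOL, eps_AOL,
    ratio).  The ratio tends to 1/2 for n >> k — balanced discovery over the
    lifespan — and departs linearly from 1/2 as k approaches n.
    """
    _check_spacing(n, k)
    eol = n / k
    aol = (n + 2) / (2 * k) - 0.5
    return eol, aol, aol / eol


def clustered_closed_form(n: int, k: int, mode: str) -> float:
    """Lifespan-averaged energy when all n/k encounters come in sequence at
    the start or the end of the lifespan.

    start: eps_AOL = (2n - n/k + 1) / (2k)   (ratio -> 1 as k grows)
    end:   eps_AOL = (n/k + 1) / (2k)        (ratio -> 0 as k grows)

    Both coincide with the evenly spaced value at k = 1, the only spacing
    with ratio (n+1)/(2n) ~ 1/2.
    """
    _check_spacing(n, k)
    m = n // k
    if mode == "start":
        return (2 * n - m + 1) / (2 * k)
    if mode == "end":
        return (m + 1) / (2 * k)
    raise ValueError(f"mode must be 'start' or 'end', got {mode!r}")


def clustered_bruteforce(n: int, k: int, mode: str) -> float:
    """Definitional per-timestep sum for the clustered schedules (oracle)."""
    _check_spacing(n, k)
    m = n // k
    if mode == "start":
        times = range(1, m + 1)
    elif mode == "end":
        times = range(n - m + 1, n + 1)
    else:
        raise ValueError(f"mode must be 'start' or 'end', got {mode!r}")
    encounter = set(times)
    eps = 0  # one unit-value resource per encounter timestep
    total = 0
    for t in range(1, n + 1):
        if t in encounter:
            eps += 1
        total += eps
    return total / n
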