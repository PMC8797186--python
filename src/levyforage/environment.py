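"""Toroidal lattice environments populated with revisitable resources.

An environment is an ``n x n`` torus whose cells hold non-negative integer
resource counts.  Resources are *revisitable*: a forager that lands on a
non-empty cell collects the cell's count but never depletes it.  Two point
processes are provided for placing resources:

* ``uniform_random`` -- independent uniform draws of cells, with replacement,
  so a cell may accumulate a count greater than one;
* ``levy_dust`` -- the visited points of a lattice Lévy flight whose move
  lengths follow a truncated discrete power law with exponent ``u`` (the
  fractal dimension of the resulting point set is ``u - 1``).  Larger ``u``
  yields clumpier, less homogeneous resource patterns.

The default deposit budget is ``floor(n**2 * 1e-4)`` resources, the sparse
density at which a foraging exponent near 2 is classically optimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_DENSITY = 1e-4

# direction codes 0..3 <-> angles {0, pi/2, pi, 3pi/2}; (di, dj) steps.
# 0 = +j, pi/2 = -i, pi = -j, 3pi/2 = +i  (row = i grows downward)
DIRECTION_STEPS = np.array([[0, 1], [-1, 0], [0, -1], [1, 0]], dtype=np.int64)


def default_deposits(n: int, density: float = DEFAULT_DENSITY) -> int:
    """Deposit budget at a given resource density: ``floor(n**2 * density)``."""
    return int(np.floor(n * n * density))


def wrap_position(i: int, j: int, n: int) -> tuple[int, int]:
    """Wrap a lattice coordinate onto the ``n x n`` torus.

    Returns ``(i mod n, j mod n)``, each in ``[0, n)``.
    """
    if n <= 0:
        raise ValueError(f"invalid environment: side length n must be >= 1, got {n}")
    return (i % n, j % n)


@dataclass
class Environment:
    """A toroidal resource landscape.

    Attributes
    ----------
    n : side length in cells.
    grid : dense ``(n, n)`` int64 array of resource counts ``e[i, j] >= 0``.
    recipe : ``"uniform_random"`` or ``"levy_dust"``.
    u : dust exponent (``levy_dust`` recipe only, else ``None``).
    seed : entropy used to build the landscape, kept for provenance.
    """

    n: int
    grid: np.ndarray
    recipe: str
    u: float | None = None
    seed: int | None = None
    _entries: dict[tuple[int, int], int] | None = field(default=None, repr=False)

    @property
    def total_deposits(self) -> int:
        return int(self.grid.sum())

    @property
    def entries(self) -> dict[tuple[int, int], int]:
        """Sparse view: mapping ``(i, j) -> count`` for non-empty cells."""
        if self._entries is None:
            ii, jj = np.nonzero(self.grid)
            self._entries = {
                (int(i), int(j)): int(self.grid[i, j]) for i, j in zip(ii, jj)
            }
        return self._entries

    def save(self, csv_path: str | Path) -> None:
        """Write sparse ``i,j,count`` CSV plus a JSON metadata sidecar."""
        csv_path = Path(csv_path)
        with open(csv_path, "w") as fh:
            fh.write("i,j,count\n")
            for (i, j), c in sorted(self.entries.items()):
                fh.write(f"{i},{j},{c}\n")
        meta = {
            "n": self.n,
            "recipe": self.recipe,
            "u": self.u,
            "seed": self.seed,
            "total_deposits": self.total_deposits,
        }
        csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, csv_path: str | Path) -> "Environment":
        csv_path = Path(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        grid = np.zeros((meta["n"], meta["n"]), dtype=np.int64)
        with open(csv_path) as fh:
            next(fh)  # header
            for line in fh:
                i, j, c = line.strip().split(",")
                grid[int(i), int(j)] = int(c)
        env = cls(n=meta["n"], grid=grid, recipe=meta["recipe"],
                  u=meta["u"], seed=meta["seed"])
        if env.total_deposits != meta["total_deposits"]:
            raise ValueError("corrupt environment file: deposit count mismatch")
        return env


def _check_env_args(n: int, n_deposits: int) -> None:
    if n < 1:
        raise ValueError(f"invalid environment: side length n must be >= 1, got {n}")
    if n_deposits < 0:
        raise ValueError(f"n_deposits must be >= 0, got {n_deposits}")


def make_uniform_environment(
    n: int, n_deposits: int | None = None, rng: np.random.Generator | None = None,
) -> Environment:
    """Uniform-random landscape: ``n_deposits`` independent cell draws with
    replacement, each incrementing its cell's count.

    With ``n_deposits=None`` the budget defaults to ``floor(n**2 * 1e-4)``.
    """
    if n_deposits is None:
        n_deposits = default_deposits(n)
    _check_env_args(n, n_deposits)
    rng = np.random.default_rng(rng)
    grid = np.zeros((n, n), dtype=np.int64)
    if n_deposits:
        flat = rng.integers(0, n * n, size=n_deposits)
        np.add.at(grid.reshape(-1), flat, 1)
    return Environment(n=n, grid=grid, recipe="uniform_random")


def make_levy_dust_environment(
    n: int,
    n_deposits: int | None = None,
    u: float = 2.0,
    rng: np.random.Generator | None = None,
    return_points: bool = False,
):
    """Lévy-dust landscape: deposits are the successive endpoints of a lattice
    Lévy flight with truncated power-law move lengths (exponent ``u``) and
    axis-aligned directions.

    The generator walk starts at a uniform random cell, which receives the
    first deposit; each subsequent jump lands torus-wrapped on a cell whose
    count is incremented.  Only jump *endpoints* are deposited, not the cells
    traversed en route.

    With ``return_points`` the (n_deposits, 2) array of deposit coordinates in
    walk order is returned alongside the environment (diagnostics: successive
    axis displacements recover the generator's jump lengths).
    """
    from .movement import truncated_power_law_pmf  # local import, no cycle at module load

    if n < 2:
        raise ValueError(f"invalid environment: levy_dust needs n >= 2, got {n}")
    if n_deposits is None:
        n_deposits = default_deposits(n)
    _check_env_args(n, n_deposits)
    rng = np.random.default_rng(rng)
    grid = np.zeros((n, n), dtype=np.int64)
    points = np.empty((n_deposits, 2), dtype=np.int64)
    if n_deposits:
        l_max = n // 2
        pmf = truncated_power_law_pmf(u, 1, l_max)
        cdf = np.cumsum(pmf)
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n))
        grid[i, j] += 1
        points[0] = (i, j)
        k = n_deposits - 1
        if k > 0:
            lengths = 1 + np.searchsorted(cdf, rng.random(k), side="right")
            np.clip(lengths, 1, l_max, out=lengths)
            steps = DIRECTION_STEPS[rng.integers(0, 4, size=k)]
            pos = (np.cumsum(steps * lengths[:, None], axis=0) + [i, j]) % n
            np.add.at(grid.reshape(-1), pos[:, 0] * n + pos[:, 1], 1)
            points[1:] = pos
    env = Environment(n=n, grid=grid, recipe="levy_dust", u=u)
    if return_points:
        return env, points
    return env


def make_environment(
    recipe: str,
    n: int,
    n_deposits: int | None = None,
    u: float | None = None,
    rng: np.random.Generator | None = None,
) -> Environment:
    """Dispatch on recipe name (``uniform_random`` / ``ru`` or ``levy_dust`` / ``ld``)."""
    key = recipe.lower()
    if key in ("uniform_random", "ru", "uniform"):
        return make_uniform_environment(n, n_deposits, rng)
    if key in ("levy_dust", "ld", "dust"):
        if u is None:
            raise ValueError("levy_dust recipe requires a dust exponent u")
        return make_levy_dust_environment(n, n_deposits, u, rng)
    raise ValueError(f"unknown environment recipe: {recipe!r}")
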