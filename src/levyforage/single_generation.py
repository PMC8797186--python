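"""Single-generation parameter sweeps and their two analyses.

A sweep releases a population of digital organisms with foraging exponents
drawn uniformly from a range (default [0, 6]) into one landscape and records
every terminal counter.  Costs are applied post hoc, so one zero-cost sweep
serves every search cost.  Two analyses follow:

* sliding-window fitness moments over the exponent axis — the windowed first
  moment (WFM), positive-only first moment (PWFM, survivors only) and SD,
  from which ``u_MAX``, the empirically optimal exponent, is read off;
* top-percentile subsampling — 1000 random sub-populations per population
  size, keeping the exponents of the top 1% of survivors, mapping how
  selection strength varies with population size.

A third utility regresses the lifespan-averaged energy on the end-of-lifespan
energy (OLS and Theil–Sen); across long lifespans the slope sits near 1/2,
the signature of encounter times spread evenly over the lifespan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .environment import Environment, default_deposits, make_environment
from .movement import MOVE_TABLE_SIZE, DigitalOrganism, MoveLengthDistribution, run_lifespan

TABLE_COLUMNS = ["u", "xi", "alpha_xi", "d", "alpha_d", "lambda", "s"]


@dataclass
class SweepConfig:
    """Study conditions for one single-generation sweep."""

    population: int = 50_000
    u_range: tuple[float, float] = (0.0, 6.0)
    lam: int = 1_000_000
    s: int = 1
    n: int = 1000
    n_deposits: int | None = None  # None -> floor(n^2 * 1e-4)
    recipe: str = "uniform_random"
    dust_u: float | None = None
    # one fresh landscape draw per organism instead of a single shared one:
    # estimates the fitness relationship over the environment ensemble rather
    # than conditional on one realization (used by the AOL~EOL regression)
    env_per_organism: bool = False

    def validate(self) -> "SweepConfig":
        if self.population < 1:
            raise ValueError(f"population must be >= 1, got {self.population}")
        if self.u_range[0] > self.u_range[1]:
            raise ValueError(f"u_range must be (low, high), got {self.u_range}")
        if self.lam < 1:
            raise ValueError(f"lam must be >= 1, got {self.lam}")
        if self.s < 1:
            raise ValueError(f"s must be >= 1, got {self.s}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.recipe.lower() in ("levy_dust", "ld", "dust") and self.dust_u is None:
            raise ValueError("dust_u is required for a levy_dust recipe")
        return self


def run_sweep(
    config: SweepConfig,
    rng: np.random.Generator,
    environment: Environment | None = None,
) -> pd.DataFrame:
    """Run every organism through the landscape and tabulate its counters.

    Each organism draws its exponent from U(u_range), builds its own
    move-length table, and traverses the (shared, read-only — resources are
    never consumed, so a shared landscape is behaviourally identical to
    per-organism copies) environment for ``lam`` timesteps.
    """
    config.validate()
    if environment is None and not config.env_per_organism:
        environment = make_environment(
            config.recipe, config.n, config.n_deposits, config.dust_u, rng
        )
    lo, hi = config.u_range
    exponents = rng.uniform(lo, hi, size=config.population)
    rows = np.empty((config.population, 4), dtype=np.int64)
    for k, u in enumerate(exponents):
        if config.env_per_organism:
            environment = make_environment(
                config.recipe, config.n, config.n_deposits, config.dust_u, rng
            )
        dist = MoveLengthDistribution.build(u, environment.n, MOVE_TABLE_SIZE, rng)
        org = DigitalOrganism(dist=dist, lam=config.lam, s=config.s)
        rec = run_lifespan(org, environment, rng)
        rows[k] = (rec.xi, rec.alpha_xi, rec.d, rec.alpha_d)
    table = pd.DataFrame(
        {
            "u": exponents,
            "xi": rows[:, 0],
            "alpha_xi": rows[:, 1],
            "d": rows[:, 2],
            "alpha_d": rows[:, 3],
            "lambda": config.lam,
            "s": config.s,
        }
    )
    return table


def table_energies(table: pd.DataFrame, chi: float, metric: str) -> np.ndarray:
    """Post-hoc energies for every row of a sweep table."""
    metric = metric.lower()
    if metric == "eol":
        return table["xi"].to_numpy() - chi * table["d"].to_numpy()
    if metric == "aol":
        lam = table["lambda"].to_numpy()
        return (table["alpha_xi"].to_numpy() - chi * table["alpha_d"].to_numpy()) / lam
    raise ValueError(f"metric must be 'eol' or 'aol', got {metric!r}")


@dataclass
class WindowStats:
    """Sliding-window fitness moments over the exponent axis."""

    centers: np.ndarray
    wfm: np.ndarray
    pwfm: np.ndarray
    sd: np.ndarray
    u_max: float
    moment: str = "pwfm"
    window_width: float = 0.25
    step: float = 0.01

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"u_center": self.centers, "wfm": self.wfm,
             "pwfm": self.pwfm, "sd": self.sd}
        )


def sliding_window_stats(
    table: pd.DataFrame,
    chi: float = 0.0,
    metric: str = "aol",
    window_width: float = 0.25,
    step: float = 0.01,
    moment: str = "pwfm",
) -> WindowStats:
    """Windowed fitness moments and the maximizing exponent ``u_MAX``.

    For each window center c the WFM is the mean energy of organisms with
    ``|u - c| <= width/2``, the PWFM the mean over those with energy > 0
    (NaN when the window holds none), and SD the sample standard deviation.
    ``u_MAX`` is the center of the window maximizing the chosen moment;
    ties resolve to the lowest center.
    """
    if len(table) == 0:
        raise ValueError("empty sweep table")
    u = table["u"].to_numpy()
    e = table_energies(table, chi, metric)
    lo, hi = float(u.min()), float(u.max())
    if window_width > hi - lo:
        raise ValueError(
            f"window_width={window_width} exceeds the exponent range [{lo}, {hi}]"
        )
    half = window_width / 2
    n_centers = int(math.floor((hi - lo - window_width) / step)) + 1
    centers = lo + half + step * np.arange(n_centers)

    order = np.argsort(u, kind="stable")
    u_sorted = u[order]
    e_sorted = e[order]
    pos = e_sorted > 0
    cum_e = np.concatenate([[0.0], np.cumsum(e_sorted)])
    cum_e2 = np.concatenate([[0.0], np.cumsum(e_sorted**2)])
    cum_pe = np.concatenate([[0.0], np.cumsum(np.where(pos, e_sorted, 0.0))])
    cum_pn = np.concatenate([[0], np.cumsum(pos.astype(np.int64))])

    left = np.searchsorted(u_sorted, centers - half, side="left")
    right = np.searchsorted(u_sorted, centers + half, side="right")
    count = right - left
    with np.errstate(invalid="ignore", divide="ignore"):
        wfm = np.where(count > 0, (cum_e[right] - cum_e[left]) / count, np.nan)
        npos = cum_pn[right] - cum_pn[left]
        pwfm = np.where(npos > 0, (cum_pe[right] - cum_pe[left]) / npos, np.nan)
        ss = cum_e2[right] - cum_e2[left]
        var = np.where(
            count > 1, (ss - count * wfm**2) / (count - 1), np.nan
        )
        sd = np.sqrt(np.maximum(var, 0.0))

    moment = moment.lower()
    curve = {"wfm": wfm, "pwfm": pwfm}[moment]
    if np.all(np.isnan(curve)):
        raise ValueError("no window holds any admissible organism")
    u_max = float(centers[np.nanargmax(curve)])  # nanargmax returns first max
    return WindowStats(
        centers=centers, wfm=wfm, pwfm=pwfm, sd=sd, u_max=u_max,
        moment=moment, window_width=window_width, step=step,
    )


@dataclass
class SubsampleResult:
    """Exponent frequencies of top performers across sub-population sizes."""

    frequencies: pd.DataFrame  # columns: size, u_center, frequency (per-size max = 1)
    skipped: dict[int, int] = field(default_factory=dict)  # size -> dead replicates


def subsample_top_percent(
    table: pd.DataFrame,
    chi: float,
    rng: np.random.Generator,
    metric: str = "aol",
    sizes: range | list[int] | None = None,
    replicates: int = 1000,
    fraction: float = 0.01,
    u_bins: np.ndarray | None = None,
) -> SubsampleResult:
    """Exponent spectrum of the top ``fraction`` of random sub-populations.

    For each size, ``replicates`` sub-populations are drawn without
    replacement (with replacement across replicates); dead organisms
    (energy <= 0) are excluded before ranking; the best ``ceil(fraction *
    size)`` exponents are kept.  Replicates whose whole sample is dead are
    skipped and counted.  Frequencies are histogrammed over ``u_bins`` and
    normalized to [0, 1] within each size.
    """
    if sizes is None:
        sizes = range(10, 1501, 10)
    sizes = list(sizes)
    if len(table) <= max(sizes):
        raise ValueError(
            f"table of {len(table)} rows cannot supply sub-populations of "
            f"size {max(sizes)} without replacement"
        )
    u = table["u"].to_numpy()
    e = table_energies(table, chi, metric)
    if u_bins is None:
        u_bins = np.linspace(u.min(), u.max(), 61)
    centers = 0.5 * (u_bins[:-1] + u_bins[1:])
    n_rows = len(table)
    frames = []
    skipped: dict[int, int] = {}
    for size in sizes:
        keep = max(1, math.ceil(fraction * size))
        counts = np.zeros(len(centers), dtype=np.int64)
        dead_reps = 0
        for _ in range(replicates):
            idx = rng.choice(n_rows, size=size, replace=False)
            e_s = e[idx]
            alive = e_s > 0
            n_alive = int(alive.sum())
            if n_alive == 0:
                dead_reps += 1
                continue
            idx_alive = idx[alive]
            e_alive = e_s[alive]
            k = min(keep, n_alive)
            top = np.argpartition(-e_alive, k - 1)[:k]
            counts += np.histogram(u[idx_alive[top]], bins=u_bins)[0]
        freq = counts / counts.max() if counts.max() > 0 else counts.astype(float)
        frames.append(pd.DataFrame(
            {"size": size, "u_center": centers, "frequency": freq}
        ))
        skipped[size] = dead_reps
    return SubsampleResult(frequencies=pd.concat(frames, ignore_index=True),
                           skipped=skipped)


@dataclass
class RegressionResult:
    """OLS and Theil–Sen fits of eps_AOL on eps_EOL."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    ts_slope: float
    ts_intercept: float
    ts_slope_low: float
    ts_slope_high: float


def aol_eol_regression(table: pd.DataFrame) -> RegressionResult:
    """Regress lifespan-averaged on end-of-lifespan energy at zero cost.

    Reports ordinary least squares alongside the Theil–Sen estimator, which
    is robust to the skew and heteroskedasticity of short-lifespan sweeps.
    """
    if len(table) < 3:
        raise ValueError(f"need >= 3 rows to regress, got {len(table)}")
    x = table_energies(table, 0.0, "eol")
    y = table_energies(table, 0.0, "aol")
    if np.ptp(x) == 0:
        raise ValueError("singular fit: end-of-lifespan energy has zero variance")
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    ts = scipy.stats.theilslopes(y, x)
    return RegressionResult(
        slope=float(ols.params[1]),
        intercept=float(ols.params[0]),
        r_squared=float(ols.rsquared),
        p_value=float(ols.pvalues[1]),
        ts_slope=float(ts.slope),
        ts_intercept=float(ts.intercept),
        ts_slope_low=float(ts.low_slope),
        ts_slope_high=float(ts.high_slope),
    )
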