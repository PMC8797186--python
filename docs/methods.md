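# Methods

## Model

A digital organism is the state list `[S, ξ, αξ, i, j, λ, d, αd]`: a table
`S` of 10⁴ pre-sampled integer move lengths, position `(i, j)` on an
`n × n` torus, a lifespan budget of `λ` timesteps, and four monotone
counters — resources encountered `ξ`, its running time-sum `αξ = Σ_{τ≤t} ξ_τ`,
distance travelled `d`, and its running sum `αd`. Moves are drawn uniformly
with replacement from `S`; directions uniformly from the four axis headings
{0, π/2, π, 3π/2} (0 = +j, π/2 = −i, π = −j, 3π/2 = +i; by symmetry the
convention is immaterial). `S` is sampled by inverse-CDF from the truncated
discrete power law `P(l) ∝ l^(−u)` on `[1, n/2]`; `n/2` is the largest
axis-aligned displacement on the torus. The exponent `u` may be any real:
`u = 0` is uniform, negative `u` weights long moves — evolution is allowed
to go there.

The walk is *truncated*: the organism advances one cell at a time, and a
move ends early the moment it arrives on a cell with resources, collecting
the cell's full count. Resources are revisitable — never consumed — so a
landscape can be shared read-only between organisms without interaction.
A move of length `l` at speed `s` takes `⌈l/s⌉` timesteps: each timestep
covers at most `s` cells of a single move, and a timestep cut short by
truncation (or by the move ending) still costs one whole timestep, with
`δ_t` recording the cells actually covered. At the close of each timestep
`αξ += ξ` and `αd += d`. All counters are integers.

### Energies and post-hoc cost

Energy follows `ε_{t+1} = ε_t + e_t − χ δ_t` from `ε_0 = 0`. Because this
recursion is linear, both summaries are exact functions of terminal
counters:

    ε_EOL = ξ_λ − χ d_λ,    ε_AOL = (αξ_λ − χ αd_λ)/λ,

so cost is applied in post-processing, once, never per timestep. The
package keeps a definitional per-timestep accumulator
(`stepwise_energy_oracle`) and the test suite asserts exact agreement on
1000+ randomized traces across speeds 1, 2, 8 and costs 0, 1/9000, 1/8000,
using `fractions.Fraction` costs so "exact" means integer-arithmetic exact.
Death is `ε ≤ 0` under the metric in use, evaluated post hoc. The energy
functions are numeric-type generic (floats in production, rationals in
proofs-by-test).

Idealized encounter schedules have closed forms used as oracles: with one
unit resource every `k` of `n` steps, `ε_EOL = n/k` and
`ε_AOL = (n+2)/(2k) − 1/2` (ratio → 1/2 for `n ≫ k`; 0.495 at `n = 10⁶,
k = 10⁴`). If all `n/k` encounters come consecutively at the start or end
of life, `ε_AOL = (2n − n/k + 1)/(2k)` or `(n/k + 1)/(2k)` respectively;
both were derived from (and are tested against) the brute-force timestep
sum, and bracket any schedule's AOL:EOL ratio. The start-clustered form is
stated here from that derivation because published renderings of it are
easily garbled; the brute-force sum is the definition.

### Environments

Landscapes hold `⌊n²·10⁻⁴⌋` deposits by default (configurable; the sparse
regime in which a search exponent near 2 is classically optimal).
*Uniform-random*: deposits are i.i.d. uniform cells with replacement, so
cells can hold counts > 1. *Lévy dust*: deposits are successive endpoints
of a lattice Lévy flight whose lengths follow the same truncated power law
with dust exponent `u` (fractal dimension `u − 1`); larger `u` gives
clumpier fields. The generating walk deposits at jump endpoints only, the
start cell receiving the first deposit — the standard dust point-set
construction; depositing along traversed paths would be a different (and
denser) object. Dispersion of quadrat counts, deposit conservation, and a
chi-square check of the generator's jump lengths against the exact pmf are
tested.

### Single-generation analyses

A sweep releases a population (default 5·10⁴, desk scale smaller) with
`u ~ U[0, 6]` into a landscape and records all counters for post-processing.
The default sweep shares one read-only landscape (equivalent to
per-organism copies, since nothing is consumed). Sliding-window statistics
move a window of width 0.25 exponent-units in steps of 0.01 (the window
geometry is this package's choice, fine enough to resolve a peak near
`u = 2` at a few thousand organisms): windowed first moment, positive-only
first moment (survivors only), and SD, with `u_MAX` the center of the
maximizing window (ties → lowest center). Top-percentile subsampling draws
1000 sub-populations per size (without replacement within a replicate),
drops the dead before ranking, keeps `⌈0.01·size⌉ ≥ 1` exponents, and
normalizes per-size frequencies to [0, 1]; all-dead replicates are skipped
and counted.

The `ε_AOL`~`ε_EOL` regression is reported under both OLS and Theil–Sen,
the latter because sweep energies are right-skewed and heteroskedastic;
single shared-landscape fits on clumpy dust make the OLS slope leverage-
sensitive while Theil–Sen stays at 0.5. For the regression study the sweep
uses one fresh uniform-random landscape per organism
(`SweepConfig(env_per_organism=True)`): the quantity of interest is the
relationship over the environment ensemble, not conditional on one
100-resource realization. At `λ = 1M` this yields slope ≈ 0.5 under both
estimators and R² ≈ 0.76–0.80, rising with lifespan as sampling noise in
each organism's energies shrinks.

### Evolution

Each generation: a fresh landscape is built; all `K` organisms (each
regenerating its own `S` from its exponent) live a full lifespan; cost is
applied post hoc; the dead are removed (if none survive the run ends,
extinct); survivors are put in a random order and stably sorted by
descending fitness; offspring are allocated by `ω_i = ⌈K f_i/Σf⌉`, greedily
capped so the running total never exceeds `K` (exact rational arithmetic,
so ceilings never suffer float round-off; a sum of ceilings always reaches
`K`). Offspring inherit `u_parent + N(0, σ_sv)`, unbounded; `σ_sv = 0` is
perfect heritability. Start positions are independent uniform cells every
generation. The pre-sort random permutation matters: with a deterministic
tie order, equal-fitness parents of one lineage would systematically
receive the larger shares, biasing neutral competition; with it, two
identical lineages each fix with probability 1/2 (verified over 300 seeded
assays). Competition assays start from two equal halves with fixed
exponents, force `σ_sv = 0`, carry a lineage label through reproduction,
and stop at fixation, extinction, or generation `G`.

## Randomness and determinism

High-level sampling uses `numpy.random.Generator`. The inner walk kernel is
compiled with numba and uses an explicit xorshift64* stream seeded per
organism from the caller's generator; a pure-Python reference walker
replays the identical stream, and the suite asserts cell-for-cell equality
of counters and per-timestep logs between the two on randomized instances.
Everything downstream of a fixed (config, seed) pair is reproducible to the
byte in CSV output.

## Scale of the shipped checks

The headline quantities are recomputed at desk scale on one CPU: 64
Brownian walkers and a 2400-organism regression sweep at `λ = 1M`, a
2000-organism `u_MAX` sweep at `λ = 1M`, 300 neutral-competition assays at
`K = 20, λ = 3000`, and 15 miniature dust-evolution runs (`K = 80,
λ = 10⁵, G = 25`). The regression population of 2400 was chosen so the R²
estimate sits near its ensemble value (its sampling SD at this size is
~0.007). The full-scale study conditions (5·10⁴ organisms, lifespans to
10⁷, 40-run ensembles, `K = 1500` over 100 generations) are expressible in
the same configs but need cluster time; at miniature scale only the
*direction* of the clumpiness effects is checked — evolved exponents
correlate negatively with dust dimension, and final Lévy-zone mass is
higher on `u = 3` dust than `u = 1` dust. For that check the founders start
at `μ = 5.0`: from Brownian founders the dim-dependent pull toward `u ≈ 2`
appears within few generations, whereas from `μ = 1.0` short runs confound
upward drift with selection and can transiently reverse the sign that
longer runs recover. Miniature environments raise resource density above
`10⁻⁴` (cost and selection effects scale ~1:1 with density), since a
128-cell torus at the default density would hold one resource.

## What the synthetic conditions do not capture

Movement is axis-aligned on a lattice with no diagonal or continuous
headings, no memory, sensing, interference, or depletion; cost is a
constant per cell with no speed-dependent drag; reproduction is asexual
with Gaussian mutation of a single trait. Passing tests show the model's
internal claims (exact energetics, allocation arithmetic, neutrality,
directional selection) and scaled statistical signatures — not that real
foragers meet the model's assumptions.
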