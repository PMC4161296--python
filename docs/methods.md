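# Methods

## Model

The unit of analysis is an evolutionary random walk in the space of all
`A**L` sequences of length `L` over an `A`-letter alphabet (default `ACGT`).
The population is monomorphic (sequential-fixation regime: mutation rate low
enough that each mutant is resolved before the next appears).  One
elementary event is one *proposed* point mutation: a uniform choice among
the `L*(A-1)` Hamming-one neighbors.  Under selection the proposal fixes
with probability `min(1, N*rho)`, where `rho` is the Moran fixation
probability of the mutant/resident fitness ratio in a population of size
`N`; the factor `N` normalizes the neutral case to acceptance 1, and the cap
keeps it a probability for strongly beneficial mutants.  All times reported
by the package are counts of these proposal events.  Conversions: expected
substitutions = events x acceptance probability; generations ~ events/(N*u)
for per-genome mutation rate `u` (the package never needs `u` internally).

**Discovery** is the first *proposal* of a target sequence, not its
fixation.  For neutral or advantageous targets the two coincide (the cap
makes the entry step's acceptance 1); for deleterious targets the package's
hitting analysis would undercount slightly — deleterious targets are outside
the intended scope.

## Target geometry and projection

A broad peak is the Hamming ball of radius `w = floor(c*L)` around a center;
its size `sum_{i<=w} C(L,i)(A-1)**i` is computed in exact integer
arithmetic (`A**L` overflows 64-bit types from `L ~ 31`).  Because a
broad-peak landscape is invariant under permuting positions and relabeling
characters away from the center, the walk projects *exactly* onto the
distance from the center: a birth–death chain with
`p_down(k) = k/(L(A-1))`, `p_up(k) = (L-k)/L`, `p_stay(k) = k(A-2)/(L(A-1))`.
The projection is verified empirically (full-space vs projected walkers,
mean within 3 SE and two-sample KS at the 1% level, L=8).

The neutral stationary distribution over shells is proportional to
`C(L,k)(A-1)**k`, whose mode — the drift equilibrium — sits at
`k* ~ L(1-1/A)` (exactly the integer argmax in the package).  Everything
about the polynomial/exponential dichotomy follows from whether the target
boundary `w` lies inside or outside `k*`.

## Hitting times: two routes, and a numerical warning

`hitting_linear_solve` eliminates the tridiagonal system
`H(k) = 1 + p_down H(k-1) + p_stay H(k) + p_up H(k+1)`, `H(<=w) = 0`.
The elimination is done in exact rational arithmetic by default: floats are
binary rationals, so lifting the rows through `Fraction` commits no
rounding.  This is not pedantry — the float (LAPACK) solve, exposed as
`method="float"`, is *wrong by O(1) factors* once `H` approaches `1/eps ~
1e16`, because the solution is exquisitely sensitive to the float-level
mismatch between `1 - p_stay` and `p_down + p_up` (a row-sum deficit acts
like a killing rate that caps `H`).  Both paths therefore write the diagonal
as `p_down + p_up`; even so the float path degrades at extreme magnitudes
and the exact path is the oracle.

`hitting_forward_sum` evaluates the closed form: increments
`t(L) = 1/p_down(L)`, `t(k) = (1 + p_up(k) t(k+1))/p_down(k)`, and
`H(k) = sum_{j=w+1..k} t(j)`.  It runs in log space
(`log t(k) = logaddexp(0, log p_up + log t(k+1)) - log p_down`, prefix
log-sum-exp for `H`), so `log H` stays finite long after `H` exceeds 1e308.
The two routes agree to relative ~2e-13 across `A in {2,4}`, `L <= 200`,
all width regimes; the identity `t(k) p_down(k) - p_up(k) t(k+1) = 1` is the
log-space self-check.

The increments carry the dichotomy: where the chain drifts outward
(`p_up > p_down`, i.e. `k < k*`) successive `t` grow geometrically toward
the boundary, so a target with `w < k*` costs `exp(Theta(L))` events; where
it drifts inward they grow at most arithmetically, so a target covering `k*`
costs polynomial time.

## Classifier

`classify_time_scale(chain, delta)` reads the verdict off the drift profile:
*exponential* if a contiguous stretch of at least `delta*L` states beyond
the boundary has `p_up/p_down >= 1+delta`; *polynomial* if every state
beyond the boundary has `p_down >= p_up`; *critical* otherwise.  Verdicts
are invariant under uniform time rescaling.  `delta` is a resolution
parameter, not a tuning constant: the default 0.1 suits coarse scans, while
`delta = 0.02` resolves the flip to within one shell of `round(3L/4)` for
`L` up to ~100.  The flip cannot be sharper than one shell: the shell at
exactly `3L/4` carries zero drift and belongs to neither regime, and for
`delta*L > 1` a single additional shell can read as critical.  The
drift-balance formulation (rather than a hard-coded 3/4) means
selection-modified thresholds emerge from the same test when the chain is
built with a fitness gradient.

## Growth scans

`growth_scan` computes `log H` at a start shell across an `L`-grid with
`w = floor(c*L)` and fits both `log H ~ a + b*L` and `log H ~ a' + b'*log L`;
the verdict is the model with smaller squared residuals, and the log-linear
fit supports extrapolation to gene-scale `L` (compute small, extrapolate the
exponential).  Two deliberate choices:

* **Start shell.**  Default is the drift equilibrium `k*` — the typical
  distance of a random starting sequence — except when the target already
  covers `k*` (`c > 1 - 1/A`), where the farthest shell `L` is used (the
  equilibrium start would sit inside the target and make `H = 0`).
* **Commensurate grids.**  Use `L`-grids with `c*L` integral (for
  `c = 0.55` or `0.85`: multiples of 20).  On incommensurate grids the
  floor makes the effective width fraction wobble (e.g. `16/30 = 0.533` vs
  `11/20 = 0.55`), which alone caps the fit `R^2` near 0.987 and is a
  discretization artifact, not a property of the growth law.

## Monte-Carlo design

All randomness descends from one master seed through numpy `SeedSequence`
spawning; identical configurations reproduce results bit for bit.  The
projected-chain and full-space batch walkers are vectorized over replicates
with active-set retirement; the full-space walker keeps incremental
distances to all `m` centers (O(m) per event) instead of recomputing
Hamming distances.  Censoring at the step budget is reported explicitly
(success probability, censored fraction), and summary means are over hits
only.

The walkers simulate exactly the stated model — no approximations — so a
green distributional test establishes agreement between two exact samplers,
not realism of the model itself: real populations are polymorphic, can
recombine, and have structured mutation spectra, none of which is modeled.

## Experiments

* **Parallel searches**: ensemble success `1-(1-p)**t` evaluated via
  `log1p/expm1` (stable for `p ~ 1e-12`, `t ~ 1e6`); the empirical ensemble
  frequency is compared against the exact finite-horizon DP value.
* **Regeneration** is modeled as independent budgeted restarts from a
  uniform random sequence at distance exactly `k0` from the center (width
  `w = 0` default, the hardest case), making the success count binomial and
  directly testable; walks run on the projected chain (distributionally
  identical, and tested so).  The per-attempt success decomposes as a
  direct-descent term `~ L**-k0` plus a background term `~ T/H(k0)` from
  attempts that drift to equilibrium and wander back.  At `L = 8` with
  `T = 20 L**2` the background dominates (the budget is a visible fraction
  of the whole-space hitting time `4**8`), so power-law fits that include
  such small `L` read steeper than `-k0`; pairwise slopes are `-5.8 (8->12)`,
  `-2.6 (12->16)`, `-2.3 (16->20)`, `-2.2 (20->24)`, converging to `-2`
  once the background is negligible.
* **Multi-peak**: `m` centers drawn uniformly; starts drawn uniformly
  outside the target by rejection (refused when targets cover more than half
  the space — outside the theory's regime).  The stationary-mass estimate
  `A**L/(m * ball_volume)` is an epoch count justified by fast mixing; the
  `O(L log L)` mixing factor is reported as an annotation, never folded in.

## Rugged-landscape approximations

The built-in rugged generator is a Rough-Mount-Fuji field
`f(s) = base - theta*d(s, anchor) + Normal(0, sd**2)`, enumerable spaces
only (`A**L <= 1e6`).  "Mountain range" is operationalized as the basin of
greedy steepest ascent with deterministic tie-breaking (position-major,
alphabet-minor neighbor order); local maxima are strict, so plateaus are
traversed only via the tie-break order — irrelevant for noise-perturbed
landscapes where ties have probability zero.  The threshold operator marks
`{f >= f*}` as targets over a neutral background; the plateau operator marks
whole basins whose peak clears `f*` and flattens the complement at the
highest sub-threshold peak fitness `f_max`.  The threshold target set is
always contained in the plateau target set.  An alternative reading of
"mountain range" (connected components of a level set) is not implemented.

## Known limitations

* No polymorphism, clonal interference, recombination, indels, or codon
  structure; the walk is the sequential-fixation caricature.
* Deleterious-target discovery times are approximated by proposal-hitting
  (see above).
* The float tridiagonal path is retained for speed but is untrustworthy for
  `H > ~1e12`; use the default exact path or the log-space forward sum.
* Small-`L` regeneration scans mix the background term into the power law;
  scaling conclusions should come from grids where `T << H(k0)`.
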