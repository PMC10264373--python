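# Methods

## Model

A metabolic network is a stoichiometric matrix `S` (internal metabolites ×
reactions) with per-reaction reversibility flags. All analysis happens in
the all-irreversible representation: each reversible reaction `r` becomes
`r_fwd` (same column) and `r_bwd` (negated column, placed immediately
after), and blocked reactions — reactions with zero flux in every
steady-state mode — are deleted. A *mode* is any `v` with `S·v = 0`,
`v ≥ 0`; an *elementary flux mode* (EFM) is a mode with minimal support.
The algebraic test used everywhere is the rank characterisation: `v` is
elementary iff the submatrix of `S` on its support columns has rank
`|supp(v)| − 1`. Because the kernel on an elementary support is
one-dimensional, the support is a sound identity key; fluxes are stored on
a canonical scale (maximum component = 1) for reporting only.

Splitting creates one artifact per reversible reaction: the futile
two-cycle `{r_fwd, r_bwd}` passes the rank test but carries no net
conversion. Collections drop these by default; `keep_futile_pairs=True`
retains them for diagnostics, and the exact enumerators accept
`include_futile` so both conventions can be compared. EFMs are reported in
the split space; recombining to signed reversible fluxes is out of scope.

## Preprocessing choices

* Blocked detection is FVA-style: maximise each `v[r]` under `S·v = 0`,
  `0 ≤ v ≤ 1` (the unit box merely bounds the cone; any positive bound is
  equivalent) via scipy's HiGHS; blocked iff the optimum ≤ 1e-9.
* Boundary species in SBML/JSON models are dropped from the rows; exchange
  reactions stay as columns. Reversibility is read from the lower flux
  bound (`lb < 0`). The biomass reaction is found by a case-insensitive
  `"biomass"` substring, always overridable, since real models name it
  explicitly.

## The extractor

**Seeding.** One LP per reaction in network order (positive constraint
`v[r] = 1`, objective coefficients drawn uniformly from [0.1, 1.0] — the
lower bound keeps objectives well-conditioned while remaining "random
positive"), then `n_seed_lps` LPs anchored on the biomass reaction with
fresh random objectives. Every optimal vertex of such an LP is an EFM;
occurrence counts are updated on every solve, including re-discoveries.
When no biomass reaction is configured, the anchored LPs fall back to
uniformly random singleton seeds (a documented deviation switch). Coverage
EFMs enter the occurrence accounting exactly like anchored ones.

**Expansion.** Loop: take the unexplored EFM with the lowest occurrence
count (ties to the earliest discovered), mark it explored, solve the LP
whose unique optimum is that EFM (minimise flux outside the support,
positive constraint over the originally-irreversible support reactions
`I`; its optimum is 0), then pivot the final tableau: for each nonbasic
column, the minimum-ratio test gives the feasible adjacent basic solutions,
each a vertex of the sliced cone and hence an EFM. Candidates are verified
with the rank test before storage (failures are logged and discarded —
a numerical guard that has not fired in the test suite). Stop on
`max_efms`, `max_time`, or queue exhaustion; exhaustion is treated as a
stop criterion in its own right, and completeness on exhaustion is an
empirical observation (verified against the oracle on every fixture), not
a theorem. EFMs whose support contains no originally-irreversible reaction
cannot anchor an exploration LP (`I = ∅`); they are skipped and logged.

**Simplex.** A dense two-phase tableau simplex with Bland's rule (zero
tolerance 1e-9, feasibility tolerance 1e-7) lives in the package because
pivot enumeration needs the final tableau, which library solvers do not
expose portably; scipy/HiGHS is used as an independent optimum oracle in
the tests, never as the implementation. Equality constraints get phase-1
artificial variables that never re-enter; rows whose artificial cannot be
driven out are redundant and are dropped, so the final tableau always has
a structural basis. Degeneracy gets explicit treatment: at a degenerate
vertex, different bases expose different edges, so a pivot enumeration
from the single basis the simplex happens to hold silently misses
neighbours (observed on fixture networks, where every exploration optimum
is degenerate). `pivot_neighbors` therefore traverses zero-ratio pivots —
basis changes that stay on the same vertex — and collects neighbours from
every basis of the vertex (capped at 500 bases), returning the adjacency
of the vertex rather than of one arbitrary basis; output is deduplicated
by support and the current vertex is never returned as its own neighbour.
The single-basis behaviour remains available
(`explore_degenerate=False`). Everything is deterministic given
the problem and the tie-breaking rule; identical seeds give byte-identical
outputs.

## Exact oracles

Two independent enumerators provide ground truth. The double description
method starts from the unit rays of the non-negative orthant and
intersects one steady-state hyperplane at a time, combining positive and
negative rays pairwise and keeping the support-minimal results; it runs in
exact `Fraction` arithmetic (fixture stoichiometries are small integers,
so this is cheap and removes all tolerance questions), processes rows in
the order minimising the number of pair combinations, and enforces a
configurable intermediate-ray cap. The brute-force enumerator sweeps
candidate supports directly (guard: ≤ 22 reactions unless `max_support`
bounds the sweep) and applies the rank test plus a strictly-positive
kernel check (tolerance 1e-9 relative); by the rank characterisation the
qualifying supports are exactly the EFM supports, so no minimality
post-filter is needed. The two methods share no code and agree, as
support sets, on every fixture.

## Metrics

* `p(r)`: fraction of EFMs whose support contains `r`; exact counting.
* `mre(p_est, p_ref)`: mean over the universe of `|Δp|/p_ref`, absolute
  values always; reactions with `p_ref(r) = 0` must be excluded from the
  universe (the stability trace drops them per checkpoint and the CLI
  restricts the universe automatically).
* Stability at checkpoint `k` compares cumulative prefixes: `p` over the
  first `k` EFMs against `p` over the first `k − d`; defined for
  `k ≥ 2d` so the reference prefix is never shorter than the offset.
  Default offsets: `d = 2000` (small models), `d = 10000` (genome scale);
  checkpoint grid every 500 EFMs by default.
* Stopping rule: the first checkpoint opening a run of `consecutive`
  (default 3) stability values strictly below the threshold (default
  0.05). A single dip below the line does not qualify.
* Partial-coupling correction: reactions with identical membership
  patterns across a *complete* enumeration form coupling classes; the
  default correction drops every member of non-singleton classes
  (`mode="drop"`), with `mode="representative"` keeping one per class as
  an alternative, since either reading is defensible.
* The k-shortest/k-largest simulator is a stable sort by support length;
  ties keep enumeration order, and any statistic of the prefix that
  depends only on lengths is tie-invariant.
* The compatible-reaction count (union of supports of EFMs containing an
  anchor, normally biomass) measures the variability of an extracted set;
  a Pearson-correlation variant of the proportion comparison is provided
  as an optional extra but the mean relative error is the primary
  statistic, being the more sensitive of the two.

## Synthetic fixtures

Builders are pure functions of their parameters: chains (one EFM), fans
(`b` EFMs of length 2), the diamond (two length-4 EFMs, the minimal
network with a branch choice and with partially coupled reaction pairs),
a reversible chain (exercising splitting and the futile-pair filter), a
dead-end pair (exercising blocked removal), and random sparse networks
with integer coefficients in {−2, −1, 1, 2}, guaranteed import/export
columns, blocked reactions removed, and reject-and-resample until an EFM
exists. These fixtures emulate mass balance, branching, reversibility and
dead ends at desk scale; they do not emulate genome-scale features —
thousands of reactions, cofactor coupling, compartments, or realistic
degree distributions — so passing tests certify algorithmic correctness
and determinism, not performance or biological fidelity on real models.
Default problem sizes (networks of ≤ 15 reactions, 25 random seeds,
1,000-LP contract checks, 2,000-step metric streams) keep the whole suite
and the acceptance script in the minutes range on one CPU.

## Known limitations

* The dense tableau targets networks up to a few thousand reactions; a
  sparse revised simplex would be an optimisation, not a behaviour change.
* The double description implementation favours exactness and simplicity
  over scale; full enumeration of models the size of core *E. coli*
  (~100k EFMs) is supported in principle but slow in pure Python, and the
  corresponding model-scale tests require the BIGG model files locally.
* Queue exhaustion finding the complete EFM set is empirical; no
  completeness theorem is claimed for the pivot walk.
* k-shortest extraction is only simulated by sorting a complete
  enumeration; no MILP machinery is included.
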