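# piefm

Elementary flux mode extraction by LP seeding and simplex pivoting, with a
metric suite for judging how representative an extracted EFM subset is.

## The problem

An elementary flux mode (EFM) of a metabolic network is a steady-state,
thermodynamically feasible flux vector `v` (`S·v = 0`, `v ≥ 0` once every
reversible reaction is split into a forward/backward pair) whose support —
the set of reactions carrying flux — is minimal. EFMs are the extreme rays
of the flux cone `C = {v : S·v = 0, v ≥ 0}` and the canonical "pathway"
decomposition of a network, but their number explodes with network size:
genome-scale models have far too many to enumerate. Practical methods
therefore extract a *subset* of EFMs, which raises two questions this
package addresses:

1. **How do you extract EFMs cheaply without a strong bias?**
   The extractor here poses linear programs over the flux cone. Any LP of
   the form *minimise a·v subject to S·v = 0, Σ_{T₁} v = 1, v ≥ 0* with
   `a ≥ 0` and a non-empty positive seed `T₁` has an optimal vertex that is
   an EFM. A *seeding* phase covers every reaction once (positive
   constraint `v[r] = 1`, random positive objective) and then poses `n`
   biomass-anchored LPs with fresh random objectives. An *expansion* phase
   then walks the vertex graph of the cone: it repeatedly takes the
   least-recomputed unexplored EFM `E'`, builds the LP whose unique optimum
   (value 0) is `E'` — minimise the total flux outside `supp(E')` subject to
   `Σ_I v = 1` over the originally-irreversible support reactions `I` — and
   performs extra pivots on the final simplex tableau: for each pair
   (basic j₁, nonbasic j₂) a feasible pivot lands on an adjacent vertex of
   the cone, i.e. another EFM. Occurrence counts steer the queue toward
   under-sampled regions.

2. **When can you trust (or stop) an extraction?**
   For a parameter λ — the mean support length, or the per-reaction
   proportion `p(r) = |{E' ∈ E : r ∈ supp(E')}| / |E|` — a subset is
   *representative* if λ on the subset is close to λ on the full set, and
   an extraction stream is *stable* if λ agrees between prefixes of
   different sizes. Stability is measurable without the full set and is
   necessary (not sufficient) for representativeness. The suite provides
   the mean relative error `mre(p_k, p) = mean_r |p_k(r) − p(r)| / p(r)`
   over non-blocked reactions, the d-offset stability trace
   `mre(p_k, p_{k−d})` with a 0.05 stopping rule, a partial-coupling
   correction, compatible-reaction counts, Jaccard distances between
   consecutive EFMs, and a sort-based simulator of length-ordered
   (k-shortest / k-largest) extraction.

For validation at small scale the package also ships two independent exact
enumerators — a double description method in exact rational arithmetic and
a brute-force sweep over candidate supports using the rank test
(`v` is elementary iff `rank(S_supp) = |supp| − 1`) — plus deterministic
synthetic fixture networks with known EFM sets.

## Worked example

```python
from piefm import PiefmConfig, random_baseline, run_piefm
from piefm import fixtures as fx
from piefm.oracle import enumerate_bruteforce

net = fx.make_random(n_met=4, n_rxn=10, density=0.4, rng_seed=50)
trace = run_piefm(net, PiefmConfig(n_seed_lps=0, rng_seed=0))
oracle = enumerate_bruteforce(net, include_futile=False)
print(len(trace.collection), trace.lp_count, trace.pivot_count)
print(trace.collection.supports() == oracle.supports())
```

prints (`examples/extract_pivoting.py` runs this with commentary):

```
extracted 22 EFMs with 34 LPs and 174 pivots
oracle count        : 22
complete            : True
efficiency          : 0.647 distinct EFMs per LP
random baseline     : 0.412 (14 distinct EFMs from the same LP budget)
```

The extractor found the network's complete EFM set (22 of 22, certified by
the independent oracle) at 0.647 distinct EFMs per LP solved; a purely
random LP method with the same budget found only 14. The other scripts in
`examples/` demonstrate exact enumeration, the representativeness metrics
on a length-biased subset, and the stability stopping rule.

A thin CLI wraps the same library calls:

```sh
piefm fixtures --name diamond --out net.tsv
piefm enumerate net.tsv --out full.tsv
piefm extract net.tsv --biomass r6 --seed 1 --out efms.tsv --trace t.jsonl
piefm stability efms.tsv --d 2000 --threshold 0.05 --out stab.csv
piefm compare a.tsv b.tsv --reference full.tsv --biomass r6 --out cmp.csv
```

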