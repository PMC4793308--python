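# Methods

This note documents the models implemented in `howlernet`, the conventions
and parameter defaults chosen where the design was genuinely open, and what
the synthetic-data generator does and does not emulate.

## Interaction matrices

A matrix is built per habitat from focal feeding records: one row per
individual, one column per plant species with at least one record, cell =
number of records (`count`), summed bout minutes (`minutes`), or 0/1
(`binary`). Censused individuals with no feeding record are retained as
all-zero rows (with a logged warning) rather than dropped, so the reported
number of monkeys matches the census; degree-0 rows participate in pairwise
metrics contributing zero. Species names are opaque strings matched exactly
after whitespace trimming. Tabular files are UTF-8 CSV with a header row;
`-` in the packaged reference tables denotes absence.

## NODF

For each ordered pair of rows (u, v) with fill(u) > fill(v) > 0 the pair
contributes `100 · |ones(v) ∩ ones(u)| / fill(v)`; pairs with equal fill or
an empty lighter row contribute 0 ("decreasing fill" is strict, ties are
never broken by ordering). The same is computed over column pairs, and NODF
is the sum divided by `R(R−1)/2 + C(C−1)/2`, giving a value in [0, 100].
The implementation is a vectorized overlap-matrix computation; tests hold it
to a literal double-loop oracle at 1e−9 and to the `vegan::nestednodf`
reference on a sample matrix. NODF is invariant under row and column
permutations; the binary (qualitative) matrix is always used.

## Null model and significance

The probabilistic null assigns every cell probability
`p_ij = (k_i/C + k_j/R)/2`, the mean of the row's and column's fill
proportions, so Σ p_ij equals the observed link count and expected marginal
degrees are preserved (exact degrees are not; degenerate sampled rows or
columns are kept and simply contribute zero to NODF). The Monte-Carlo test
draws `n = 1000` matrices by default and reports a one-tailed p-value
`count(null ≥ observed)/n`; the conservative `(count+1)/(n+1)` variant is
available by flag. Each sample consumes its own spawned substream of the
seed, so enlarging `n` extends the null sample without reshuffling earlier
draws and a fixed seed reproduces the result bit for bit.

Two calibration facts matter for interpretation. (1) If the observation
really is a draw from a *known* probability matrix and that matrix is
supplied to the test (`probabilities=`), the p-value is exactly
rank-uniform; this is the design used in the calibration suite. (2) In
routine use the probabilities are re-estimated from the observed matrix's
own degrees. Because the null smooths each row degree halfway toward the
mean degree, this variant is only approximately calibrated: it runs
anti-conservative for strongly heterogeneous degree sequences and
conservative for near-regular ones. This is a property of the null model
itself, not of the Monte-Carlo machinery.

## H2′ specialization

`H2` is the Shannon entropy of the cell-weight distribution. The index
`H2′ = (H2max − H2)/(H2max − H2min)` standardizes it by the entropy extremes
achievable by *any* nonnegative matrix with the same marginal totals:

- **Exact bounds** (≤ 16 cells and total weight ≤ 12, integer marginals):
  depth-first enumeration of the whole transportation polytope.
- **Heuristic bounds** otherwise: `H2min` from greedy packing (repeatedly
  place `min(remaining row, remaining col)` at the largest remaining
  marginals); `H2max` from the independence expectation `r_i c_j / m`,
  adjusted to an integer-compatible allocation by flooring and distributing
  the remaining units to feasible cells with the largest remainders.

When the bounds coincide (e.g. all unit marginals) the index is undefined
and 0 is returned. With the integer adjustment the index drifts slightly
(≲ 0.1 in tests) under rescaling of all weights; `integer=False` uses the
continuous expectation and is exactly scale-free.

A binary matrix sits at (or next to) its marginal-compatible entropy
maximum, so binary H2′ degenerates to ≈ 0. The attribute bundle therefore
computes H2′ on the weighted matrix by default while interaction diversity
defaults to binary links (where it equals ln L); both choices can be
overridden.

## Core–periphery

The categorical model labels every row and column core or periphery. Fit
quality is the Pearson correlation between cell values and the ideal
pattern — core×core cells compared against 1, periphery×periphery against
0, mixed blocks excluded from the correlation ("ignore" treatment). The
correlation is computed from block sums, and is undefined (NaN) when either
compared vector has zero variance.

Memberships are fitted by simulated annealing over the joint label vector:
single-label flips, geometric cooling from T = 0.25 to 0.002, roughly
200·(R+C) proposals split over 4 random restarts. Two degeneracies are
resolved deterministically: the label-swap symmetry (complement labels give
the negated correlation) by reporting the orientation in which core nodes
have the higher mean degree — core species are the generalists — and the
ignore-treatment tie (dropping a core node of a perfect block moves its
cells into an ignored block without changing the correlation) by preferring
the larger core block among equal-fitness labelings.

The occurrence table repeats the fit (default 20 runs) and reports, per
node, the percentage of runs classified core and periphery; degenerate runs
abstain, so the two percentages may sum below 100. Note that under
cell-flip noise the *optimal* labelling genuinely excludes core nodes that
lost links — recovery of a planted core is only a meaningful expectation
when the planted labelling remains the optimum, which the test suite
verifies by exhaustive enumeration before asserting recovery. On matrices
without block structure the occurrence percentages are unstable across
nodes; they describe, rather than test, structure.

## Community statistics

- **IVI**: per species, the mean of relative density (stem share), relative
  frequency (share of transect occurrences), and relative dominance (share
  of basal area, `π(dbh/2)²` per stem), each on a 0–1 scale, so IVI sums to
  1 over species within a habitat. Only stems with dbh ≥ 10 cm enter.
- **Jaccard**: `|A∩B| / |A∪B|`; undefined for two empty sets.
- **Mantel**: Pearson correlation of the upper off-diagonal triangles;
  significance from joint row/column permutations of the second matrix,
  two-tailed on |r|, identity permutation included in the count, 999
  permutations by default.
- **Transformed t-tests**: pooled-variance two-sample t with
  df = n₁ + n₂ − 2 after log(x+1) (counts, richness) or arcsin√p
  (proportions, radians).
- **Nested ANOVA**: item nested within habitat on angular-transformed
  fractions. Sums of squares decompose into habitat, item-within-habitat,
  and residual; df follow the standard Σ(levels−1) rule and *both* F ratios
  use the residual mean square (fixed-effects convention). Per-individual
  item-time fractions serve as replicates in the pipeline.

## Synthetic data generator

The generator reproduces the statistical structure the analysis assumes,
not the biology of any particular forest. Study conditions are fixed by the
`paper_like` preset:

- **Census**: 15 continuous-forest individuals (6 adult F, 4 adult M, 1
  juvenile F, 1 juvenile M, 2 infant F, 1 infant M) and 18 fragment
  individuals (5/4/4/3/1/1), each assigned to one of 3 sites per habitat.
- **Floras**: taken from the packaged per-species item table — 27 species
  in continuous forest, 30 in fragments, 37 distinct, 20 shared — along
  with each species' consumable items per habitat.
- **Diet breadth**: mean fraction of the habitat pool per class —
  adult F 0.52, adult M 0.42, juvenile F 0.32, juvenile M 0.28, infant F
  0.18, infant M 0.14 — with lognormal spread 0.15. These means are free
  parameters chosen once to reproduce the qualitative ordering (adults
  broadest, females above males within age, adult females the extreme
  generalists) and a realized connectance near 0.4; no printed per-class
  quantity constrains them.
- **Nestedness knob ν**: each partner pick is, with probability ν, the
  currently most popular plant (highest partner degree, ties random) among
  those already used by strictly broader classes, else a uniform random
  plant. The rank-based rule was chosen over degree-proportional sampling
  because the latter produces too weak a decreasing-fill signal for the
  power properties the generator must satisfy. At ν = 1 a narrow class
  cannot leave the broader classes' plant union (the diet is truncated
  instead), so infant ⊆ adult diets hold exactly by construction; at ν = 0
  diets are uniform and the nestedness test fires near its nominal rate.
- **Records and durations**: per link, 1 + Poisson(mean−1) records
  (default mean 3); bout durations Gamma(shape 2) with mean 3 min scaled by
  per-(habitat, age) factors emulating the observed foraging-time contrasts
  (adults/juveniles forage longer in fragments, infants barely); the item
  of each record is drawn from the species' item set weighted by
  habitat-level feeding-time item proportions.
- **Transects**: 10 transects × 3 sites per habitat, Poisson(14) trees per
  transect, geometric rank-abundance (ratio 0.88) over the habitat flora,
  dbh = 10 + Gamma(1.5, 10) cm, sites 2 km apart.

Population, flora, diets, records, and transects consume independent
substreams of the master seed, so changing ν regenerates diets and records
only. Not emulated: seasonality and phenology, within-site movement,
demographic change, observation effort imbalance, misidentification, or
any nutritional mechanism. Passing tests therefore show that the *methods*
behave correctly on data with known structure — not that real howler data
satisfy the generator's assumptions.

## Numerical conventions and problem sizes

Reported tables round half-even to 2 decimals; full precision is kept
internally. One attribute-table identity is borderline: 196 links on an
18×30 network give ln 196 = 5.278, which rounds to 5.28 but truncates to
the printed-style 5.27 — rounding is used and the discrepancy noted.
Shannon quantities are in nats throughout.

Test and acceptance problem sizes were chosen to estimate each property
with adequate precision: NODF oracle agreement on 200 random 6×6 matrices;
H2′ exhaustive agreement on all 2×2 (total ≤ 8) plus sampled up-to-4×4
matrices; null-model calibration over 500 replicates of a 15×27 base with
400 randomizations each; annealing-vs-enumeration on 100 5×5 instances;
Mantel calibration over 1,000 experiments with 99 permutations; detection
power over 100 (ν = 1) and 300 (ν = 0) study-scale replicates with 400
randomizations each. The ν = 0 rejection rate sits at 2–3%, slightly below
nominal, reflecting the approximate calibration of the re-estimating test
on near-regular degree sequences discussed above.

## Known limitations

- The re-estimating nestedness test inherits the null model's degree
  smoothing; its type-I error is only near-nominal (see above).
- Heuristic H2′ bounds above the exact-enumeration limits are not certified
  extremes; they match exhaustive search on every small case tested but can
  in principle be loose on pathological marginals.
- The core–periphery objective ignores mixed blocks, so nodes whose links
  fall mostly in mixed blocks are weakly determined and their occurrence
  percentages fluctuate across runs.
- The nested ANOVA treats items as fixed effects; with items regarded as
  random the habitat F ratio would use the item-within-habitat mean square
  instead.
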