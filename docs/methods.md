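# Methods

This note documents the model implemented by `epistasim`, the defaults it
ships with and why, the statistical structure of the synthetic network
generator, the numerical methods, and the known limitations. Nothing here
asserts an empirical result that is not computed by the test suite or by
`scripts/acceptance.py`.

## 1. Fitness model

### 1.1 Genotype fitness

A network is a set of loci with independent homozygous selection coefficients
`s_i ≥ −1`, dominance coefficients `h_i`, and a sparse symmetric map of
pairwise epistatic coefficients `ε_ij` (absent pairs have ε = 0). Genotype
fitness is multiplicative over loci and over unordered pairs of mutated loci:

```
W = ∏_{i∈Het} (1 + h_i s_i) · ∏_{i∈Hom} (1 + s_i)
  · ∏_{i<j both Het} (1 + α₁ ε_ij)
  · ∏_{i Het, j Hom}  (1 + α₂ ε_ij)
  · ∏_{i<j both Hom} (1 + ε_ij)
```

Each factor is clamped at zero before multiplying: a sufficiently deleterious
effect is lethal, never "negative-fitness". Pairs are counted exactly once.
`α₁` scales an interaction when both partners are heterozygous, `α₂` when
exactly one is — the *epistatic dominance* parameters. `α₁ = α₂ = 0` makes
epistasis fully recessive (expressed only between homozygous mutations);
`α₁ = α₂ = 1` makes it fully dominant.

### 1.2 Relative hybrid fitness

Two allopatric populations fix disjoint mutation sets A and B. The F1 hybrid
is heterozygous at every locus in A ∪ B, and its fitness is compared with the
*arithmetic* mean of the parental fitnesses:

```
w_H = W(Het = A ∪ B) / [ (W(Hom = A) + W(Hom = B)) / 2 ]
```

Three classes of pairs shape `w_H`: within-population pairs enter the parents
at full strength but the hybrid only at α₁; between-population pairs enter
only the hybrid (at α₁) — the Dobzhansky–Muller channel; and every
independent effect enters the hybrid at `h_i` instead of fully. With
`h = 1/2` the independent effects cancel against the parental mean to first
order, which is why epistasis dominates the behavior of `w_H`.

### 1.3 Effective selection in a background

A new mutation *i* in a population fixed for A has effective coefficients

```
σ_{i|A} = (1 + s_i) ∏_{j∈A} (1 + ε_ij) − 1
ω_{i|A} = [ (1 + h_i s_i) ∏_{j∈A} (1 + α₂ ε_ij) − 1 ] / σ_{i|A}
```

(each factor clamped at zero; at σ = 0 the dominance is defined by continuity
as `h_i`). σ is the homozygous advantage of the mutation over the resident
background; ω plays the role of its dominance in the diffusion approximation.

## 2. Closed-form trajectory

Writing ε̄w and ε̄b for the mean epistatic coefficient of within- and
between-population pairs, n for the total number of substitutions, and
v = F(1−F) for the symmetry of the split (F the fraction fixed in one
population), the expected log relative hybrid fitness under the small-ε
(first-order) expansion of the products is

```
log w_H(n) = ε̄b·α₁·v·n² − ε̄w·(1/2 − α₁)·[ (1/2 − v)·n² − n/2 ]
```

Properties the test suite verifies:

- the between term vanishes when α₁ = 0 (hybrid epistasis recessive) or
  v = 0 (one-sided divergence);
- at ε̄b = ε̄w, v = 1/4, α₁ = 1/4 the quadratic coefficients cancel and
  log w_H is exactly linear in n — no snowball;
- w_H rises with ε̄b and, past the first couple of substitutions, falls as
  ε̄w grows (the within term's n² part takes over from the +n/2 part);
- when ε̄w > max(ε̄b, 0), w_H starts above 1 and crosses back at
  `n* = 2 ε̄w / (ε̄w − ε̄b)` (v = 1/4, α₁ = 1/4); `heterosis_window` finds the
  crossing by bracketed root-finding on the trajectory rather than trusting a
  printed formula, and agrees with the closed-form root to 1e−9.

## 3. Fixation probability

Fixation probabilities come from Kimura's diffusion approximation for a new
mutation at initial frequency p = 1/(2N_e):

```
u = ∫₀^p G(x) dx / ∫₀^1 G(x) dx,
G(x) = exp{ −2Nσ x [ 2ω + (1 − 2ω) x ] }
```

Numerical treatment (implemented in `simulate.py`):

- the exponent is rewritten as `−(a x² + b x)` with
  `a = 2N(σ − 2σ_het)`, `b = 4N σ_het` (σ_het = ωσ the heterozygous
  coefficient), which removes the 0/0 ambiguity at ω = 1/2;
- the additive case (a = 0) uses the closed form
  `u = expm1(−σ)/expm1(−2Nσ)` evaluated with `expm1`, with a guard that
  returns 0 when the denominator overflows (strongly deleterious limit);
- the general case integrates in log space: the integrand is decomposed into
  monotone pieces (split at the interior extremum x* = −b/2a when it lies in
  (0,1)), each piece is rescaled by its peak value, and integrated on a fixed
  57-segment geometric Gauss–Legendre grid reaching down to 1e−14 so the
  near-zero region that dominates ∫₀^p is resolved;
- σ ≤ −1 (lethal in the resident background) returns 0 exactly; σ = 0
  returns p exactly.

The quadrature agrees with the additive closed form to better than 1e−6
(typically ~1e−15) across σ ∈ [−0.05, 0.05] and N_e ∈ {10³, 10⁶}, underflows
cleanly to 0 for strongly deleterious mutations, is monotone in σ, and
reproduces Haldane's sieve (u increasing in ω for beneficial mutations).

## 4. Divergence simulator

Evolution is modeled in the mutation-limited origin–fixation regime: one
substitution at a time, no standing polymorphism, no linkage. At each step
the focal population computes `(σ, ω)` for every locus not yet fixed in
either population, converts them to fixation probabilities, and samples the
next substitution with probability proportional to `u`. Populations A and B
alternate strictly by default (`alternation="random"` with a configurable
rate ratio is available). Fixed sets are disjoint by construction: a locus
substituted in one population is removed from the other's candidate pool,
keeping every between-population pair a genuinely untested combination.

A population whose candidate weights are all zero (every remaining mutation
lethal in its background) makes the replicate *stuck*; stuck replicates are
flagged and excluded from summary tables, never silently restarted.

Per-fixation cost is O(degree of the fixed locus): running products
∏(1+ε_ij) and ∏(1+α₂ε_ij) per candidate locus are updated only at the
neighbors of the newly fixed locus, and an incremental ledger maintains the
log parental and hybrid fitnesses and the within/between ε sums. Both
fast paths are tested against full recomputation and exhaustive enumeration.

Each replicate draws from `numpy.random.default_rng([seed, replicate_index])`,
so a run is reproducible bit-for-bit, independent of execution order, and
stable under growth of the replicate count.

The trajectory table records, after every substitution, the replicate index,
total n, per-population counts, `w_H`, and the running mean within- and
between-population ε among fixed pairs (absent pairs counted as 0).

## 5. Estimation from knockout screens

`load_interaction_table` reads tab-delimited double-knockout releases (query
and array single-mutant fitnesses plus double-mutant fitness; the default
column map follows the 2016 genome-scale SGA layout, gzip supported).
`filter_complete` keeps records with all three fitnesses present — no
p-value filtering, since discarding weak interactions would bias the ε
distribution toward large effects. `estimate_effects` supports three
measures:

- `multiplicative` (default, matches the fitness model):
  `ε = W_ij / (W_i W_j) − 1`; pairs with `W_i W_j = 0` are undefined, dropped,
  and counted in metadata (a locus with W = 0 has s = −1 and can never fix);
- `additive`: `ε = W_ij − W_i − W_j + 1`;
- `costanzo`: `ε = W_ij − W_i W_j` (the screen's own score; with
  `use_reported=True` the published score column is taken verbatim).

Duplicate single-mutant measurements are resolved by averaging (or
first-seen), pairs measured in both orientations are symmetrized by
averaging, and s, ε are clamped at −1. `effect_correlation` regresses each
locus's mean interaction against its s (statsmodels OLS) and reports slope,
intercept and adjusted R² — the fitness–interaction coupling.

## 6. Synthetic network generator

`SyntheticNetworkSpec` defaults (these are the package's study conditions;
they were fixed a priori and are not fitted to any particular dataset):

| parameter | default | rationale |
|---|---|---|
| `n_loci` | 1000 | large enough that 2×20–50 substitutions don't exhaust the pool's diversity, small enough for desk-scale replicate runs |
| `s_weights` | (0.05, 0.75, 0.20) | mixture weights: a small strongly deleterious class, a broad mildly deleterious majority, a minority of weakly beneficial mutations — the qualitative shape of genome-wide knockout fitness distributions |
| `s_means` | (−0.35, −0.03, 0.01) | class means for the three components |
| `s_sds` | (0.10, 0.02, 0.01) | class spreads |
| `pair_density` | 0.35 | fraction of locus pairs with a measurable interaction; interaction networks are sparse |
| `coupling` | 0.2 | `ε_ij ~ N(coupling·(s_i+s_j), noise)`: loci with stronger independent effects interact more strongly, the empirical fitness–interaction coupling |
| `epsilon_noise_sd` | 0.05 | interaction noise around the coupling trend |
| `h` (dominance) | 0.5 | additive independent effects unless overridden |

Draws are clipped at −1 and reproducible from the spec's seed.

What the generator emulates: the sign structure and coupling of a
genome-scale screen — mostly deleterious knockouts, sparse interactions
whose mean tracks the partners' independent effects. What it does not
emulate: the heavy tails and modular (complex/pathway) structure of real
interaction networks, hub genes, correlated ε across pairs sharing a locus
beyond the coupling term, measurement error, or any environment dependence.
One emergent consequence worth knowing: because the weakly beneficial class
is finite, long runs fix mildly deleterious, epistatically rescued mutations
whose mean s is negative, which makes the *between*-population ε mean
slightly negative — so the default synthetic condition produces hybrid
breakdown without an early heterosis phase. The closed-form module covers
the (ε̄w, ε̄b) combinations that do open a window.

## 7. Simulation defaults

| parameter | default | rationale |
|---|---|---|
| `effective_size` | 10⁶ | large-population, selection-dominated regime; drift still decides among near-neutral candidates |
| `fixations_per_population` | 50 | deep enough divergence to see the post-window decline |
| `alternation` | strict | symmetric divergence, v = 1/4, matching the closed form's symmetric case |
| `dominance` | h = 0.5, α₁ = 0.25, α₂ = 0.5 | independent effects additive; an interaction scales with the expected number of mutant-allele pairs across the two loci (1/4 of full when both heterozygous, 1/2 when one is) |
| `replicate_count` | 1 | summaries and acceptance runs set this explicitly |

## 8. Numerical and software choices

- Quadrature nodes from `numpy.polynomial.legendre.leggauss`; root refinement
  with `scipy.optimize.brentq` (xtol/rtol 1e−12); OLS via statsmodels;
  CLI via click; configs via PyYAML with strict unknown-key rejection and a
  provenance manifest (config snapshot, seed, package version, SHA-256 of
  inputs) written beside every CLI output.
- Tables round-trip exactly: written with `float_format="%.17g"`, read with
  `float_precision="round_trip"`.
- All fitness products clamp factors at zero; relative hybrid fitness raises
  on the degenerate both-parents-lethal case rather than returning NaN.

## 9. Limitations

- Origin–fixation: no standing variation, no clonal interference, no linkage
  or recombination within a population; valid when `N_e μ ≪ 1` per locus.
- Pairwise epistasis only; no three-way or higher interactions.
- The diffusion approximation is used outside its weak-selection comfort zone
  for strongly deleterious candidates, where it (correctly for this purpose)
  underflows to zero probability.
- Allopatry is absolute: no migration during divergence. Introgression
  summaries score only the *sign* of a foreign allele's effective selection
  in the other background — potential, not dynamics.
- The closed-form trajectory is a first-order expansion in ε; the simulator
  matches it to the stated O(ε²) pair-count bound on constant-ε networks and
  diverges from it, as it should, when ε is large or the ε distribution is
  wide.
- Hybrid fitness is evaluated for the F1 only; later generations
  (recombinant breakdown, F2 hybrid breakdown) are out of scope.
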