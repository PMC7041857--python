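# Methods

## Model

The design system is a fixed-backbone protein with a small set of
*mutable* positions (each with an allowed list of residue types) and
optional *flexible* positions (fixed type, variable rotamer). A
microstate assigns one (type, rotamer) combo to every position; its
energy is a sum of precomputed diagonal (side chain ↔ backbone) and
pairwise (side chain ↔ side chain) matrix terms in kcal/mol. One matrix
per thermodynamic state (apo, holo, alternate-ligand complex,
transition-state complex) over a shared sequence space. Pair entries
absent from a matrix file are exactly zero — distant side-chain pairs
have negligible interaction, and sparse storage keeps files small.
Computing matrix entries from structures/force fields is explicitly out
of scope; matrices are opaque inputs in a line-oriented text format (or
an equivalent JSON rendering) documented in `energy_model.py`.

The sequence free energy of a state X is
`G_X(S) = −kT ln Σ_rot exp(−E/kT)`, the log-sum over the rotamers of S.
All design quantities are *differences* of such free energies relative
to a reference sequence R, so every unknowable normalization constant
cancels.

## Sampling

Metropolis MC with symmetric proposals: with probability `1 − move_mix`
one position is drawn uniformly (mutable + flexible alike) and a new
(type, rotamer) combo drawn uniformly from its allowed set; otherwise
two distinct positions are reassigned independently. `move_mix` defaults
to 0.2 — both 1- and 2-position moves are standard for this protocol,
and the exact mix only affects mixing speed, not stationary
distributions. Sequence visits are recorded every `record_interval`
steps (default 10; the validation suites record every step since the
count arrays are cheap at toy scale). Chains are pure functions of
(matrix, bias, config, seed): all randomness is pre-drawn from a single
`numpy` generator per chain and consumed by a compiled (numba) kernel.

Replica exchange runs one chain per rung of a thermal-energy ladder
(default 0.17, 0.26, 0.39, 0.59, 0.88, 1.33, 2.0, 3.0 kcal/mol),
attempting adjacent-pair configuration swaps every `swap_interval` steps
(default 500) with alternating even/odd parity — the standard scheme
satisfying detailed balance. All replicas share the same bias.
Populations are read from one rung; 0.59 kcal/mol (≈ kT at 296 K) is the
physical default. Pooling across rungs is available
(`sampler.pool_populations`) but not the default, since the extraction
formulas require a single kT.

## Adaptive bias

The bias is defined over sequence types only — rotamer moves never
change it. Updates occur every `update_period = 1000` steps: each
single-position term addressed by the current sequence gains
`e0 · exp(−term/E0)` with `e0 = 0.2`, `E0 = 50` kcal/mol (well-tempered;
`E0 → ∞` recovers a constant, Wang-Landau-like increment). Increments
are computed from pre-update values, so single and (optional) pair terms
have no update-order dependence. Pair bias terms are implemented but off
by default — production use of the protocol relies on single-position
terms. Adaptation runs for a fixed, configurable step budget (no
automatic stopping rule); the flatness report (per-position type
marginals and least/most ratio) is the convergence diagnostic.

**Frozen-bias estimator.** The instantaneous bias fluctuates around the
flattening fixed point with a stationary standard deviation of roughly
`sqrt(e0·kT/2)` per term (≈ 0.24 kcal/mol at the defaults) — an
irreducible consequence of discrete increments. The bias returned by
`run_flattening` is therefore the *time average* of the adapting bias
over the tail of the adaptation phase (default: the last half of the
updates), in the spirit of Ruppert–Polyak averaging in stochastic
approximation. This suppresses the jitter by an order of magnitude
without altering the adaptation dynamics, and the extraction formulas
are in any case exactly independent of which frozen bias is used (the
bias cancels from ΔΔG). Stage-2 runs use a frozen bias by default, which
preserves detailed balance and makes the population→free-energy
conversion exact; holo-state flattening is available by running
`run_flattening` on the complex instead.

## Free-energy extraction

`G̃(S) = −kT ln(counts/total)` per stage; `G = G̃ − E_B` removes the
bias. ΔΔG uses the bias-cancelling double ratio of stage-2 to stage-1
populations. Sequences with fewer than `visit_threshold = 1000` visits
in either stage are left unscored rather than estimated from noise.
Both stages must be extracted at the same kT; mixing temperatures is an
error. Optional block-bootstrap standard errors resample contiguous
trajectory blocks (population tables can carry per-block counts), giving
users error bars at the ~0.1 kcal/mol scale where design decisions are
made. Specificity is the difference of two ΔΔG columns toward two
ligands (or one biased run with the competitor-trained bias); catalytic
efficiency is `eff = −ΔΔG‡ − ΔΔG_bind`, i.e. kT·log of k_cat/K_M
relative to the reference under transition-state theory — no kT factor
appears because both inputs are already energies.

Folding free energies use a tri-peptide unfolded-state model: per type,
the best-rotamer energy averaged over the mutating positions where the
type is allowed (positions that disallow a type simply drop out of the
mean), summed over the sequence; the stability filter excludes variants
whose relative folding free energy reaches the threshold (default 5
kcal/mol; the AnL worked example uses 7, matching its published
protocol — both are exposed in the API/CLI). Ranking sorts the
remaining variants ascending by the chosen criterion with deterministic
lexicographic tie-breaks. The reference sequence must be supplied
explicitly; if it is unsampled the code errors rather than silently
re-referencing.

## Exact oracle and synthetic fixtures

For systems up to ~10⁷ microstates, `exact_oracle` enumerates all
(sequence, rotamer) states with log-sum-exp accumulation (stable down to
the 0.17 kcal/mol ladder rung) and returns exact sequence free energies,
Boltzmann marginals and ΔΔG — the ground truth for every stochastic
estimate in the test suite.

The fixture generator emulates the *structure* of real design inputs,
not force-field statistics: diagonal energies are zero-mean normal at
`energy_scale` (default 1.0 kcal/mol, giving sequence free-energy
spreads of a few kcal/mol over a 3-position × 5-type × 2-rotamer default
space), pair terms appear with probability `pair_density` (default 0.25)
at half scale, and a second state is a correlated perturbation of the
first (half-scale jitter, preserving topology). Planted binders pin the
enumerated ΔΔG of chosen sequences exactly (to 1e−9 at the fixture kT,
default 0.59) by shifting the bound-state diagonal of each planted
sequence's type at a dedicated marker position; planted sequences must
carry distinct marker types distinct from the reference. What passing
tests show: the sampler, bias machinery and extraction formulas are
correct and internally consistent on landscapes of realistic roughness.
What they do not show: anything about force-field accuracy, rotamer
libraries, or backbone flexibility in real proteins — those live in the
(out-of-scope) matrix construction.

## Numerical choices and problem sizes

- Acceptance moves use `dE ≤ 0 or u < exp(−dE/kT)`; no exponential
  overflow is possible for uphill moves at any ladder kT.
- Dense per-position combo tables back the compiled kernel; sequence
  counts are tabulated in a flat mixed-radix array (errors out above
  5·10⁷ sequences).
- Validation runs use 10⁶-step sampling checks, 4·10⁶-step adaptations
  and up to 2·10⁷-step production runs on ≤125-sequence toys — sizes
  chosen so exact enumeration is instant and statistical tolerances
  (total variation < 0.02, ΔΔG within 0.1 kcal/mol at the 1000-visit
  threshold, efficiencies within 0.2 kcal/mol) carry 3–4σ margins.
- Deterministic seeds everywhere; REMC spawns independent child streams
  per replica plus one for swap decisions from the master seed.

## Known limitations

- The bias acts on sequence types only; systems whose ruggedness lives
  in rotamer space within one sequence flatten more slowly (REMC is the
  remedy offered here).
- Single-position bias terms can only represent separable landscapes
  exactly; with strong pairwise sequence couplings the flattened
  populations stay uneven (pair bias terms exist but are off by
  default), which costs coverage, not correctness — ΔΔG extraction is
  bias-independent.
- Planted fixture truths are exact at the fixture's kT only; elsewhere
  they are approximate (the planting shift itself is
  temperature-independent, the residual it cancels is not).
- No continuous degrees of freedom, no backbone moves, no MD hybrid.
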