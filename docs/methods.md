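# Methods

`crisprtrace` reconstructs the evolutionary history of CRISPR spacer
arrays — which spacers ancestral strains carried, where spacers were
acquired, and which blocks of adjacent spacers were jointly deleted —
and estimates the parameters of an explicit stochastic model of array
turnover. This note records the models, the algorithmic and numerical
choices, and what the validation on synthetic data does and does not
establish.

## The evolutionary model

A spacer array is an ordered sequence of spacer labels, written
leader-proximal first. Arrays evolve along a rooted phylogeny `𝒯` with
branch lengths `t_b` by two Poisson processes:

* **Polarized insertion.** New, globally unique spacers are acquired at
  the leader end only, at total rate `θ`. The array is therefore a
  timeline: within one array, every spacer is younger than everything
  trailer-ward of it.
* **Deletion.** Two nested variants:
  * *Independent deletion model (IDM):* each present spacer is deleted
    on its own at rate `ρ_I`.
  * *Block deletion model (BDM):* each present spacer position initiates
    deletion events at rate `ρ_B`; an event at position `i` draws a
    length `L ~ geometric(mean α)`, `P(L=k) = (1−1/α)^(k−1)/α`, and
    removes the `L` adjacent currently-present spacers `i..i+L−1`.
    Events that would run past the current trailer end are ignored
    entirely (no truncation), which depresses realized deletion rates
    near both array boundaries — the behaviour expected if deletions
    arise from misalignment of nearby repeats. Earlier deletions close
    gaps, so later events act on the shortened array. `α = 1` recovers
    the IDM exactly.

## Branch likelihood of reconstructed deletions

For a branch `b`, let `N_b` be the number of spacers present at the
parent node and `K_b` the set of parent-array positions deleted along
`b`. The branch likelihood `L_B(b, N_b, K_b, ρ, α)` is the probability
that after time `t_b` exactly the spacers in `K_b` are gone. The
difficulty is the coupling: one observed run of missing spacers can
arise from many combinations of overlapping block events.

The implementation computes this likelihood **exactly for any array
size**. The deletion process is monotone, so every trajectory ending in
the observed outcome stays inside the states "all survivors present,
some subset of `K_b` still present". Restricting the continuous-time
Markov chain to these `2^|K_b|` states loses nothing, and `|K_b|` (the
number of deleted spacers on one branch) is small in practice even when
`N_b` is large. The restricted generator is graded: transitions strictly
decrease the number of surviving members of `K_b`, and the total exit
rate of a state depends only on the current array length. Its
eigenvalues are therefore the distinct executed-event rates
`ρ·R(m)`, `R(m) = Σ_{c=1..m} P(L ≤ c)`, and the outcome probability has
the closed form

    P(K_b deleted at t) = Σ_m γ_m · exp(−ρ R(m) t),

whose coefficients `γ_m` are filled in one sweep over the subset lattice
by partial fractions (no matrix exponential, no resonance: the `R(m)`
are strictly increasing). The `γ` depend only on `(α, K_b-run structure,
N_b)`, not on `ρ` or `t`, so profile-likelihood optimization over `ρ`
at fixed `α` reuses them.

Numerical safeguards: the spectral sum is evaluated with a condition
check (`Σ|terms| / result ≤ 1e10`); when cancellation exceeds it, the
same restricted chain is evaluated through a matrix exponential (dense
up to 64 states, single-vector `expm_multiply` beyond). Branches with
more than 12 deleted spacers in one maximal run are handled by halving
the run recursively and combining the pieces as if independent — the
only approximation in the likelihood, measured at ~1e-10 relative error
against the exact path at `α = 1` and used only in that rare regime.
The exact path is validated in the test suite against an independently
coded full `2^N` subset chain (dense `expm`), against closed forms
(`N = 1`, `α = 1`), against outcome-space normalization, and against
direct Monte-Carlo simulation of branches.

## Group likelihood, corrections, estimation, test

The group log-likelihood is the sum of branch terms (Eq. of the product
over branches). Two bias corrections apply:

* **Unobserved-spacer conditioning.** Spacers deleted in every sampled
  descendant of their acquisition point leave no trace, biasing rate
  estimates down. The likelihood is conditioned on each observed spacer
  surviving in at least one leaf below its acquisition node `v`:
  per spacer the factor `1 − q(v)`, with the recursion
  `q(leaf) = 0`, `q(v) = Π_c [(1−e^{−r t_c}) + e^{−r t_c} q(c)]`.
  The recursion treats spacers independently, which is exact under the
  IDM. Under the BDM, block deletions make spacer survivals strongly
  positively correlated; feeding the *marginal* per-spacer rate `ρ·α`
  into the product understates the joint observation probability
  without bound and makes the conditional likelihood improper (it
  diverges along the ridge `α → ∞`, `ρ ∝ α`). The implementation
  therefore uses the joint-consistent effective rate `r = ρ·R(n̄)/n̄`
  (`n̄` = mean observed array length), which preserves the array-wide
  no-deletion probability and reduces to `ρ_I` in the IDM. With this
  choice the corrected estimator removes the downward bias at the study
  scale while staying bounded everywhere.
* **Geometric small-sample correction.** The MLE of the geometric
  success probability `p = 1/α` is biased high for few events; the
  first-order correction `p̃ = p̂ − p̂(1−p̂)/n` (with `n` the number of
  reconstructed deletion events) is applied to the reported `α̂` and
  vanishes asymptotically. The likelihood-ratio test uses the
  uncorrected MLEs, since its statistic compares sup-likelihoods.

Estimation maximizes the corrected log-likelihood with a bounded
profile search: an outer golden-section search over `log α ∈ [0,
log 1000]` and an inner search over `log ρ ∈ [log 1e-6, log 1e6]`
(tolerances 1e-3 and 1e-5 on the log scale; the spectral coefficients
are cached per `α`). The boundary `α = 1` is always evaluated
explicitly so the alternative's supremum can never fall below the
null's. Standard errors, when requested, come from the
finite-difference observed information.

The LRT of IDM (`α = 1`) against BDM (`α ≥ 1`) uses
`−2 log λ = 2(ℓ_1 − ℓ_0)` with the boundary-aware null
`(χ²_0 + χ²_1)/2` (a plain `χ²_1` is available by configuration),
rejecting at level 0.05 by default. Measured calibration at the null on
200 simulated groups: 2–3% rejections, inside the 99% binomial band of
the nominal 5%; power exceeds 50% from simulated mean block length
≈ 1.4 on the validation grid.

## Reconstruction pipeline

1. **Alignment (MSAA).** Arrays are aligned on labels only; two cells
   share a column only if their labels are equal, so the alignment
   maximizes matched cells (equivalently minimizes gap cells). Groups of
   at most three arrays with arrays of length ≤ 12 are aligned exactly
   by multi-dimensional dynamic programming over consumed-prefix tuples;
   larger groups use progressive pairwise alignment ordered by shared
   label counts (exactness verified against the DP oracle on small
   cases). Within-array repeats are numbered from the trailer end (so a
   single occurrence elsewhere matches the oldest copy), and any label
   that still occupies several columns is split into renamed duplicate
   candidates (`3A`, `3B`, …).
2. **Guide reconstruction.** Each column evolves under a two-state
   gain/loss chain with loss:gain = 10:1 — explaining shared absence by
   repeated deletion is preferred over repeated independent acquisition
   of the same spacer. Internal states are assigned by exact joint
   maximum likelihood (max-product dynamic programming with backtrace,
   vectorized over columns), with support for externally fixed states.
   Three deliberate choices, each exposed as configuration and each
   motivated by reconstruction accuracy measured against simulation
   truth:
   * rates are scaled relative to the tree (loss × mean branch length
     = 0.5 by default) so behaviour does not depend on whether branch
     lengths are substitutions per site or coalescent units;
   * every positive branch contributes the same transition matrix
     (evaluated at the mean branch length). With literal per-branch
     Poisson costs, events migrate onto long branches (an acquisition
     costs `≈ log g·t`), fabricating ancestral presence near deep roots
     and spurious deletions in sister lineages;
   * likelihood ties at the root — time reversibility makes "acquired
     just below the root" and "present at root, deleted in the sister
     lineage" exactly equally likely — are broken toward absence, i.e.
     toward the polarized-acquisition reading. Within the tree, ties
     break toward presence.
3. **PSIO.** The per-array total orders ("acquired after") are pooled
   into a DAG and transitively reduced. Only the oldest candidate of
   each duplicate set (rootmost guide acquisition; ties toward the
   trailer-proximal column) is retained in the PSIO.
4. **Refinement.** An acquisition event of spacer `x` conflicts with the
   PSIO when some younger spacer's acquisition is not at-or-leafward of
   it. Each round fixes every conflicting spacer present at the parent
   node of its own acquisition branch and recomputes the constrained
   joint-ML assignment; constraints accumulate, the conflicting
   insertion walks rootward one node per round, and the loop terminates
   (capped at labels × nodes). After refinement no contradictions
   remain and the deletion count never falls below the guide's (both
   fuzz-tested over 500 simulated groups).
5. **Duplicate classification.** Each non-oldest candidate's insertion
   is classified, in order: *duplication* (a partner coexists at the
   acquisition node, or the insertion is internal rather than
   leader-end), *rearrangement* (a partner is deleted on the same
   branch), *reacquisition* (a partner exists at an ancestor),
   *independent acquisition* (no partner root-ward), *other* (e.g. a
   candidate already present at the root). This operationalizes the
   five published categories; edge cases of the original flowchart may
   differ.
6. **Orientation.** The pipeline runs on the group as given and on the
   reversed arrays; the reversed orientation is adopted only when its
   maximized BDM likelihood wins by more than 2 log-units, otherwise
   the supplied orientation is kept.

## Tree estimation from arrays

When no tree is supplied, a distance is computed per array pair from the
most parsimonious event explanation under the model: a private maximal
run touching the leader end counts one insertion per spacer; every other
private maximal run counts one block-deletion event. UPGMA (deterministic
lexicographic tie-breaking) or neighbor joining (negative estimates
clamped to zero) turns the matrix into a tree. These branch lengths are
event counts, not substitutions per site, so rates estimated on such
trees are not comparable to substitution-scaled rates; a genome-based
tree should be supplied whenever rate estimates matter. The distance
satisfies identity and symmetry but not the triangle inequality.

## Simulator

The simulator is the ground truth for every statistical claim. Trees
are standard coalescents (exponential waits with rate `C(k,2)`, uniform
pair merges; branch lengths in coalescent units) or user-supplied.
Arrays evolve by exact event-driven simulation of the insertion process
and one of three deletion variants: `boundary` (the BDM above),
`independent` (`α = 1`), and `uniform` — a symmetric reference in which
blocks may virtually overhang both array ends (start positions
`2−L..n`, truncated to the array) so that every position is covered at
exactly rate `ρ_B·α` regardless of position; its flatness is
unit-tested, and it serves as the null against which boundary-effect
profiles are compared. Root lengths are drawn from the balance Poisson
with mean `θ/(ρ_B·α)` (exact stationary law for the IDM; an
approximation under the BDM, with an optional single-lineage burn-in
mode). A full event log is kept and replay of the log from the root
array must reproduce every node array exactly.

Default study conditions (chosen once): 10-leaf coalescent trees,
per-spacer deletion rate `ρ_B·α = 0.3` per coalescent unit, and
`θ = 17.4 × 0.3` so the balance array length is ≈ 17 spacers — enough
turnover to observe deletions on coalescent-scale trees without
collapsing arrays.

Two simulator caveats. The balance length `θ/(ρ_B·α)` is exact only
under the IDM (and the uniform variant); under the boundary-ignoring
BDM the equilibrium mean sits noticeably higher (edge positions are
partially protected), so the 5%-band balance check is run at `α = 1`.
The `uniform` variant truncates the block-length proposal at `n + 60`,
an error below `1e-7` of coverage for `α ≤ 5`.

## What the synthetic validation shows — and does not

With both corrections enabled, on 100 simulated groups per condition the
median estimates of the per-spacer rate `ρ_B·α`, of `ρ_B`, and of `α`
land within 20% of truth at `α ∈ {1, 2, 4}`, and fitting the IDM to
blockwise data reproduces the documented downward rate bias. The LRT is
slightly conservative at the boundary and crosses 50% power near
`α ≈ 1.4` under the default conditions. Reconstruction recovers ≥ 90%
of logged deleted spacers only in easy regimes (branch lengths with
`ρ·α·t ≤ 0.1` and insertion-rich groups); at stationary turnover the
ceiling is ≈ 85%, because the deletion of a young spacer with no
younger shared spacer above it is fundamentally unidentifiable — the
order information that rescues older spacers does not exist for the
youngest cohort. The same asymmetry makes reconstructed first-spacer
(leader) deletion frequencies fall below last-spacer frequencies even
when the generating process treats both ends symmetrically; positional
profiles near the leader end should be read with this bias in mind.

The simulator draws insertion times from a constant-rate Poisson
process. Real acquisitions respond to phage exposure and likely occur
in bursts; real block lengths are geometric only to first approximation
(observed length distributions have heavier tails); and real groups
carry tree error, incomplete arrays, and mis-clustered spacers. Passing
the synthetic suite therefore establishes internal correctness of the
algorithms and estimators under the stated model, not the model's
adequacy for any particular dataset.

## Reported quantities

Per group the tool reports `ρ̂_I`, `ρ̂_B`, raw and bias-corrected `α̂`,
the per-spacer rate `ρ̂_B·α̂`, the LRT (`λ`, `−2 log λ`, p-value, chosen
model), the orientation decision with its likelihood margin, and the ad
hoc insertion-rate estimate `θ̂ = n̄·ρ̂_B·α̂` derived from the balance
heuristic — a quantity with large variance that should be treated with
extreme caution, particularly for single groups. Aggregation across
groups reports means and medians over groups with at least one
reconstructed deletion, the LRT rejection fraction, and duplicate-class
counts.
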