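# Methods

This note records how the package's constructions work and why the
non-obvious choices were made. Notation: `X` is the database/reference
side, `Y` the query/read side; the score of a pair is always the
log-likelihood ratio `llr(X, Y) = log P(X, Y) − log P(X) − log P(Y)`
between the joint model and independent background models.

## 1. Generative models

**Joint HMM.** A hidden chain `H_1 … H_T` (transition matrix `p_trans`,
prior `p_init`) emits one `(x_t, y_t)` pair per step from `p_emit[a, b, h]`.
The canonical two-state binary model (`HMMParams.symmetric_binary(ε, δ)`)
has a "matched" state, where the two symbols agree with probability
`1 − 2ε`, and a "swapped" state with the roles reversed; the chain switches
with probability δ. Forward recursion, scaled per column, gives
`log P(X, Y)` in O(T·|H|²); a batch variant scores one query against many
database rows at once.

**Alignment (SA) model.** A latent event string over `{m, i, d}` is drawn
i.i.d. from `(q_match, q_insertion, q_deletion)`. An `m` column emits an
`(x, y)` base pair from the joint table `p_m` (off-diagonal mass is the
substitution rate), a `d` column emits into X only, an `i` column into Y
only. `sa_joint_probability` sums all event strings with the standard
pair-HMM forward DP (numba, linear space, per-row rescaling);
`sa_path_probability` scores one explicit gapped alignment as the product
of its column factors. `SAParams.from_error_profile(total_error,
indel_frac)` builds the DNA model matched to a per-base error rate with a
chosen indel share.

Both samplers draw `(X, Y)` jointly, which is what every Monte-Carlo
estimate and synthetic benchmark in the package uses.

## 2. Bucket construction

### 2.1 Decision tree (gapless pairs)

Nodes are pair prefixes `(S_x, S_y)` of equal length. Each node carries the
joint prefix probability `p_joint` (forward state summed over hidden
states) and the background probabilities `p_x`, `p_y`. The builder grows
breadth-first and classifies every node:

* **prune** if `p_joint < prune_threshold` — the model says pairs are
  almost never here;
* **accept** as a bucket if the enrichment `p_joint / (p_x · p_y)` reaches
  `accept_ratio` (at the depth cap, a ratio ≥ 1 suffices);
* **branch** otherwise.

The layer-by-layer construction is fully vectorized over nodes; a
recursive single-node reference implementation (`root_node`/`extend_node`)
is kept as the semantic oracle and exercised in tests. With
`record_nodes=True` the per-layer tables are retained so the invariant
*"every expanded node's mass equals the sum over its children"* can be
audited (`conservation_error`; observed ≤ 1e-16 on the standard models).

The accepted set defines the index statistics
`α = Σ p_joint` (per-band true-positive mass),
`β = Σ p_x·p_y` (per-band background collision mass), and
`γ_x, γ_y` (per-side mapping multiplicities).

**Thresholds.** `accept_ratio` is the knob that decides how deep buckets
get. Small ratios accept shallow, high-mass buckets: α is large but β is
enormous and the candidate set approaches all-pairs. The defaults put
acceptance near the depth cap (binary HMM: ratio 300 at depth 12; DNA SA:
ratio 1e4), where one band keeps a usable α (0.1–0.2) while β stays small
enough that `J·β·M·N` — the expected number of background candidates — is
a tiny fraction of `M·N`. For the binary search model the prune threshold
5e-6 additionally keeps only the error-free, switch-free depth-12 buckets;
this "pure bucket" regime is what makes verified-pair growth clearly
sub-quadratic in the database size.

### 2.2 Bands

One bucketing pass looks at a single window of the sequences; a true pair
lands in some shared bucket there with probability α. `J` passes at
different offsets bound the miss probability: `J = ⌈−ln(ε_miss)/α⌉` gives
`(1 − α)^J ≤ ε_miss`. The prediction `TPR = 1 − (1 − α)^J` assumes the
bands are independent. Adjacent offsets share almost all their columns and
are strongly positively correlated, so bands are **spaced** (default
stride = bucket depth, i.e. disjoint windows); with disjoint windows the
measured TPR matches the formula within Monte-Carlo error
(`empirical_tpr`, checked at 10⁴ pairs within 3σ). When the sequence is
too short for J disjoint windows, the stride can be reduced; overlap then
biases the union rate slightly below the independent prediction, which is
conservative for planning but is kept out of the formula-validation
measurements.

### 2.3 Decision graph with indels

With indels the two prefixes grow at different rates, so nodes are keyed
by the pair `(S_x, S_y)` itself and distinct event paths (e.g. `m` versus
`d`-then-`i`) **merge**: their probabilities add, exactly like the forward
DP. `build_graph` grows layers by total emitted length and decides
accept/prune/branch only after a layer's mass is complete. This surface is
exponential in bucket length and serves small configurations and tests.

For DNA-scale indexes the package exploits base exchangeability (uniform
backgrounds, one substitution rate): every bucket statistic depends only
on the **column pattern** over `{M, S, D, I}` (clean match, substitution,
deletion, insertion), not on the concrete bases. `build_structure_index`
enumerates patterns with per-column enrichment factors (at 30% error:
`r_M = 2.8`, `r_S = 0.2`, `r_D = r_I = 0.075`), keeps indel runs in
canonical order (deletions before insertions) with a multiplicity factor
for the merged orderings, and branch-and-bounds patterns that cannot reach
the accept ratio within the length budget. `max_error_cols` (default 2)
caps non-clean columns per bucket, because each error column multiplies
the read-side enumeration cost; error tolerance beyond that is cheaper to
buy with more bands.

**Length budget.** Accepting a pattern containing error columns requires
enough clean-match columns to pay for them: the default budget is derived
from the model as `needed = ⌈(ln ρ + max_error_cols · err_cost)/ln r_M⌉`
emitted pairs plus room for the error columns themselves. A fixed budget
silently degenerates to exact-match-only buckets once the error rate rises
(at 45% error every error-tolerant pattern needs > 28 emitted characters),
which is precisely the regime where error tolerance matters most.

**Asymmetric join.** Classes of equal x-length `k` share one key space of
raw k-mer codes. The reference side contributes one code per position per
distinct `k` (sorted arrays). The read side enumerates, per class and
offset, every x-string compatible with the read suffix — M columns are
forced by the read base, S columns take the three other bases, D columns
all four, I columns consume a read base without contributing — and
deduplicates `(code, offset)` pairs. Co-occurrence is a vectorized sorted
join. A matching key at reference position `p` and read offset `r` votes
for diagonal `p − r`; votes are clustered within `0.35·L` (indel drift
bound for read length L) and each cluster's window (`L` plus 25% padding
on both sides) is verified.

Unlike the tree case, graph buckets overlap as events, so `Σ p_joint` only
upper-bounds the per-band hit rate. The band plan therefore uses a
Monte-Carlo estimate of α (`estimate_alpha`: jointly sampled pairs, shared
bucket at band 1), with the seed recorded on the index.

## 3. Verification scores

Candidates are always verified with the exact model score, so a DSB hit
list is a subset of the brute-force hit list at the same threshold and
every reported score is reproducible independently — both properties are
asserted in the acceptance tests.

For read-vs-window verification the *global* joint probability is the
wrong yardstick: a window longer than the read's true span charges every
flank base as a deletion (≈ −2.6 nats each at 30% error), so even perfect
reads score below background. `sa_llr_window` therefore computes a
**semi-global** ratio-space DP: match/insert/delete factors are divided by
the background probabilities of the characters they consume, unaligned
window flanks contribute factor 1, and the result sums alignments over
every sub-interval of the window (canonicalized so an alignment never
starts with a deletion column; a leading deletion is the same
configuration as a shorter window). Row maxima are rescaled out; because a
fresh alignment may start at any row, the unscaled row maximum is ≥ 1 and
the scale never underflows. The same scorer is used by the DSB search, the
exhaustive window oracle, and the verifiable-truth reference, and is
unit-tested against a brute-force sum over all windows.

## 4. Evaluation harness

`make_genome_reads` draws a uniform random genome and reads with per-base
substitution/insertion/deletion errors, ±20% length jitter, uniform
origins, and a 50% reverse-complement rate. `evaluate_hits` scores
sensitivity (a truth row is recovered when a same-read, same-strand hit
overlaps ≥ 50% of the true interval) and false positives (hits recovering
nothing). `verifiable_truth` computes the denominator for *relative*
sensitivity: rows whose padded true window itself scores below the
threshold are unrecoverable by any verification-based method and are
excluded. Only windows overlapping the true origin can count toward a
row's recovery, so scoring each read's padded true window is equivalent to
the full all-window scan for this purpose; the literal scan
(`exhaustive_window_search`) is kept and exercised on small genomes.

## 5. Limitations

* The structure builder requires a base-exchangeable model; position- or
  base-specific error profiles need the concrete graph (small scales) or
  an extension of the class notion.
* Pattern masses use the canonical event path per class; cross-class DP
  merging is neglected, making the stored α-sum conservative (the band
  plan uses the Monte-Carlo α, which is unaffected).
* The synthetic genome is uniform i.i.d.; repetitive real genomes would
  raise β (more background collisions) without affecting correctness,
  since every candidate is verified exactly.
* Band offsets on reads are evenly spaced across the read; very short
  reads (shorter than the longest bucket x-string) are skipped.
* The HMM search assumes equal-length, aligned-frame pairs; frame shifts
  belong to the SA model.
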