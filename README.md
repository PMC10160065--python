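# dsbucket

Distribution-sensitive bucketing for sequence alignment viewed as inference
in generative models.

Two related retrieval problems are solved exactly but fast:

1. **Joint-HMM retrieval** — pairs of equal-length sequences are modeled by a
   hidden Markov model that emits both sequences at once. Given a database of
   X-sides and a query Y-side, find the database entries whose joint
   log-likelihood ratio `log P(X,Y) − log P(X) − log P(Y)` is large.
2. **Read mapping under an alignment model** — a pair-HMM-like model with
   independent indel columns generates a read from a reference substring.
   Given a genome and error-bearing long reads, find where each read came
   from, scored by the same kind of likelihood ratio.

Both searches share one idea: instead of generic seeds (k-mers, minimizers),
buckets are derived **from the model itself**. A decision tree (gapless
case) or decision graph (indel case) is grown over pair prefixes; a branch
is accepted as a bucket once the model says co-occurrence there is strongly
enriched over chance, pruned when its probability is negligible, and
expanded otherwise. Buckets therefore concentrate exactly the pair mass the
model predicts, and the accepted-mass statistic α gives a closed-form band
plan: `J = ⌈−ln(ε_miss)/α⌉` repeated, shifted bucketing passes bound the
miss probability by `ε_miss`. Every candidate is then verified with the
exact likelihood ratio, so reported scores are identical to brute force —
bucketing can only *miss*, never hallucinate, and the miss rate is the
quantity the theory controls.

## Library tour

| Module | Contents |
| --- | --- |
| `dsbucket.models` | `HMMParams`, `SAParams`, exact forward recursions (`hmm_forward_joint`, `sa_joint_probability`), per-path scores, LLRs, and joint samplers |
| `dsbucket.brute_force` | Exact all-pairs search (`brute_force_search`), the quadratic-cost probe, TSV output |
| `dsbucket.dsb_hmm` | Decision-tree construction (`build_tree`), conservation audit, band planning (`choose_bands`, `predicted_tpr`, `empirical_tpr`), bucketed search (`dsb_search`) |
| `dsbucket.dsb_sa` | Concrete decision graph (`build_graph`), pattern-class builder for DNA (`build_structure_index`), Monte-Carlo band-rate estimation, read mapping (`dsb_sa_search`), the exhaustive window oracle, and the semi-global verification score `sa_llr_window` |
| `dsbucket.simulate` | Joint-HMM datasets, synthetic genome + long reads with substitution/indel errors, evaluation harness |
| `dsbucket.cli_io` | FASTA (plain or gzip), hit/truth tables, run configuration |

```python
from dsbucket import (
    HMMParams, BuildConfig, build_tree, dsb_search,
)
from dsbucket.simulate import make_hmm_dataset

params = HMMParams.symmetric_binary(error_rate=0.05, switch_prob=0.05)
index = build_tree(params, BuildConfig(prune_threshold=5e-6, accept_ratio=300))
db, queries, _ = make_hmm_dataset(0.05, 0.05, T=200, N=1000, rng_seed=7)
result = dsb_search(index, db, queries, params, top_k=1)
```

## Command line

The `dsbucket` umbrella command exposes the pipelines:

```sh
dsbucket simulate --genome-len 100000 --n-reads 200 --mean-len 700 \
    --total-error 0.30 --seed 0 \
    --out-reference ref.fa --out-reads reads.fa --out-truth truth.tsv
dsbucket sa-build --total-error 0.30 --indel-frac 0.5 --out index.dsb
dsbucket sa-search --index index.dsb --reference ref.fa --reads reads.fa \
    --total-error 0.30 --indel-frac 0.5 --out hits.tsv
dsbucket evaluate --hits hits.tsv --truth truth.tsv
```

`hmm-build` / `hmm-search` / `brute-force` do the same for the joint-HMM
setting; `stats` prints the α/β/γ statistics of a saved index. Every
subcommand logs its resolved configuration and seed to stderr.

## Tests

```sh
python -m pytest
```

The suite pins every numerical claim to an independent oracle: exhaustive
latent-variable enumeration for the forward recursions, a recursive
single-node reimplementation for the vectorized tree builder, brute-force
window sums for the semi-global score, and closed-form hand values for the
worked examples. `tests/test_acceptance.py` holds the end-to-end claims.

## Design notes

See [`docs/methods.md`](docs/methods.md) for the construction details:
accept/prune thresholds, the band-independence argument for spaced bands,
the pattern-class builder that makes DNA-scale indexing tractable, the
semi-global verification score, and known limitations.
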