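"""SA-model bucketing: decision graph, pattern classes, read mapping."""

import math

import numpy as np
import pytest

from dsbucket._dp import sa_forward_scaled
from dsbucket.dsb_hmm import choose_bands
from dsbucket.dsb_sa import (
    GraphNode,
    Hit,
    SABuildConfig,
    SAIndex,
    build_graph,
    build_structure_index,
    dsb_sa_search,
    encode_dna,
    estimate_alpha,
    exhaustive_window_search,
    extend_graph_node,
    map_sequence_sa,
    plan_bands,
    reverse_complement,
    sa_llr_window,
)
from dsbucket.models import SAParams, sample_sa_pair
from dsbucket.simulate import evaluate_hits, make_genome_reads, verifiable_truth


def _joint_prefix(params, x, y):
    """All-alignments mass of the pair (x, y): forward DP value."""
    em = params.q_match * params.p_m
    ei = params.q_insertion * params.p_i
    ed = params.q_deletion * params.p_d
    return math.exp(sa_forward_scaled(encode_dna(x), encode_dna(y), em, ei, ed))


# ---------------------------------------------------------------------------
# Basic DNA helpers
# ---------------------------------------------------------------------------


def test_reverse_complement():
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AACG") == "CGTT"
    assert reverse_complement(reverse_complement("GATTACA")) == "GATTACA"


def test_encode_dna_rejects_unknown():
    assert encode_dna("ACGT").tolist() == [0, 1, 2, 3]
    with pytest.raises(ValueError):
        encode_dna("ACGN")


# ---------------------------------------------------------------------------
# Concrete decision graph
# ---------------------------------------------------------------------------


def test_extend_graph_node_merges_alignment_paths(dna_read_model):
    p = dna_read_model
    root = GraphNode("", "", 1.0, 1.0, 1.0)
    graph = {}
    # three event paths land on the pair ("A", "C"): match, del-then-ins,
    # ins-then-del; the merged node must carry their summed mass
    extend_graph_node(root, ("m", "A", "C"), p, graph=graph)
    d = extend_graph_node(root, ("d", "A"), p)
    extend_graph_node(d, ("i", "C"), p, graph=graph)
    i = extend_graph_node(root, ("i", "C"), p)
    extend_graph_node(i, ("d", "A"), p, graph=graph)
    node = graph[("A", "C")]
    lut = {c: k for k, c in enumerate(p.alphabet)}
    expect = (
        p.q_match * p.p_m[lut["A"], lut["C"]]
        + 2 * p.q_deletion * p.p_d[lut["A"]] * p.q_insertion * p.p_i[lut["C"]]
    )
    assert node.p_joint == pytest.approx(expect, rel=1e-12)
    assert node.p_joint == pytest.approx(_joint_prefix(p, "A", "C"), rel=1e-12)


def test_extend_graph_node_validation(dna_read_model):
    root = GraphNode("", "", 1.0, 1.0, 1.0, status="pruned")
    with pytest.raises(ValueError, match="pruned"):
        extend_graph_node(root, ("m", "A", "A"), dna_read_model)
    with pytest.raises(ValueError, match="event"):
        extend_graph_node(GraphNode("", "", 1, 1, 1), ("x", "A"), dna_read_model)


def test_build_graph_requires_length_budget(dna_read_model):
    with pytest.raises(ValueError, match="max_total_len"):
        build_graph(dna_read_model, SABuildConfig())


def test_build_graph_masses_match_forward_dp(dna_read_model):
    # with no pruning and an unreachable accept ratio, every interior node
    # stays branched, so each bucket accepted at the penultimate layer
    # carries the exact all-alignments mass of its string pair
    cfg = SABuildConfig(max_total_len=7, prune_threshold=0.0, accept_ratio=1e12)
    index = build_graph(dna_read_model, cfg)
    assert index.kind == "sa-concrete"
    checked = 0
    for sx, sy, pj in zip(index.s_x, index.s_y, index.p_joint):
        if len(sx) + len(sy) == cfg.max_total_len - 1:
            assert pj == pytest.approx(_joint_prefix(dna_read_model, sx, sy), rel=1e-10)
            checked += 1
    assert checked > 0


def test_build_graph_buckets_are_enriched(dna_read_model):
    cfg = SABuildConfig(max_total_len=8, prune_threshold=1e-9, accept_ratio=30.0)
    index = build_graph(dna_read_model, cfg)
    ratios = index.p_joint / (index.p_x * index.p_y)
    assert (ratios >= 1.0 - 1e-12).all()
    assert index.alpha_sum == pytest.approx(float(index.p_joint.sum()))
    assert index.beta == pytest.approx(float((index.p_x * index.p_y).sum()))


def test_build_graph_exact_match_only_diagonal(dna_read_model):
    cfg = SABuildConfig(
        max_total_len=12, prune_threshold=0.0, accept_ratio=50.0, exact_match=True
    )
    index = build_graph(dna_read_model, cfg)
    assert all(sx == sy for sx, sy in zip(index.s_x, index.s_y))


# ---------------------------------------------------------------------------
# Structure (event-pattern) builder
# ---------------------------------------------------------------------------


def test_structure_rejects_uninformative_model(uniform_sa):
    with pytest.raises(ValueError, match="no diagonal enrichment"):
        build_structure_index(uniform_sa, SABuildConfig(max_total_len=10))


def test_structure_rejects_non_exchangeable_model():
    p_m = np.full((4, 4), 0.01)
    np.fill_diagonal(p_m, [0.2, 0.2, 0.2, 0.07])  # uneven diagonal
    p_m = p_m / p_m.sum()
    params = SAParams(
        p_m=p_m,
        p_i=np.full(4, 0.25),
        p_d=np.full(4, 0.25),
        q_match=0.85,
        q_insertion=0.075,
        q_deletion=0.075,
        px_background=np.full(4, 0.25),
        py_background=np.full(4, 0.25),
    )
    with pytest.raises(ValueError, match="exchangeable"):
        build_structure_index(params, SABuildConfig(max_total_len=10))


def test_structure_exact_match_classes_are_all_match(dna_read_model):
    cfg = SABuildConfig(exact_match=True)
    index = build_structure_index(dna_read_model, cfg)
    assert index.kind == "sa-structure"
    assert all(set(c) == {"M"} for c in index.classes)
    # per-class quantities follow in closed form from the column factors:
    # f_M = q_match * p_m_diagonal, per-concrete enrichment (16 f_M)^k
    f_m = dna_read_model.q_match * float(dna_read_model.p_m[0, 0])
    for cols, mass, ratio in zip(index.classes, index.p_joint, index.class_ratio):
        k = len(cols)
        assert mass == pytest.approx((4 * f_m) ** k, rel=1e-12)
        assert ratio == pytest.approx((16 * f_m) ** k, rel=1e-12)
        assert ratio >= cfg.accept_ratio


def test_structure_auto_length_budget(dna_read_model):
    cfg = SABuildConfig(accept_ratio=1e4, max_error_cols=2)
    index = build_structure_index(dna_read_model, cfg)
    # the resolved budget is stored on the index and follows the formula:
    # enough clean-match columns to pay for the costliest error columns
    r = {"M": 2.8, "S": 0.2, "D": 0.075, "I": 0.075}
    err_cost = max(-math.log(r[e]) for e in "SDI")
    needed = math.ceil((math.log(1e4) + 2 * err_cost) / math.log(r["M"]))
    assert index.config["max_total_len"] == 2 * needed + 4
    # classes with error columns exist and are longer than clean ones
    clean = min(len(c) for c in index.classes if set(c) == {"M"})
    dirty = min(len(c) for c in index.classes if set(c) != {"M"})
    assert dirty > clean


def test_structure_classes_respect_error_budget(dna_read_model):
    index = build_structure_index(dna_read_model, SABuildConfig(max_error_cols=2))
    for c in index.classes:
        assert sum(1 for e in c if e != "M") <= 2
        # canonical indel runs keep deletions before insertions
        runs = [r for r in c.replace("S", "M").split("M") if r]
        for run in runs:
            assert run == "D" * run.count("D") + "I" * run.count("I")


def test_read_keys_matches_scalar_path(dna_read_model, rng):
    index = build_structure_index(dna_read_model, SABuildConfig())
    for _ in range(5):
        enc = rng.integers(0, 4, size=60).astype(np.int64)
        offsets = np.array([0, 7, 20], dtype=np.int64)
        vec = index.read_keys(enc, offsets)
        vec_pairs = {
            (k, int(c), int(o))
            for k, (codes, offs) in vec.items()
            for c, o in zip(codes, offs)
        }
        scalar_pairs = set()
        for off in offsets:
            for k, code in index.read_key_set(enc, int(off)):
                scalar_pairs.add((k, code, int(off)))
        assert vec_pairs == scalar_pairs


def test_map_sequence_sa_structure_axes(dna_read_model):
    index = build_structure_index(dna_read_model, SABuildConfig(exact_match=True))
    s = "ACGTACGTACGTACGTACGT"
    xkeys = map_sequence_sa(index, s, "x", 1)
    # x side: raw k-mer codes at the band start, one per distinct length
    ks = sorted({len(c) for c in index.classes})
    assert {k for k, _ in xkeys} == {k for k in ks if k <= len(s)}
    # a jointly identical y maps to a superset containing the same keys
    ykeys = map_sequence_sa(index, s, "y", 1)
    assert xkeys & ykeys
    with pytest.raises(ValueError, match="axis"):
        map_sequence_sa(index, s, "z", 1)
    with pytest.raises(ValueError, match="band_j"):
        map_sequence_sa(index, s, "x", 0)


def test_map_sequence_sa_concrete_oracle(dna_read_model, rng):
    cfg = SABuildConfig(max_total_len=8, prune_threshold=1e-9, accept_ratio=30.0)
    index = build_graph(dna_read_model, cfg)
    s = "".join(rng.choice(list("ACGT"), size=25))
    for j in (1, 5):
        got = map_sequence_sa(index, s, "x", j)
        want = {
            i
            for i, sx in enumerate(index.s_x)
            if j - 1 + len(sx) <= len(s) and s[j - 1 : j - 1 + len(sx)] == sx
        }
        assert got == want


# ---------------------------------------------------------------------------
# Band-rate estimation and planning
# ---------------------------------------------------------------------------


def test_estimate_alpha_bounds_and_validation(dna_read_model):
    index = build_structure_index(dna_read_model, SABuildConfig())
    a, se = estimate_alpha(index, dna_read_model, n_sim=200, rng_seed=1)
    assert 0.0 <= a <= 1.0
    assert se > 0.0
    with pytest.raises(ValueError, match="n_sim"):
        estimate_alpha(index, dna_read_model, n_sim=10)


def test_plan_bands_zero_rate_floor(dna_read_model, monkeypatch):
    # when the Monte-Carlo estimate observes no shared bucket, the planner
    # falls back to the resolution floor 1/n_sim instead of failing
    import dsbucket.dsb_sa as mod

    index = build_structure_index(dna_read_model, SABuildConfig())
    monkeypatch.setattr(mod, "estimate_alpha", lambda *a, **k: (0.0, 0.0))
    plan_bands(index, dna_read_model, n_sim=500, rng_seed=0)
    assert index.alpha_estimate == pytest.approx(1 / 500)
    assert index.j_bands == choose_bands(1 / 500, index.eps_miss)


def test_plan_bands_fills_band_count(dna_read_model):
    index = build_structure_index(dna_read_model, SABuildConfig())
    assert index.j_bands is None
    plan_bands(index, dna_read_model, n_sim=300, rng_seed=2)
    assert index.alpha_estimate is not None
    assert index.j_bands == choose_bands(
        min(index.alpha_estimate, 1.0), index.eps_miss
    )


# ---------------------------------------------------------------------------
# Semi-global verification score
# ---------------------------------------------------------------------------


def test_sa_llr_window_equals_window_sum_oracle(dna_read_model, rng):
    """The semi-global score sums, over every x sub-window, the joint
    alignment mass of (window, y) divided by the backgrounds of the
    consumed window and of y; flanks outside the window are free.
    Alignments are canonicalized so that their first column is never a
    deletion (a leading deletion is instead a shorter window)."""
    p = dna_read_model
    rm = p.q_match * p.p_m / np.outer(p.px_background, p.py_background)
    ri = p.q_insertion * p.p_i / p.py_background
    rd = p.q_deletion * p.p_d / p.px_background

    def window_mass(xs, y):
        m = len(y)
        pr = [1.0] + [0.0] * m
        for j in range(1, m + 1):
            pr[j] = pr[j - 1] * ri[y[j - 1]]
        for i in range(1, len(xs) + 1):
            cu = [0.0] * (m + 1)  # column 0 dies: no leading deletions
            for j in range(1, m + 1):
                cu[j] = (
                    rm[xs[i - 1], y[j - 1]] * pr[j - 1]
                    + rd[xs[i - 1]] * pr[j]
                    + ri[y[j - 1]] * cu[j - 1]
                )
            pr = cu
        return pr[m]

    for _ in range(3):
        x = rng.integers(0, 4, size=10).astype(np.int64)
        y = rng.integers(0, 4, size=5).astype(np.int64)
        total = sum(
            window_mass(x[i:j], y)
            for i in range(len(x) + 1)
            for j in range(i, len(x) + 1)
        )
        assert sa_llr_window(p, x, y) == pytest.approx(math.log(total), abs=1e-9)


def test_sa_llr_window_separates_true_from_random(dna_read_model, rng):
    # an exact substring embedded in background should score well above 0
    genome = rng.integers(0, 4, size=200).astype(np.int64)
    read = genome[60:140]
    assert sa_llr_window(dna_read_model, genome, read) > 50.0
    # an unrelated read should score below 0
    other = rng.integers(0, 4, size=80).astype(np.int64)
    assert sa_llr_window(dna_read_model, genome, other) < 0.0


# ---------------------------------------------------------------------------
# End-to-end mapping
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_mapping():
    params = SAParams.from_error_profile(0.20, 0.5)
    reference, reads, truth = make_genome_reads(
        genome_len=5_000,
        n_reads=40,
        mean_len=250,
        total_error=0.20,
        indel_frac=0.5,
        rng_seed=21,
    )
    index = build_structure_index(params, SABuildConfig())
    plan_bands(index, params, n_sim=500, rng_seed=4)
    return params, reference, reads, truth, index


def test_dsb_sa_search_finds_reads(small_mapping):
    params, reference, reads, truth, index = small_mapping
    hits, stats = dsb_sa_search(index, reference, reads, params)
    report = evaluate_hits(hits, truth)
    assert report.sensitivity >= 0.9
    assert report.n_false_positive == 0
    assert stats.n_verified >= stats.n_hits
    assert stats.j_bands == index.j_bands


def test_dsb_sa_search_scores_match_independent_recomputation(small_mapping):
    params, reference, reads, truth, index = small_mapping
    hits, _ = dsb_sa_search(index, reference, reads, params)
    ref_seq = dict(reference)["ref0"]
    read_map = dict(reads)
    assert hits
    for h in hits[:20]:
        seq = read_map[h.query_id]
        if h.strand == "-":
            seq = reverse_complement(seq)
        window = encode_dna(ref_seq[h.ref_start : h.ref_end])
        assert h.score == pytest.approx(
            sa_llr_window(params, window, encode_dna(seq)), rel=1e-12
        )


def test_dsb_sa_search_unrelated_reads_yield_nothing(small_mapping):
    params, reference, _, _, index = small_mapping
    g = np.random.default_rng(99)
    decoys = [
        (f"decoy{i}", "".join("ACGT"[b] for b in g.integers(0, 4, size=250)))
        for i in range(10)
    ]
    hits, _ = dsb_sa_search(index, reference, decoys, params)
    assert hits == []


def test_dsb_sa_search_validates_model_hash(small_mapping, uniform_sa):
    _, reference, reads, _, index = small_mapping
    with pytest.raises(ValueError, match="hash"):
        dsb_sa_search(index, reference, reads, uniform_sa)


def test_exhaustive_oracle_recovers_verifiable_truth():
    params = SAParams.from_error_profile(0.20, 0.5)
    reference, reads, truth = make_genome_reads(
        genome_len=2_000,
        n_reads=10,
        mean_len=200,
        total_error=0.20,
        indel_frac=0.5,
        rng_seed=31,
    )
    hits = exhaustive_window_search(reference, reads, params)
    vt = verifiable_truth(reference, reads, truth, params)
    assert vt, "no verifiable truth rows in small simulation"
    report = evaluate_hits(hits, vt)
    assert report.sensitivity == 1.0


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def test_sa_index_roundtrip_concrete(tmp_path, dna_read_model):
    cfg = SABuildConfig(max_total_len=8, prune_threshold=1e-9, accept_ratio=30.0)
    index = build_graph(dna_read_model, cfg)
    path = tmp_path / "sa.dsb"
    index.save(path)
    loaded = SAIndex.load(path)
    assert loaded.kind == "sa-concrete"
    assert loaded.s_x == index.s_x and loaded.s_y == index.s_y
    assert np.allclose(loaded.p_joint, index.p_joint)
    assert loaded.model_hash == index.model_hash


def test_sa_index_roundtrip_structure(tmp_path, dna_read_model):
    index = build_structure_index(dna_read_model, SABuildConfig())
    plan_bands(index, dna_read_model, n_sim=200, rng_seed=5)
    path = tmp_path / "sa2.dsb"
    index.save(path)
    loaded = SAIndex.load(path)
    assert loaded.kind == "sa-structure"
    assert loaded.classes == index.classes
    assert np.allclose(loaded.class_ratio, index.class_ratio)
    assert loaded.j_bands == index.j_bands
    assert loaded.alpha_estimate == index.alpha_estimate
    # the loaded index maps identically
    s = "ACGTTGCAACGTTGCAACGT"
    assert map_sequence_sa(loaded, s, "y", 1) == map_sequence_sa(index, s, "y", 1)


def test_sa_build_config_validation():
    with pytest.raises(ValueError, match="eps_miss"):
        SABuildConfig(eps_miss=1.5)
    with pytest.raises(ValueError, match="max_total_len"):
        SABuildConfig(max_total_len=1)
    cfg = SABuildConfig(exact_match=True, max_error_cols=3)
    assert cfg.max_error_cols == 0
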