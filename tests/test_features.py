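"""The 39-feature descriptor, neighborhood rules, rank estimation."""

import numpy as np
import pytest

from ca2sse.features import (
    CANDIDATE_DIST,
    CANDIDATE_SEQ_SEP,
    FEATURE_NAMES,
    FINAL_SEG_DIST,
    N_FEATURES,
    NBR_COUNT_IDX,
    compute_feature_matrix,
    compute_feature_vector,
    estimate_rank,
    neighborhood_features,
    read_feature_tsv,
    reduce_features,
    write_feature_tsv,
)
from ca2sse.geometry import point_segment_distance, random_rotation
from ca2sse.synthetic import build_from_internal, make_helix, make_strand
from ca2sse.trace import CaTrace, Residue

HELIX_D13 = 5.053712   # ideal-helix dist(i, i+3), from the parameterization


def _trace_from(coords, start_seq=1):
    res = [Residue("A", start_seq + i, "ALA", xyz) for i, xyz in enumerate(coords)]
    return CaTrace(res, "TST_A")


def test_feature_names_cover_39():
    assert len(FEATURE_NAMES) == N_FEATURES == 39
    assert len(set(FEATURE_NAMES)) == 39


def test_internal_coordinate_round_trip():
    """Chains built from (l, theta, phi) reproduce theta in R, phi in T."""
    n = 9
    P = build_from_internal([3.8] * (n - 1), [91.0] * (n - 2), [50.0] * (n - 3))
    trace = _trace_from(P)
    vals, valid = compute_feature_vector(trace, 4)
    # R block: all three interior angles equal the built-in 91 degrees
    assert np.allclose(vals[0:3], 91.0, atol=1e-6)
    # T block: all four torsions equal the built-in 50 degrees
    assert np.allclose(vals[19:23], 50.0, atol=1e-6)
    # M sums are vector-angle + torsion
    assert np.allclose(vals[24:28], vals[15:19] + 50.0, atol=1e-6)
    assert valid[:28].all()


def test_partial_validity_mask_by_position():
    trace, _ = make_helix(7)
    _, valid = compute_feature_vector(trace, 3)  # center of 7 residues
    # center residue of a 7-chain has full i+-3 context
    assert valid.all()
    vals, valid = compute_feature_vector(trace, 1)
    # angle(i-1,i,i+1) is computable at i=1, but anything needing i-2 is not
    assert valid[0] and not valid[1]
    # dist(i-3,i) invalid, dist(i,i+2) valid
    assert not valid[3] and valid[5]


def test_chain_break_invalidates_spanning_features():
    coords = np.vstack([make_helix(10)[0].coords])
    res = [Residue("A", i + 1 if i < 5 else i + 3, "ALA", xyz)
           for i, xyz in enumerate(coords)]  # seq gap between index 4 and 5
    trace = CaTrace(res, "BRK_A")
    assert trace.has_break
    _, valid = compute_feature_vector(trace, 4)
    assert not valid[0]   # angle(i-1,i,i+1) spans the break
    _, valid2 = compute_feature_vector(trace, 2)
    assert valid2[0]      # far side of the break unaffected


def test_feature_matrix_column_consistency():
    trace, _ = make_helix(13)
    F = compute_feature_matrix(trace)
    assert F.values.shape == (39, 13)
    # columns equal per-residue vectors
    for i in (0, 4, 9, 12):
        v, m = compute_feature_vector(trace, i)
        assert np.array_equal(F.values[:, i], v)
        assert np.array_equal(F.valid[:, i], m)
    # i+-3 context: columns 3..9 fully valid, ends not
    assert F.column_valid().tolist() == [False] * 3 + [True] * 7 + [False] * 3


def test_rigid_motion_invariance_all_features():
    trace, _ = make_helix(13, jitter_sd=0.05, seed=9)
    F0 = compute_feature_matrix(trace).values
    rng = np.random.default_rng(1)
    for _ in range(10):
        moved = trace.transformed(random_rotation(rng), rng.normal(size=3))
        F1 = compute_feature_matrix(moved).values
        assert np.allclose(F0, F1, atol=1e-6)


def test_reflection_negates_torsions_only():
    trace, _ = make_helix(13, jitter_sd=0.05, seed=9)
    F0 = compute_feature_matrix(trace)
    mirrored = _trace_from(trace.coords * np.array([1.0, 1.0, -1.0]))
    F1 = compute_feature_matrix(mirrored)
    ok = F0.column_valid()
    # torsions negate; distances and unsigned angles unchanged
    assert np.allclose(F1.values[19:23][:, ok], -F0.values[19:23][:, ok], atol=1e-6)
    assert np.allclose(F1.values[0:19][:, ok], F0.values[0:19][:, ok], atol=1e-6)


# -- neighborhood rules ------------------------------------------------------

def test_helix_interior_neighbors_are_i_pm_3(ideal_helix):
    """Final list is exactly {i-3, i+3}: i+-4 are candidates (6.20 < 6.31)
    but their projection falls outside the (i-1, i+1) segment."""
    trace, _ = ideal_helix
    vals, valid, final = neighborhood_features(trace, 6)
    assert final == [3, 9]
    assert vals[0] == 2
    assert vals[4] == pytest.approx(HELIX_D13, abs=1e-5)
    # two-point cloud: second and third singular values vanish
    assert vals[2] == pytest.approx(0.0, abs=1e-9)
    assert vals[3] == pytest.approx(0.0, abs=1e-9)
    assert valid.all()


def test_straight_chain_has_no_neighbors():
    coords = np.array([[3.8 * i, 0.0, 0.0] for i in range(10)])
    trace = _trace_from(coords)
    vals, valid, final = neighborhood_features(trace, 5)
    assert final == [] and vals[0] == 0 and valid.all()
    assert np.allclose(vals, 0.0)  # sentinel


def test_hairpin_neighbors_match_brute_force(hairpin):
    """neighbor_count equals an independent double-loop enumeration."""
    trace, labels = hairpin
    coords, seq = trace.coords, trace.seq_nums
    n = len(trace)
    for i in range(1, n - 1):
        cand = [k for k in range(n)
                if abs(int(seq[k]) - int(seq[i])) >= CANDIDATE_SEQ_SEP
                and np.linalg.norm(coords[k] - coords[i]) < CANDIDATE_DIST]
        cand = [k for k in cand
                if any(abs(int(seq[k]) - int(seq[kk])) == 1 for kk in cand)]
        expect = [k for k in cand
                  if (lambda d_in: d_in[0] < FINAL_SEG_DIST and d_in[1])(
                      point_segment_distance(coords[k], coords[i - 1],
                                             coords[i + 1]))]
        vals, _, final = neighborhood_features(trace, i)
        assert final == sorted(expect)
        assert vals[0] == len(expect)


def test_hairpin_cross_strand_partner(hairpin):
    trace, _ = hairpin
    # interior residue of the first strand pairs across at ~4.8 A
    vals, valid, final = neighborhood_features(trace, 2)
    assert vals[0] >= 2
    assert vals[4] == pytest.approx(4.8, abs=0.3)
    assert vals[5] < 0  # partner comes later in sequence


def test_separated_strands_have_no_neighbors():
    from ca2sse.synthetic import hairpin_coords
    coords = hairpin_coords(6, separation=8.0)
    trace = _trace_from(coords)
    vals, _, final = neighborhood_features(trace, 2)
    assert final == [] and vals[0] == 0


def test_eigenlengths_are_sorted_on_corpus(small_corpus):
    for trace, _ in small_corpus:
        F = compute_feature_matrix(trace)
        e = F.values[29:32][:, F.column_valid()]
        assert np.all(e[0] >= e[1]) and np.all(e[1] >= e[2]) and np.all(e[2] >= 0)
        assert np.all(F.values[NBR_COUNT_IDX] >= 0)


# -- rank estimation and feature reduction -----------------------------------

@pytest.mark.parametrize("strategy", ["energy", "gap"])
def test_identity_full_rank(strategy):
    assert estimate_rank(np.eye(5), strategy) == 5


@pytest.mark.parametrize("strategy", ["energy", "gap"])
def test_outer_product_rank_one(strategy):
    M = np.outer(np.arange(1, 5.0), np.ones(3))
    assert estimate_rank(M, strategy) == 1


def test_zero_matrix_rank_zero():
    assert estimate_rank(np.zeros((4, 4))) == 0


def test_gap_strategy_recovers_planted_rank():
    hits = 0
    for s in range(500):
        rng = np.random.default_rng(s)
        k = int(rng.integers(1, 6))
        M = (rng.normal(size=(20, k)) @ rng.normal(size=(k, 30))
             + 1e-6 * rng.normal(size=(20, 30)))
        hits += estimate_rank(M, "gap") == k
    assert hits / 500 >= 0.99


def test_reduce_features_spans_independent_rows():
    rng = np.random.default_rng(0)
    r, s = rng.normal(size=12), rng.normal(size=12)
    M = np.vstack([r, 2 * r, s])
    rows = reduce_features(M, seed=0)
    assert len(rows) == 2
    sub = M[rows]
    assert np.linalg.matrix_rank(sub) == 2  # spans {r, s}, never {r, 2r}


def test_reduce_features_full_rank_square():
    # well-conditioned full-rank matrix: every row is needed
    rng = np.random.default_rng(3)
    M = np.linalg.qr(rng.normal(size=(5, 5)))[0]
    assert reduce_features(M, seed=0).tolist() == [0, 1, 2, 3, 4]


def test_reduce_features_energy_criterion_may_be_unsatisfiable(small_corpus):
    """Under the energy rule no valid submatrix need exist on real
    feature matrices; the search reports its best attempt instead of
    silently looping."""
    trace, _ = small_corpus[0]
    F = compute_feature_matrix(trace)
    with pytest.raises(RuntimeError, match="best achieved rank"):
        reduce_features(F, strategy="energy", seed=0, max_restarts=50)


def test_reduce_features_identical_rows_lowest_index():
    M = np.tile(np.arange(1, 7.0), (4, 1))
    assert reduce_features(M, seed=0).tolist() == [0]


def test_reduce_features_output_rank_invariant(small_corpus):
    trace, _ = small_corpus[0]
    F = compute_feature_matrix(trace)
    rows = reduce_features(F, strategy="gap", seed=0)
    sub = F.values[:, F.column_valid()][rows]
    assert estimate_rank(sub, "gap") == len(rows)


# -- TSV export --------------------------------------------------------------

def test_feature_tsv_round_trip(small_corpus):
    trace, labels = small_corpus[0]
    F = compute_feature_matrix(trace)
    text = write_feature_tsv(F, trace, labels)
    assert text.splitlines()[0].split("\t")[4:] == list(FEATURE_NAMES)
    back, labs = read_feature_tsv(text)
    assert labs == list(labels)
    assert np.array_equal(back.valid, F.valid)
    assert np.allclose(back.values[F.valid], F.values[F.valid], atol=1e-5)
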