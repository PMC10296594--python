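"""The 39-dimensional geometric descriptor of a C-alpha residue.

Each residue i of a trace is described by seven blocks computed purely
from C-alpha coordinates within the i-3 .. i+3 context plus a
neighborhood search over the whole chain:

* R (3)  interior angles of consecutive triples,
* E (4)  Euclidean distances d(i-3,i), d(i-2,i), d(i,i+2), d(i,i+3),
* D (8)  distances measured along virtual axes through nearby residues,
* V (4)  angles between displacement vectors,
* T (4)  signed pseudo-torsions of consecutive quadruples,
* M (5)  amino-acid type code plus the four V+T sums,
* N (11) neighborhood block: spatially close, sequence-distant partners
         (the signature of paired beta-strands).

Every element carries a validity flag; an element is invalid when a
residue it needs is missing or the atoms it spans cross a chain break.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    axis_distance,
    interior_angle,
    point_segment_distance,
    torsion_angle,
    vector_angle,
)
from .trace import AA_INDEX, CaTrace, LabelSequence

__all__ = [
    "N_FEATURES",
    "FEATURE_NAMES",
    "FeatureMatrix",
    "neighborhood_features",
    "compute_feature_vector",
    "compute_feature_matrix",
    "estimate_rank",
    "reduce_features",
    "write_feature_tsv",
    "read_feature_tsv",
]

N_FEATURES = 39

#: Distance cutoff for a residue to enter the neighbor candidate list (A).
CANDIDATE_DIST = 6.31
#: Minimum sequence separation of a neighbor candidate.
CANDIDATE_SEQ_SEP = 3
#: Final-list cutoff: distance to the segment (i-1, i+1) (A).
FINAL_SEG_DIST = 5.81

FEATURE_NAMES = (
    # R: interior angles
    "angle_im1_i_ip1", "angle_im2_im1_i", "angle_i_ip1_ip2",
    # E: Euclidean distances
    "dist_im3_i", "dist_im2_i", "dist_i_ip2", "dist_i_ip3",
    # D: axis distances
    "axisDist_im2_im1", "axisDist_i_ip1", "axisDist2_i_ip1",
    "axisDist_im1_i", "axisDist2_im1_i", "axisDist_ip1_ip2",
    "axisDist_im3_im2", "axisDist_ip2_ip3",
    # V: vector angles
    "vAngle_1", "vAngle_2", "vAngle_3", "vAngle_4",
    # T: torsions
    "torsion_1", "torsion_2", "torsion_3", "torsion_4",
    # M: miscellaneous
    "aa_type", "vt_sum_1", "vt_sum_2", "vt_sum_3", "vt_sum_4",
    # N: neighborhood
    "nbr_count", "nbr_eig1", "nbr_eig2", "nbr_eig3", "nbr_dist_ij",
    "nbr_seq_diff", "nbr_dist_im1_jm1", "nbr_dist_im1_jp1",
    "nbr_dist_ip1_jm1", "nbr_dist_ip1_jp1", "nbr_angle",
)

# relative index span (lo, hi) needed by each non-neighborhood feature
_SPANS = (
    (-1, 1), (-2, 0), (0, 2),                       # R
    (-3, 0), (-2, 0), (0, 2), (0, 3),               # E
    (-2, 1), (-2, 1), (-2, 2), (-1, 2), (-3, 1),    # D (first five)
    (-1, 2), (-3, 0), (0, 3),                       # D (last three)
    (-2, 1), (-1, 2), (-3, 0), (0, 3),              # V
    (-2, 1), (-1, 2), (-3, 0), (0, 3),              # T
    (0, 0), (-2, 1), (-1, 2), (-3, 0), (0, 3),      # M
)

# index ranges of the blocks within the 39-vector
R_SLICE = slice(0, 3)
E_SLICE = slice(3, 7)
D_SLICE = slice(7, 15)
V_SLICE = slice(15, 19)
T_SLICE = slice(19, 23)
M_SLICE = slice(23, 28)
N_SLICE = slice(28, 39)

NBR_COUNT_IDX = 28
#: The five neighborhood distances the post-processing rules count.
NBR_DIST_IDX = (32, 34, 35, 36, 37)


@dataclass
class FeatureMatrix:
    """d x N feature matrix: one 39-feature column per residue."""

    values: np.ndarray          # (39, N)
    valid: np.ndarray           # (39, N) bool
    source_id: str = ""
    seq_nums: np.ndarray | None = None

    def __post_init__(self):
        if self.values.shape[0] != N_FEATURES or self.values.shape != self.valid.shape:
            raise ValueError("feature matrix must be 39 x N with matching mask")

    @property
    def n_residues(self) -> int:
        return self.values.shape[1]

    def column_valid(self) -> np.ndarray:
        """Mask of residues whose full 39-vector is valid."""
        return self.valid.all(axis=0)


def _span_ok(i: int, lo: int, hi: int, n: int, breaks: frozenset) -> bool:
    a, b = i + lo, i + hi
    if a < 0 or b >= n:
        return False
    return not any(a <= k < b for k in breaks)


def neighborhood_features(trace: CaTrace, i: int):
    """Neighborhood block N of residue ``i``.

    Returns ``(values, valid, final_list)`` where values/valid have 11
    entries and ``final_list`` holds the trace indices of the retained
    neighbors.

    Candidates are residues at least ``CANDIDATE_SEQ_SEP`` apart in
    sequence and closer than ``CANDIDATE_DIST`` in space, pruned to
    those with a sequence-adjacent fellow candidate; the final list
    keeps candidates whose perpendicular to the segment (i-1, i+1) is
    shorter than ``FINAL_SEG_DIST`` and lands inside the segment.  An
    empty final list yields all-zero (but valid) sentinel values.
    """
    n = len(trace)
    vals = np.zeros(11)
    valid = np.zeros(11, dtype=bool)
    if not (_span_ok(i, -1, 1, n, trace.break_after)):
        return vals, valid, []

    coords = trace.coords
    seq = trace.seq_nums
    di = np.linalg.norm(coords - coords[i], axis=1)
    cand = [k for k in range(n)
            if abs(int(seq[k]) - int(seq[i])) >= CANDIDATE_SEQ_SEP
            and di[k] < CANDIDATE_DIST]
    cand_seq = {int(seq[k]) for k in cand}
    cand = [k for k in cand
            if (int(seq[k]) - 1) in cand_seq or (int(seq[k]) + 1) in cand_seq]
    final = []
    for k in cand:
        d, inside = point_segment_distance(coords[k], coords[i - 1], coords[i + 1])
        if d < FINAL_SEG_DIST and inside:
            final.append(k)

    valid[:] = True
    if not final:
        return vals, valid, []  # sentinel zeros

    vals[0] = len(final)
    pts = coords[final]
    centered = (pts - pts.mean(axis=0)).T  # 3 x n
    sv = np.linalg.svd(centered, compute_uv=False)
    sv = np.pad(sv, (0, max(0, 3 - len(sv))))[:3]
    vals[1:4] = sv
    j = min(final, key=lambda k: (di[k], k))
    vals[4] = di[j]
    vals[5] = int(seq[i]) - int(seq[j])
    # pairwise distances between the flanks of i and of j
    for slot, (a, b) in enumerate(((i - 1, j - 1), (i - 1, j + 1),
                                   (i + 1, j - 1), (i + 1, j + 1))):
        if 0 <= b < n:
            vals[6 + slot] = np.linalg.norm(coords[a] - coords[b])
        else:
            valid[6 + slot] = False
    if 0 <= j - 1 and j + 1 < n:
        vals[10] = vector_angle(coords[i + 1] - coords[i - 1],
                                coords[j + 1] - coords[j - 1])
    else:
        valid[10] = False
    return vals, valid, final


def compute_feature_vector(trace: CaTrace, i: int):
    """The 39-element descriptor of residue ``i`` with its validity mask."""
    n = len(trace)
    c = trace.coords
    breaks = trace.break_after
    vals = np.zeros(N_FEATURES)
    valid = np.zeros(N_FEATURES, dtype=bool)

    ok = [
        _span_ok(i, lo, hi, n, breaks) for lo, hi in _SPANS
    ]

    # R: interior angles
    triples = ((i - 1, i, i + 1), (i - 2, i - 1, i), (i, i + 1, i + 2))
    for m, (a, b, d) in enumerate(triples):
        if ok[m]:
            vals[m] = interior_angle(c[a], c[b], c[d])
            valid[m] = True
    # E: distances
    pairs = ((i - 3, i), (i - 2, i), (i, i + 2), (i, i + 3))
    for m, (a, b) in enumerate(pairs, start=3):
        if ok[m]:
            vals[m] = np.linalg.norm(c[a] - c[b])
            valid[m] = True
    # D: axis distances.  Table: (axis_a, axis_b, from, to, proj_from, proj_to)
    axes = (
        (i - 2, i + 1, i - 2, i - 1, False, True),   # axisDist(i-2,i-1)
        (i - 2, i + 1, i, i + 1, True, False),       # axisDist(i,i+1)
        (i - 2, i + 2, i, i + 1, True, True),        # axisDist2(i,i+1)
        (i - 1, i + 2, i - 1, i, False, True),       # axisDist(i-1,i)
        (i - 3, i + 1, i - 1, i, True, True),        # axisDist2(i-1,i)
        (i - 1, i + 2, i + 1, i + 2, True, False),   # axisDist(i+1,i+2)
        (i - 3, i, i - 3, i - 2, False, True),       # axisDist(i-3,i-2)
        (i, i + 3, i + 2, i + 3, True, False),       # axisDist(i+2,i+3)
    )
    for m, (aa, ab, f, t, pf, pt) in enumerate(axes, start=7):
        if ok[m]:
            vals[m] = axis_distance(c[aa], c[ab], c[f], c[t], pf, pt)
            valid[m] = True
    # V: vector angles
    vpairs = (((i - 2, i), (i - 1, i + 1)), ((i - 1, i + 1), (i, i + 2)),
              ((i - 3, i - 1), (i - 2, i)), ((i, i + 2), (i + 1, i + 3)))
    for m, ((a1, a2), (b1, b2)) in enumerate(vpairs, start=15):
        if ok[m]:
            vals[m] = vector_angle(c[a2] - c[a1], c[b2] - c[b1])
            valid[m] = True
    # T: torsions
    quads = ((i - 2, i - 1, i, i + 1), (i - 1, i, i + 1, i + 2),
             (i - 3, i - 2, i - 1, i), (i, i + 1, i + 2, i + 3))
    for m, q in enumerate(quads, start=19):
        if ok[m]:
            vals[m] = torsion_angle(*(c[k] for k in q))
            valid[m] = True
    # M: amino-acid type + V/T sums
    vals[23] = AA_INDEX[trace.residues[i].aa_code]
    valid[23] = True
    for m in range(4):
        if valid[15 + m] and valid[19 + m]:
            vals[24 + m] = vals[15 + m] + vals[19 + m]
            valid[24 + m] = True
    # N: neighborhood
    nvals, nvalid, _ = neighborhood_features(trace, i)
    vals[N_SLICE] = nvals
    valid[N_SLICE] = nvalid
    return vals, valid


def compute_feature_matrix(trace: CaTrace) -> FeatureMatrix:
    """Feature descriptors for every residue, columns aligned to the trace."""
    n = len(trace)
    values = np.zeros((N_FEATURES, n))
    valid = np.zeros((N_FEATURES, n), dtype=bool)
    for i in range(n):
        values[:, i], valid[:, i] = compute_feature_vector(trace, i)
    return FeatureMatrix(values, valid, trace.source_id, trace.seq_nums)


def estimate_rank(M: np.ndarray, strategy: str = "energy", tol: float = 0.95) -> int:
    """Effective rank of a matrix from its singular-value spectrum.

    ``energy``: smallest k whose leading singular values carry at least
    a fraction ``tol`` of the total squared spectrum (default 0.95).

    ``gap``: index maximizing the ratio of consecutive singular values;
    the numerical-rank cut (sigma < 1e-10 * sigma_1) acts as a virtual
    gap so exactly-low-rank and full-rank matrices resolve correctly.
    """
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        return 0
    sv = np.linalg.svd(M, compute_uv=False)
    if sv[0] <= 0:
        return 0
    if strategy == "energy":
        if not (0 < tol <= 1):
            raise ValueError("energy threshold must be in (0, 1]")
        energy = np.cumsum(sv ** 2) / np.sum(sv ** 2)
        return int(np.searchsorted(energy, tol - 1e-12) + 1)
    if strategy == "gap":
        floor = 1e-10 * sv[0]
        r = int(np.sum(sv > floor))  # numerical rank
        sv_ext = np.append(sv, 0.0)
        ratios = [sv_ext[j] / max(sv_ext[j + 1], floor) for j in range(r)]
        return int(np.argmax(ratios) + 1)
    raise ValueError(f"unknown rank strategy {strategy!r}")


def reduce_features(F, strategy: str = "gap", tol: float = 0.95,
                    seed: int | None = 0, max_restarts: int = 200) -> np.ndarray:
    """Select k = effective-rank(F) rows whose submatrix has effective rank k.

    Accepts a :class:`FeatureMatrix` (only fully valid columns are used)
    or a plain array.  A deterministic greedy sweep (lowest row index
    first, keeping rows that enlarge the span) is tried first; if the
    chosen submatrix does not reach effective rank k under the same
    criterion, random k-subsets are tried up to ``max_restarts`` times.

    The spectral-gap criterion is the default here: under the energy
    criterion a k-row submatrix of effective rank k need not exist at
    all (every subset can concentrate its spectrum faster than the full
    matrix), in which case the search reports its best attempt.
    """
    if isinstance(F, FeatureMatrix):
        M = F.values[:, F.column_valid()]
    else:
        M = np.asarray(F, dtype=float)
    if M.size == 0 or M.shape[1] == 0:
        raise ValueError("no valid columns to reduce")
    k = estimate_rank(M, strategy, tol)
    if k == 0:
        return np.array([], dtype=int)

    # greedy: accept a row iff it leaves a significant residual against
    # the span of the rows accepted so far
    basis: list[np.ndarray] = []
    chosen: list[int] = []
    for r in range(M.shape[0]):
        row = M[r].astype(float)
        nrm = np.linalg.norm(row)
        if nrm <= 0:
            continue
        resid = row.copy()
        for b in basis:
            resid -= np.dot(resid, b) * b
        if np.linalg.norm(resid) > 1e-8 * nrm:
            basis.append(resid / np.linalg.norm(resid))
            chosen.append(r)
        if len(chosen) == k:
            break

    def ok(rows):
        return len(rows) == k and estimate_rank(M[list(rows)], strategy, tol) == k

    if ok(chosen):
        return np.array(chosen, dtype=int)

    rng = np.random.default_rng(seed)
    best = np.array(chosen, dtype=int)
    best_rank = estimate_rank(M[best], strategy, tol) if len(best) else 0
    for _ in range(max_restarts):
        rows = np.sort(rng.choice(M.shape[0], size=k, replace=False))
        rk = estimate_rank(M[rows], strategy, tol)
        if rk == k:
            return rows
        if rk > best_rank:
            best, best_rank = rows, rk
    raise RuntimeError(
        f"no {k}-row submatrix of effective rank {k} found in "
        f"{max_restarts} restarts; best achieved rank {best_rank} with rows "
        f"{best.tolist()}")


def write_feature_tsv(F: FeatureMatrix, trace: CaTrace,
                      labels: LabelSequence | None = None) -> str:
    """Serialize a feature matrix as TSV (masked entries become NA)."""
    data = {
        "source_id": [trace.source_id] * len(trace),
        "chain": [r.chain_id for r in trace.residues],
        "seq_num": [r.seq_num for r in trace.residues],
        "label": list(labels) if labels is not None else ["L"] * len(trace),
    }
    vals = F.values.T.astype(object)
    vals[~F.valid.T] = None
    for m, name in enumerate(FEATURE_NAMES):
        data[name] = vals[:, m]
    df = pd.DataFrame(data)
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, na_rep="NA", float_format="%.6f")
    return buf.getvalue()


def read_feature_tsv(text: str) -> tuple[FeatureMatrix, list[str]]:
    """Parse a feature TSV back into a matrix plus its label column."""
    df = pd.read_csv(io.StringIO(text), sep="\t")
    missing = [n for n in FEATURE_NAMES if n not in df.columns]
    if missing:
        raise ValueError(f"feature TSV missing columns: {missing[:3]} ...")
    vals = df[list(FEATURE_NAMES)].to_numpy(dtype=float).T
    valid = ~np.isnan(vals)
    vals = np.nan_to_num(vals)
    fm = FeatureMatrix(vals, valid,
                       str(df["source_id"].iloc[0]) if len(df) else "",
                       df["seq_num"].to_numpy() if "seq_num" in df else None)
    return fm, df["label"].astype(str).tolist()
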