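"""Synthetic labeled C-alpha traces for offline training and testing.

The generator emulates the three secondary-structure geometries at the
C-alpha level:

* ideal right-handed alpha-helices (radius 2.3 A, rise 1.5 A per
  residue, 100 degrees of twist; consecutive C-alpha spacing then comes
  out at 3.83 A and the pseudo-torsion at +50 degrees);
* extended beta-strands (virtual bond 3.8 A, virtual angle 123
  degrees, alternating +/-170 degree pseudo-torsions), pairable into
  antiparallel hairpins at a 4.8 A inter-strand separation so the
  neighborhood features fire exactly as they do for real sheets;
* random coils drawn from wide virtual-angle/torsion distributions
  with a self-intersection rejection step.

Gaussian coordinate jitter models experimental noise.  All randomness
derives from explicit seeds, so every fixture is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace import CaTrace, LabelSequence, Residue, STANDARD_AA

__all__ = [
    "SegmentSpec",
    "ProteinSpec",
    "build_from_internal",
    "measure_internal",
    "make_helix",
    "make_strand",
    "make_hairpin",
    "make_coil",
    "make_protein",
    "make_corpus",
]

#: Minimum clearance between residues of different segments (A); chosen
#: above the neighbor-candidate cutoff so cross-segment contacts never
#: masquerade as strand pairing.
SEGMENT_CLEARANCE = 6.5
CONNECT_BOND = 3.8


def build_from_internal(bonds, angles, torsions) -> np.ndarray:
    """Chain coordinates from internal coordinates (NeRF extension).

    ``bonds`` has n-1 lengths (A), ``angles`` n-2 interior angles and
    ``torsions`` n-3 dihedrals (degrees).  The measured internal
    coordinates of the result reproduce the inputs exactly.
    """
    bonds = np.asarray(bonds, dtype=float)
    angles = np.radians(np.asarray(angles, dtype=float))
    torsions = np.radians(np.asarray(torsions, dtype=float))
    if np.any(bonds <= 0):
        raise ValueError("bond lengths must be positive")
    n = len(bonds) + 1
    if len(angles) != max(0, n - 2) or len(torsions) != max(0, n - 3):
        raise ValueError("need n-1 bonds, n-2 angles, n-3 torsions")
    P = np.zeros((n, 3))
    if n >= 2:
        P[1] = [bonds[0], 0.0, 0.0]
    if n >= 3:
        th = angles[0]
        P[2] = P[1] + bonds[1] * np.array([-np.cos(th), np.sin(th), 0.0])
    for k in range(3, n):
        A, B, C = P[k - 3], P[k - 2], P[k - 1]
        b, th, ph = bonds[k - 1], angles[k - 2], torsions[k - 3]
        bc = C - B
        bc /= np.linalg.norm(bc)
        ab = B - A
        nvec = np.cross(ab, bc)
        nvec /= np.linalg.norm(nvec)
        m = np.cross(nvec, bc)
        d = np.array([-b * np.cos(th), b * np.sin(th) * np.cos(ph),
                      b * np.sin(th) * np.sin(ph)])
        P[k] = C + d[0] * bc + d[1] * m + d[2] * nvec
    return P


def measure_internal(P: np.ndarray):
    """Bonds, interior angles and torsions of a coordinate chain."""
    from .geometry import interior_angle, torsion_angle

    P = np.asarray(P, dtype=float)
    bonds = np.linalg.norm(np.diff(P, axis=0), axis=1)
    angles = np.array([interior_angle(P[i], P[i + 1], P[i + 2])
                       for i in range(len(P) - 2)])
    torsions = np.array([torsion_angle(P[i], P[i + 1], P[i + 2], P[i + 3])
                         for i in range(len(P) - 3)])
    return bonds, angles, torsions


def _apply_jitter(coords: np.ndarray, rng: np.random.Generator,
                  sd: float, max_passes: int = 100) -> np.ndarray:
    """Gaussian coordinate noise that respects the trace invariants.

    Residues whose jitter pushes a virtual bond outside the plausible
    CA-CA range get their displacement redrawn (locally, so the rest of
    the chain keeps its first draw).
    """
    from .trace import CA_CA_MAX, CA_CA_MIN

    lo, hi = CA_CA_MIN + 0.05, CA_CA_MAX - 0.05
    out = coords + rng.normal(0.0, sd, coords.shape)
    for _ in range(max_passes):
        d = np.linalg.norm(np.diff(out, axis=0), axis=1)
        bad = np.where((d <= lo) | (d >= hi))[0]
        if len(bad) == 0:
            return out
        redraw = np.unique(np.concatenate([bad, bad + 1]))
        out[redraw] = coords[redraw] + rng.normal(0.0, sd, (len(redraw), 3))
    return out


def _trace_from_coords(coords: np.ndarray, labels: str | list,
                       rng: np.random.Generator | None = None,
                       jitter_sd: float = 0.0, chain_id: str = "A",
                       source_id: str = "SYN", start_seq: int = 1) -> tuple:
    coords = np.asarray(coords, dtype=float)
    if jitter_sd > 0:
        if rng is None:
            raise ValueError("jitter requires a seeded generator")
        coords = _apply_jitter(coords, rng, jitter_sd)
    aas = (rng.choice(len(STANDARD_AA), size=len(coords))
           if rng is not None else np.zeros(len(coords), dtype=int))
    residues = [Residue(chain_id, start_seq + i, STANDARD_AA[int(a)], xyz)
                for i, (a, xyz) in enumerate(zip(aas, coords))]
    return CaTrace(residues, source_id), LabelSequence(list(labels), "truth")


def helix_coords(n: int, radius: float = 2.3, rise: float = 1.5,
                 twist: float = 100.0) -> np.ndarray:
    """Ideal right-handed helix C-alpha positions."""
    t = np.arange(n)
    w = np.radians(twist)
    return np.stack([radius * np.cos(w * t), radius * np.sin(w * t),
                     rise * t], axis=1)


def make_helix(n: int, radius: float = 2.3, rise: float = 1.5,
               twist: float = 100.0, jitter_sd: float = 0.0,
               seed: int | None = None) -> tuple[CaTrace, LabelSequence]:
    if n < 1:
        raise ValueError("helix needs at least one residue")
    rng = np.random.default_rng(seed)
    return _trace_from_coords(helix_coords(n, radius, rise, twist), "H" * n,
                              rng, jitter_sd, source_id="SYN-helix")


def strand_coords(n: int, bond: float = 3.8, angle: float = 123.0,
                  torsion: float = 170.0, planarize: bool = False) -> np.ndarray:
    """Extended-strand coordinates, principal axis along +x.

    ``planarize`` drops the small out-of-plane component, which makes
    hairpin pairing distances exact.
    """
    if n < 2:
        return np.zeros((max(n, 1), 3))
    tor = [torsion if k % 2 == 0 else -torsion for k in range(max(0, n - 3))]
    P = build_from_internal([bond] * (n - 1), [angle] * max(0, n - 2), tor)
    P = P - P.mean(axis=0)
    # rotate principal axes onto x (chain direction) and z (pleat)
    _, _, Vt = np.linalg.svd(P, full_matrices=False)
    R = Vt  # rows: principal directions
    if np.linalg.det(R) < 0:
        R[2] = -R[2]
    P = P @ R.T
    P = P[:, [0, 2, 1]]  # x = chain axis, z = pleat, y = out-of-plane residual
    if P[-1, 0] < P[0, 0]:  # make sequence run toward +x (proper rotation)
        P[:, 0] *= -1
        P[:, 1] *= -1
    if planarize:
        P[:, 1] = 0.0
    return P - P[0]


def make_strand(n: int, jitter_sd: float = 0.0,
                seed: int | None = None) -> tuple[CaTrace, LabelSequence]:
    if n < 2:
        raise ValueError("strand needs at least two residues")
    rng = np.random.default_rng(seed)
    return _trace_from_coords(strand_coords(n), "E" * n, rng, jitter_sd,
                              source_id="SYN-strand")


def hairpin_coords(n_per_strand: int, separation: float = 4.8) -> np.ndarray:
    """Antiparallel two-strand hairpin with a two-residue turn."""
    s1 = strand_coords(n_per_strand, planarize=True)
    # mirror across the plane y = separation/2 and reverse the order
    s2 = s1.copy()
    s2[:, 1] = separation - s2[:, 1]
    s2 = s2[::-1]
    e1 = s1[-1]
    t1 = np.array([e1[0] + 3.1, 0.15 * separation, 0.0])
    t2 = np.array([e1[0] + 3.1, 0.85 * separation, 0.0])
    return np.vstack([s1, t1, t2, s2])


def make_hairpin(n_per_strand: int, separation: float = 4.8,
                 jitter_sd: float = 0.0,
                 seed: int | None = None) -> tuple[CaTrace, LabelSequence]:
    if n_per_strand < 3:
        raise ValueError("hairpin strands need at least three residues")
    rng = np.random.default_rng(seed)
    labels = "E" * n_per_strand + "LL" + "E" * n_per_strand
    return _trace_from_coords(hairpin_coords(n_per_strand, separation), labels,
                              rng, jitter_sd, source_id="SYN-hairpin")


def coil_coords(n: int, rng: np.random.Generator, min_dist: float = 3.5,
                max_tries: int = 100) -> np.ndarray:
    """Random-walk coil with self-intersection rejection."""
    best, best_min = None, -np.inf
    for _ in range(max_tries):
        angles = rng.uniform(85.0, 140.0, max(0, n - 2))
        torsions = rng.uniform(-180.0, 180.0, max(0, n - 3))
        P = build_from_internal([3.8] * (n - 1), angles, torsions)
        if n < 4:
            return P
        dm = np.linalg.norm(P[:, None] - P[None, :], axis=-1)
        iu = np.triu_indices(n, k=2)
        m = dm[iu].min()
        if m >= min_dist:
            return P
        if m > best_min:
            best, best_min = P, m
    return best


def make_coil(n: int, jitter_sd: float = 0.0,
              seed: int | None = None) -> tuple[CaTrace, LabelSequence]:
    if n < 1:
        raise ValueError("coil needs at least one residue")
    rng = np.random.default_rng(seed)
    return _trace_from_coords(coil_coords(n, rng), "L" * n, rng, jitter_sd,
                              source_id="SYN-coil")


@dataclass(frozen=True)
class SegmentSpec:
    """One secondary-structure segment of a synthetic protein."""

    kind: str                  # helix | strand | coil | hairpin
    length: int                # residues (per strand for hairpins)
    jitter_sd: float = 0.0
    geometry: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("helix", "strand", "coil", "hairpin"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.length < 1 or self.jitter_sd < 0:
            raise ValueError("length must be >= 1 and jitter_sd >= 0")


@dataclass(frozen=True)
class ProteinSpec:
    segments: tuple
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))


def _segment_coords(seg: SegmentSpec, rng: np.random.Generator):
    g = seg.geometry
    if seg.kind == "helix":
        coords = helix_coords(seg.length, g.get("radius", 2.3),
                              g.get("rise", 1.5), g.get("twist", 100.0))
        labels = "H" * seg.length
    elif seg.kind == "strand":
        coords = strand_coords(seg.length)
        labels = "E" * seg.length
    elif seg.kind == "hairpin":
        if seg.length < 3:
            raise ValueError("hairpin strands need at least three residues")
        coords = hairpin_coords(seg.length, g.get("separation", 4.8))
        labels = "E" * seg.length + "LL" + "E" * seg.length
    else:
        coords = coil_coords(seg.length, rng)
        labels = "L" * seg.length
    if seg.jitter_sd > 0:
        coords = _apply_jitter(coords, rng, seg.jitter_sd)
    return coords, labels


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from .geometry import random_rotation
    return random_rotation(rng)


def make_protein(spec: ProteinSpec) -> tuple[CaTrace, LabelSequence]:
    """Concatenate segments into one chain, keeping segments apart.

    Each new segment is rotated at random and attached at the standard
    3.8 A virtual bond in a direction pointing away from the existing
    structure; orientations are re-drawn until every inter-segment
    atom pair clears ``SEGMENT_CLEARANCE``.
    """
    rng = np.random.default_rng(spec.seed)
    all_coords: list[np.ndarray] = []
    labels: list[str] = []
    placed = None
    for seg in spec.segments:
        coords, labs = _segment_coords(seg, rng)
        coords = coords - coords[0]
        if placed is None:
            placed = coords
        else:
            tail = placed[-1]
            centroid = placed.mean(axis=0)
            away = tail - centroid
            if np.linalg.norm(away) < 1e-9:
                away = np.array([1.0, 0.0, 0.0])
            away = away / np.linalg.norm(away)
            best, best_clear = None, -np.inf
            for _ in range(100):
                R = _random_rotation(rng)
                d = away + 0.35 * rng.normal(size=3)
                d /= np.linalg.norm(d)
                cand = coords @ R.T + tail + CONNECT_BOND * d
                dmat = np.linalg.norm(placed[:, None] - cand[None, :], axis=-1)
                dmat[-1, 0] = np.inf  # the connecting bond itself
                clear = dmat.min()
                if clear >= SEGMENT_CLEARANCE:
                    best = cand
                    break
                if clear > best_clear:
                    best, best_clear = cand, clear
            placed = np.vstack([placed, best])
        labels.extend(labs)
    n = len(placed)
    aas = rng.choice(len(STANDARD_AA), size=n)
    residues = [Residue("A", i + 1, STANDARD_AA[int(a)], xyz)
                for i, (a, xyz) in enumerate(zip(aas, placed))]
    return (CaTrace(residues, f"SYN-{spec.seed:06d}"),
            LabelSequence(labels, "truth"))


def make_corpus(n_proteins: int, seed: int = 0, jitter_sd: float = 0.1,
                ) -> list[tuple[CaTrace, LabelSequence]]:
    """A reproducible corpus of multi-segment synthetic proteins.

    Every protein contains at least one helix, one strand hairpin and
    one coil segment in random order (plus an optional extra segment),
    so all three classes are represented in any split.
    """
    out = []
    master = np.random.default_rng(np.random.SeedSequence([seed, 2953]))
    for k in range(n_proteins):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        segs = [
            SegmentSpec("helix", int(rng.integers(8, 17)), jitter_sd),
            SegmentSpec("hairpin", int(rng.integers(5, 9)), jitter_sd),
            SegmentSpec("coil", int(rng.integers(5, 11)), jitter_sd),
        ]
        if rng.random() < 0.5:
            kind = ("helix", "coil")[int(rng.integers(0, 2))]
            length = int(rng.integers(8, 15) if kind == "helix"
                         else rng.integers(5, 11))
            segs.append(SegmentSpec(kind, length, jitter_sd))
        order = rng.permutation(len(segs))
        spec = ProteinSpec(tuple(segs[i] for i in order), seed=sub_seed)
        out.append(make_protein(spec))
    return out
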