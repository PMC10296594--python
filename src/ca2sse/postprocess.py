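"""Rule-based correction of predicted secondary-structure labels.

The neighborhood block of the feature vector carries five distances
(residue-to-closest-neighbor plus the four flank pairs).  Counting how
many of them fall under 6 angstrom gives a cheap compactness signal
that separates strand pairing from everything else; four rules use it
to repair the classifier's most common confusions:

1. a helix call with more than two neighbors is suspect: it becomes a
   sheet when at least three of the five distances are short, else a
   loop;
2. a loop call with more than four neighbors and more than two short
   distances becomes a sheet;
3. a loop call with fewer than three neighbors and all five distances
   short becomes a helix;
4. a single residue labeled differently from a uniform flanking group
   on both sides is flipped to the group label.

A fifth, bookkeeping rule assigns unresolved residues (chain ends the
window never covers) the label of the nearest resolved residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix, NBR_COUNT_IDX, NBR_DIST_IDX
from .trace import LabelSequence, UNRESOLVED

__all__ = ["PostprocessConfig", "postprocess"]


@dataclass(frozen=True)
class PostprocessConfig:
    dist_threshold: float = 6.0
    helix_fix_min_neighbors: int = 2      # rule 1 fires when count > this
    helix_fix_min_close: int = 3          # >= this many short -> sheet, else loop
    loop_to_sheet_min_neighbors: int = 4  # rule 2: count > this
    loop_to_sheet_min_close: int = 2      # rule 2: short count > this
    loop_to_helix_max_neighbors: int = 3  # rule 3: count < this
    loop_to_helix_close_count: int = 5    # rule 3: short count == this
    isolation_flank: int = 2              # same-label support on each side

    def __post_init__(self):
        if self.dist_threshold <= 0:
            raise ValueError("dist_threshold must be positive")


def _close_count(F: FeatureMatrix, i: int, thr: float) -> int:
    # No neighbor -> no j -> the five distances are undefined, count 0.
    if F.values[NBR_COUNT_IDX, i] < 1:
        return 0
    idx = np.array(NBR_DIST_IDX)
    ok = F.valid[idx, i]
    return int(np.sum(F.values[idx, i][ok] < thr))


def _neighborhood_flip(label: str, features: FeatureMatrix, i: int,
                       cfg: PostprocessConfig) -> str | None:
    """Label rules 1-3 would assign residue ``i`` carrying ``label``.

    Returns None when no rule fires.  The transition map has no cycles:
    whatever a rule assigns is itself stable under the rules.
    """
    if not features.valid[NBR_COUNT_IDX, i]:
        return None
    count = features.values[NBR_COUNT_IDX, i]
    close = _close_count(features, i, cfg.dist_threshold)
    if label == "H" and count > cfg.helix_fix_min_neighbors:
        return "E" if close >= cfg.helix_fix_min_close else "L"
    if label == "L":
        if (count > cfg.loop_to_sheet_min_neighbors
                and close > cfg.loop_to_sheet_min_close):
            return "E"
        if (count < cfg.loop_to_helix_max_neighbors
                and close == cfg.loop_to_helix_close_count):
            return "H"
    return None


def postprocess(labels: LabelSequence, features: FeatureMatrix,
                cfg: PostprocessConfig = PostprocessConfig()) -> LabelSequence:
    """Apply the correction rules; returns a new label sequence.

    Order: neighborhood rules 1-3, isolation rule 4, unresolved fill 5.
    Rule 4 defers to the neighborhood evidence -- a flip that rules 1-3
    would immediately revert is not applied -- and labels filled in by
    rule 5 are themselves passed through rules 1-3; together these make
    the whole step idempotent.
    """
    if len(labels) != features.n_residues:
        raise ValueError("labels and features are not aligned")
    out = list(labels)
    n = len(out)

    # rules 1-3: per-residue, driven by the neighborhood block only
    for i in range(n):
        if out[i] == UNRESOLVED:
            continue
        new = _neighborhood_flip(out[i], features, i, cfg)
        if new is not None:
            out[i] = new

    # rule 4: isolated singletons flip to the surrounding label, unless
    # the neighborhood rules disagree with the flipped label
    k = cfg.isolation_flank
    snapshot = list(out)
    for i in range(n):
        lab = snapshot[i]
        if lab == UNRESOLVED:
            continue
        left = snapshot[max(0, i - k):i]
        right = snapshot[i + 1:i + 1 + k]
        if (len(left) == k and len(right) == k
                and len(set(left)) == 1 and set(left) == set(right)
                and left[0] != lab and left[0] != UNRESOLVED
                and _neighborhood_flip(left[0], features, i, cfg) is None):
            out[i] = left[0]

    # rule 5: unresolved residues inherit the nearest resolved label
    # (ties -> left) and are then subject to rules 1-3 themselves
    resolved = [i for i in range(n) if out[i] != UNRESOLVED]
    if resolved:
        for i in range(n):
            if out[i] == UNRESOLVED:
                j = min(resolved, key=lambda r: (abs(r - i), r))
                out[i] = out[j]
                new = _neighborhood_flip(out[i], features, i, cfg)
                if new is not None:
                    out[i] = new

    return LabelSequence(out, provenance="postprocessed")
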