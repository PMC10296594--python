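"""C-alpha traces, 3-state labels, and PDB / TSV input-output.

A :class:`CaTrace` is the ordered list of C-alpha positions of one
protein chain.  Ground-truth secondary structure comes from the HELIX
and SHEET records of the same PDB file, collapsed to the 3-state
alphabet H (helix), E (sheet/strand), L (loop, everything else).

Chains are cleaned the way redundancy-culled training corpora usually
are: insertion codes, non-standard amino acids and residues without a
C-alpha atom all reject the chain (a ``lenient`` mode downgrades the
rejection to a per-residue skip and flags the trace as broken).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "STANDARD_AA",
    "AA_INDEX",
    "Residue",
    "CaTrace",
    "LabelSequence",
    "ChainRejectionError",
    "read_ca_trace",
    "read_sse_labels",
    "write_predictions",
    "read_predictions",
    "write_ca_pdb",
]

#: The 20 standard amino acids, alphabetical by 3-letter code.  The
#: position in this tuple is the numeric amino-acid-type feature.
STANDARD_AA = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

LABELS = ("H", "E", "L")
UNRESOLVED = "U"

#: Plausible consecutive C-alpha / C-alpha distance range (angstrom).
#: Anything outside marks a chain break.
CA_CA_MIN, CA_CA_MAX = 2.0, 4.5


class ChainRejectionError(ValueError):
    """A chain failed one of the cleaning rules.

    ``reason`` is a stable code: ``missing-chain``, ``insertion-code``,
    ``unknown-residue`` or ``missing-CA``.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class Residue:
    chain_id: str
    seq_num: int
    aa_code: str
    ca_xyz: np.ndarray

    def __post_init__(self):
        xyz = np.asarray(self.ca_xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError("ca_xyz must be a finite 3-vector")
        object.__setattr__(self, "ca_xyz", xyz)
        if self.aa_code not in AA_INDEX:
            raise ValueError(f"non-standard amino acid {self.aa_code!r}")


@dataclass
class CaTrace:
    """Ordered C-alpha trace of one chain."""

    residues: list[Residue]
    source_id: str = ""
    #: bond indices i such that the (i, i+1) link is a chain break;
    #: None -> detect from seq_num gaps and implausible CA-CA distances
    break_after: frozenset | None = None

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("CaTrace needs at least one residue")
        seq = self.seq_nums
        if np.any(np.diff(seq) <= 0):
            raise ValueError("seq_num must be strictly increasing")
        if self.break_after is None:
            self.break_after = _detect_breaks(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.ca_xyz for r in self.residues])

    @property
    def seq_nums(self) -> np.ndarray:
        return np.array([r.seq_num for r in self.residues])

    @property
    def has_break(self) -> bool:
        return len(self.break_after) > 0

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "CaTrace":
        """Rigidly moved copy of the trace (rotation then translation)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        res = [Residue(r.chain_id, r.seq_num, r.aa_code, R @ r.ca_xyz + t)
               for r in self.residues]
        return CaTrace(res, self.source_id, self.break_after)


@dataclass
class LabelSequence:
    """Per-residue 3-state labels aligned 1:1 with a trace."""

    labels: list[str]
    provenance: str = "truth"

    def __post_init__(self):
        bad = set(self.labels) - set(LABELS) - {UNRESOLVED}
        if bad:
            raise ValueError(f"unknown labels {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __getitem__(self, i):
        return self.labels[i]


def _detect_breaks(residues: list[Residue]) -> frozenset:
    breaks = set()
    for i in range(len(residues) - 1):
        a, b = residues[i], residues[i + 1]
        d = float(np.linalg.norm(a.ca_xyz - b.ca_xyz))
        if b.seq_num != a.seq_num + 1 or not (CA_CA_MIN < d < CA_CA_MAX):
            breaks.add(i)
    return frozenset(breaks)


def _pick_ca(res: gemmi.Residue):
    """Resolve altlocs: prefer '' or 'A', else highest occupancy, tie first."""
    cas = [a for a in res if a.name == "CA"]
    if not cas:
        return None
    for a in cas:
        if a.altloc in ("", "\x00", "A"):
            return a
    return max(cas, key=lambda a: a.occ)  # max keeps the first on ties


def read_ca_trace(pdb_text: str, chain_id: str, lenient: bool = False) -> CaTrace:
    """Parse the C-alpha trace of one chain from PDB-format text.

    Only ATOM records of the first model are used; HETATM entries are
    ignored.  Cleaning rules (insertion code, non-standard residue,
    missing CA) reject the whole chain unless ``lenient`` is set, in
    which case offending residues are skipped with a warning and the
    break bookkeeping marks the gap.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ChainRejectionError("missing-chain", "no models in file")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainRejectionError("missing-chain", chain_id)

    source = (st.name or "????").strip() or "????"
    residues: list[Residue] = []
    for res in chain:
        if res.het_flag != "A":  # HETATM (waters, ligands, modified HET)
            continue
        if res.seqid.icode not in (" ", "\x00", ""):
            if lenient:
                logger.warning("%s/%s: skipping residue %s%s (insertion code)",
                               source, chain_id, res.seqid.num, res.seqid.icode)
                continue
            raise ChainRejectionError("insertion-code",
                                      f"residue {res.seqid.num}{res.seqid.icode}")
        if res.name not in AA_INDEX:
            if lenient:
                logger.warning("%s/%s: skipping non-standard residue %s %d",
                               source, chain_id, res.name, res.seqid.num)
                continue
            raise ChainRejectionError("unknown-residue",
                                      f"{res.name} {res.seqid.num}")
        ca = _pick_ca(res)
        if ca is None:
            if lenient:
                logger.warning("%s/%s: residue %d has no CA atom, skipped",
                               source, chain_id, res.seqid.num)
                continue
            raise ChainRejectionError("missing-CA", f"residue {res.seqid.num}")
        residues.append(Residue(chain_id, res.seqid.num, res.name,
                                np.array([ca.pos.x, ca.pos.y, ca.pos.z])))
    if not residues:
        raise ChainRejectionError("missing-chain",
                                  f"chain {chain_id} has no usable residues")
    return CaTrace(residues, f"{source}_{chain_id}", _detect_breaks(residues))


def read_sse_labels(pdb_text: str, trace: CaTrace) -> LabelSequence:
    """3-state truth labels from the HELIX/SHEET records of a PDB file.

    Residues covered by a HELIX record (any helix class) become H, by a
    SHEET record E, everything else L.  On overlap HELIX wins.  Ranges
    pointing at residues absent from the trace are an error.
    """
    st = gemmi.read_pdb_string(pdb_text)
    chain_id = trace.residues[0].chain_id
    seq_to_idx = {r.seq_num: i for i, r in enumerate(trace.residues)}
    labels = ["L"] * len(trace)

    def fill(start_seq: int, end_seq: int, lab: str, what: str):
        for s in range(start_seq, end_seq + 1):
            if s not in seq_to_idx:
                raise ValueError(
                    f"{what} record spans residue {s} absent from trace "
                    f"{trace.source_id}")
            if lab == "H" and labels[seq_to_idx[s]] == "E":
                logger.warning("HELIX/SHEET overlap at residue %d; HELIX wins", s)
            labels[seq_to_idx[s]] = lab

    for sheet in st.sheets:
        for strand in sheet.strands:
            if strand.start.chain_name != chain_id:
                continue
            fill(strand.start.res_id.seqid.num, strand.end.res_id.seqid.num,
                 "E", "SHEET")
    for helix in st.helices:  # after sheets so HELIX takes precedence
        if helix.start.chain_name != chain_id:
            continue
        fill(helix.start.res_id.seqid.num, helix.end.res_id.seqid.num,
             "H", "HELIX")
    return LabelSequence(labels, provenance="truth")


PRED_HEADER = ("source_id", "chain", "seq_num", "aa_code", "label")


def write_predictions(trace: CaTrace, labels: LabelSequence, sink=None) -> str:
    """Write per-residue predictions as TSV; returns the text."""
    if len(trace) != len(labels):
        raise ValueError("trace and labels have different lengths")
    buf = io.StringIO()
    buf.write("\t".join(PRED_HEADER) + "\n")
    for res, lab in zip(trace.residues, labels):
        buf.write(f"{trace.source_id}\t{res.chain_id}\t{res.seq_num}\t"
                  f"{res.aa_code}\t{lab}\n")
    text = buf.getvalue()
    if sink is not None:
        sink.write(text)
    return text


def read_predictions(text: str) -> LabelSequence:
    """Inverse of :func:`write_predictions` (labels only)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != list(PRED_HEADER):
        raise ValueError("not a prediction TSV (bad header)")
    labels = [ln.split("\t")[4] for ln in lines[1:]]
    return LabelSequence(labels, provenance="model1") if labels else \
        LabelSequence([], provenance="model1")


# -- minimal PDB writer (used by the synthetic generator and the CLI) -------

_ATOM_FMT = ("ATOM  {serial:5d}  CA  {res:3s} {chain:1s}{seq:4d}    "
             "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
             " C\n")
_HELIX_FMT = ("HELIX  {ser:3d} {ser:3d} {r1:3s} {ch:1s} {s1:4d}  {r2:3s} "
              "{ch:1s} {s2:4d}  1{pad:30s}{ln:5d}\n")
_SHEET_FMT = ("SHEET  {ser:3d} {sid:>3s} 1 {r1:3s} {ch:1s}{s1:4d}  {r2:3s} "
              "{ch:1s}{s2:4d}  0\n")


def _label_runs(labels) -> list[tuple[str, int, int]]:
    runs = []
    start = 0
    labs = list(labels)
    for i in range(1, len(labs) + 1):
        if i == len(labs) or labs[i] != labs[start]:
            runs.append((labs[start], start, i - 1))
            start = i
    return runs


def write_ca_pdb(trace: CaTrace, labels: LabelSequence | None = None) -> str:
    """Render a CA-only PDB file, with HELIX/SHEET records from labels.

    The output is column-exact wwPDB v3.3 and round-trips through
    :func:`read_ca_trace` / :func:`read_sse_labels`.
    """
    if labels is not None and len(labels) != len(trace):
        raise ValueError("trace and labels have different lengths")
    out = io.StringIO()
    if labels is not None:
        hser = eser = 0
        for lab, lo, hi in _label_runs(labels):
            a, b = trace.residues[lo], trace.residues[hi]
            if lab == "H":
                hser += 1
                out.write(_HELIX_FMT.format(ser=hser, r1=a.aa_code, r2=b.aa_code,
                                            ch=a.chain_id, s1=a.seq_num,
                                            s2=b.seq_num, pad="", ln=hi - lo + 1))
            elif lab == "E":
                eser += 1
                out.write(_SHEET_FMT.format(ser=1, sid=chr(ord("A") + (eser - 1) % 26),
                                            r1=a.aa_code, r2=b.aa_code,
                                            ch=a.chain_id, s1=a.seq_num,
                                            s2=b.seq_num))
    for i, r in enumerate(trace.residues, 1):
        x, y, z = r.ca_xyz
        out.write(_ATOM_FMT.format(serial=i, res=r.aa_code, chain=r.chain_id,
                                   seq=r.seq_num, x=x, y=y, z=z, occ=1.0, b=0.0))
    out.write("END\n")
    return out.getvalue()
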