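"""Pairwise global alignment, percent identity, and conservation mapping.

Percent identity between transporter sequences is computed from a global
(Needleman–Wunsch) alignment under BLOSUM62 with affine gaps (open 10,
extend 0.5), the scoring a practitioner would use for diverged orthologs.
Identity is counted over mutually aligned columns — positions where both
sequences contribute a residue — so terminal overhangs do not dilute it.

Conservation mapping reports, for residues of interest in the reference
numbering (full-length rat transcobalamin), which residue each homolog
aligns at that position and whether it is identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignedPair",
    "global_align",
    "percent_identity",
    "map_conservation",
    "read_fasta",
    "write_fasta",
]

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYXBZJUO]+$")

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


@dataclass
class AlignedPair:
    """A pairwise global alignment with gap characters ('-')."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    def columns(self):
        return zip(self.aligned_a, self.aligned_b)


def _check_sequence(seq: str, name: str) -> str:
    seq = seq.upper().replace("*", "")
    if not seq:
        raise ValueError(f"sequence {name!r} is empty")
    if not _AA_RE.match(seq):
        bad = sorted({c for c in seq if not _AA_RE.match(c)})
        raise ValueError(f"sequence {name!r} contains illegal characters {bad}")
    return seq


def global_align(
    a: str,
    b: str,
    substitution: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    id_a: str = "a",
    id_b: str = "b",
) -> AlignedPair:
    """Optimal global alignment of two protein sequences.

    ``gap_open``/``gap_extend`` are positive penalties; the first gap
    position costs ``gap_open`` and each further position ``gap_extend``.
    The traceback is deterministic (the aligner's first optimal path).
    """
    sa = _check_sequence(a, id_a)
    sb = _check_sequence(b, id_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution)
    aligner.open_gap_score = -(gap_open)
    aligner.extend_gap_score = -(gap_extend)
    alignment = aligner.align(sa, sb)[0]
    ga, gb = _gapped_from_alignment(alignment, sa, sb)
    return AlignedPair(id_a=id_a, id_b=id_b, aligned_a=ga, aligned_b=gb,
                       score=float(alignment.score))


def _gapped_from_alignment(alignment, sa: str, sb: str) -> tuple[str, str]:
    # rebuild gapped rows from the alignment coordinate path (robust to
    # biopython's string-layout changes)
    coords = alignment.coordinates
    ga: list[str] = []
    gb: list[str] = []
    for k in range(coords.shape[1] - 1):
        a0, a1 = int(coords[0][k]), int(coords[0][k + 1])
        b0, b1 = int(coords[1][k]), int(coords[1][k + 1])
        da, db = a1 - a0, b1 - b0
        if da and db:
            ga.append(sa[a0:a1])
            gb.append(sb[b0:b1])
        elif da:
            ga.append(sa[a0:a1])
            gb.append("-" * da)
        elif db:
            ga.append("-" * db)
            gb.append(sb[b0:b1])
    return "".join(ga), "".join(gb)


def percent_identity(pair: AlignedPair) -> float:
    """Identical columns / mutually aligned columns × 100.

    Terminal gap columns never enter the denominator (they are not mutually
    aligned); raises when no column has residues from both sequences.
    """
    both = [(x, y) for x, y in pair.columns() if x != "-" and y != "-"]
    if not both:
        raise ValueError("alignment has no mutually aligned columns; identity undefined")
    same = sum(1 for x, y in both if x == y)
    return 100.0 * same / len(both)


def map_conservation(
    reference_id: str,
    reference_seq: str,
    homologs: dict[str, str],
    residues: list[int],
    **align_kwargs,
) -> list[dict]:
    """Conservation of selected reference residues across homologs.

    ``residues`` are 1-based positions in the (full-length) reference
    sequence. Returns one row per residue with the reference amino acid, the
    aligned amino acid in each homolog ('-' for a gap), and a ``conserved``
    flag that is true only when every homolog shows the identical residue.
    """
    ref = _check_sequence(reference_seq, reference_id)
    for pos in residues:
        if not 1 <= pos <= len(ref):
            raise ValueError(f"residue {pos} outside reference length {len(ref)}")

    per_homolog: dict[str, dict[int, str]] = {}
    for hid, hseq in homologs.items():
        pair = global_align(ref, hseq, id_a=reference_id, id_b=hid, **align_kwargs)
        mapping: dict[int, str] = {}
        ref_pos = 0
        for x, y in pair.columns():
            if x != "-":
                ref_pos += 1
                mapping[ref_pos] = y
        per_homolog[hid] = mapping

    rows = []
    for pos in residues:
        aligned = {hid: per_homolog[hid].get(pos, "-") for hid in homologs}
        rows.append(
            {
                "residue": pos,
                "reference_aa": ref[pos - 1],
                "aligned": aligned,
                "conserved": all(aa == ref[pos - 1] for aa in aligned.values()),
            }
        )
    return rows


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Sequences from a FASTA file, keyed by the first word of each header."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
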