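"""Orientation-resolved alignment of amplicon reads to the reference.

Reads may arrive in either orientation (merged paired-end data is emulated
as orientation-mixed single-end reads), so each read is scored against the
reference in both orientations and the better one is kept. Alignments
below the identity threshold (default 80% over aligned columns) are
rejected and tallied as alignment failures.

Two routes produce the same per-reference-column representation:

* a fast ungapped route for reads whose length equals the reference
  (the common case for full-amplicon reads with substitution-only error);
* an affine-gap dynamic-programming route (Bio.Align.PairwiseAligner,
  match +2 / mismatch -1 / gap open -5 / gap extend -1, free end gaps)
  for everything else, including reads the fast route cannot place.

In the DP route, reference columns adjacent (within 1) to an indel are
masked to 'N' so that alignment ambiguity around gaps cannot create false
A>G calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .reference import AmpliconReference
from .sequtil import bytes_to_seq, complement_bytes, revcomp, seq_to_bytes

MATCH_SCORE = 2
MISMATCH_SCORE = -1
GAP_OPEN = -5
GAP_EXTEND = -1
DEFAULT_MIN_IDENTITY = 0.8


@dataclass
class AlignedRead:
    """A read projected onto reference coordinates.

    ``bases`` has exactly one character per reference position: the aligned
    read base, 'N' for a masked base (low quality or gap-adjacent), or '-'
    for a gap / uncovered position.
    """

    id: str
    bases: str
    orientation: str  # '+' or '-'
    identity: float


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # free end gaps: reads may cover only part of the amplicon
    new_attrs = (
        "open_end_insertion_score",
        "extend_end_insertion_score",
        "open_end_deletion_score",
        "extend_end_deletion_score",
    )
    old_attrs = (
        "target_end_open_gap_score",
        "target_end_extend_gap_score",
        "query_end_open_gap_score",
        "query_end_extend_gap_score",
    )
    attrs = new_attrs if hasattr(aligner, new_attrs[0]) else old_attrs
    for attr in attrs:
        setattr(aligner, attr, 0.0)
    return aligner


_ALIGNER = make_aligner()


def _ungapped_identity(read: np.ndarray, ref: np.ndarray) -> float:
    informative = read != b"N"
    n = int(informative.sum())
    if n == 0:
        return 0.0
    return float((informative & (read == ref)).sum() / n)


def _project_dp(ref_seq: str, read_seq: str):
    """Align one read (one orientation) and project it onto ref columns."""
    aln = _ALIGNER.align(ref_seq, read_seq)[0]
    ref_blocks, read_blocks = aln.aligned
    L = len(ref_seq)
    out = np.full(L, b"-", dtype="S1")
    read_bytes = seq_to_bytes(read_seq)
    for (ts, te), (qs, qe) in zip(ref_blocks, read_blocks):
        out[ts:te] = read_bytes[qs:qe]
    if len(ref_blocks) == 0:
        return out, 0.0, aln.score

    mask_at = set()
    cstart, cend = int(ref_blocks[0][0]), int(ref_blocks[-1][1])
    # deletion columns: '-' inside the covered span; mask flanks
    for pos in range(cstart, cend):
        if out[pos] == b"-":
            mask_at.update((pos - 1, pos + 1))
    # insertion junctions: query jumps while target is contiguous
    for k in range(1, len(ref_blocks)):
        if ref_blocks[k][0] == ref_blocks[k - 1][1]:
            mask_at.update((int(ref_blocks[k][0]) - 1, int(ref_blocks[k][0])))
    for pos in mask_at:
        if cstart <= pos < cend and out[pos] != b"-":
            out[pos] = b"N"

    ref_bytes = seq_to_bytes(ref_seq)
    span = out[cstart:cend]
    informative = (span != b"-") & (span != b"N")
    n = int(informative.sum())
    identity = float((informative & (span == ref_bytes[cstart:cend])).sum() / n) if n else 0.0
    return out, identity, aln.score


def align_read(
    read,
    ref: AmpliconReference,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> AlignedRead | None:
    """Align one read in its better orientation; None if identity < threshold.

    ``read`` is a :class:`~amped.simulate.ReadRecord` or a plain sequence
    string (quality masking, if any, must already be applied as 'N').
    """
    rid = getattr(read, "id", "read")
    seq = getattr(read, "bases", read)
    if not seq:
        return None
    L = len(ref)

    if len(seq) == L:
        fwd = seq_to_bytes(seq)
        rev = complement_bytes(fwd)[::-1]
        refb = seq_to_bytes(ref.sequence)
        id_f = _ungapped_identity(fwd, refb)
        id_r = _ungapped_identity(rev, refb)
        if max(id_f, id_r) >= min_identity:
            if id_r > id_f:
                return AlignedRead(rid, bytes_to_seq(rev), "-", id_r)
            return AlignedRead(rid, seq, "+", id_f)
        # fall through: an indel can wreck ungapped identity; let DP decide

    out_f, id_f, score_f = _project_dp(ref.sequence, seq)
    out_r, id_r, score_r = _project_dp(ref.sequence, revcomp(seq))
    if score_r > score_f:
        out, identity, orientation = out_r, id_r, "-"
    else:
        out, identity, orientation = out_f, id_f, "+"
    if identity < min_identity:
        return None
    return AlignedRead(rid, bytes_to_seq(out), orientation, identity)
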