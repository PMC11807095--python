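"""Amplicon reference sequences.

The unit of analysis is a short (~200 bp) amplicon of the mutant allele on
the sense strand, carrying a G>A premature-stop mutation. The transcript
adenosine created by that mutation is the editing target; all other
reference adenosines are potential bystander-editing sites. Coordinates are
0-based half-open throughout; site labels ``A_k`` are 1-based ordinals over
the sense-strand adenosines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class AmpliconReference:
    """A sense-strand mutant-allele amplicon with its editing target annotated.

    Parameters
    ----------
    name : str
        Amplicon identifier.
    sequence : str
        Uppercase DNA (A/C/G/T only).
    target_index : int
        0-based offset of the editable adenosine; the base there must be 'A'.
    guide_window : tuple of int
        Half-open interval ``[start, end)`` covered by the gRNA duplex;
        must contain ``target_index``.
    """

    name: str
    sequence: str
    target_index: int
    guide_window: tuple[int, int]
    adenosine_positions: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq or set(seq) - _VALID:
            bad = sorted(set(seq) - _VALID)
            raise ValueError(f"sequence must be non-empty A/C/G/T; found {bad}")
        if not 0 <= self.target_index < len(seq):
            raise ValueError(
                f"target_index {self.target_index} outside [0, {len(seq)})"
            )
        if seq[self.target_index] != "A":
            raise ValueError(
                f"base at target_index {self.target_index} is "
                f"{seq[self.target_index]!r}, expected 'A'"
            )
        start, end = self.guide_window
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"guide_window [{start}, {end}) does not fit in [0, {len(seq)})"
            )
        if not start <= self.target_index < end:
            raise ValueError(
                f"target_index {self.target_index} not inside guide_window "
                f"[{start}, {end})"
            )
        positions = tuple(i for i, b in enumerate(seq) if b == "A")
        object.__setattr__(self, "adenosine_positions", positions)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def window_adenosines(self) -> tuple[int, ...]:
        """Adenosine positions that fall inside the gRNA duplex window."""
        start, end = self.guide_window
        return tuple(p for p in self.adenosine_positions if start <= p < end)

    def site_label(self, position: int) -> str:
        """1-based ordinal label ``A_k`` of a reference adenosine."""
        try:
            k = self.adenosine_positions.index(position)
        except ValueError:
            raise ValueError(f"position {position} is not a reference adenosine")
        return f"A_{k + 1}"

    def to_fasta(self, path) -> None:
        start, end = self.guide_window
        rec = SeqRecord(
            Seq(self.sequence),
            id=self.name,
            description=f"target_index={self.target_index} guide_window={start}-{end}",
        )
        SeqIO.write([rec], str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "AmpliconReference":
        rec = SeqIO.read(str(path), "fasta")
        desc = rec.description
        m_t = re.search(r"target_index=(\d+)", desc)
        m_w = re.search(r"guide_window=(\d+)-(\d+)", desc)
        if m_t is None or m_w is None:
            raise ValueError(
                f"{path}: FASTA header must carry 'target_index=<i>' and "
                "'guide_window=<start>-<end>' annotations"
            )
        return cls(
            name=rec.id,
            sequence=str(rec.seq).upper(),
            target_index=int(m_t.group(1)),
            guide_window=(int(m_w.group(1)), int(m_w.group(2))),
        )


def make_reference(
    length: int = 200,
    target_offset: int = 100,
    guide_span: int = 50,
    seed: int = 0,
    name: str | None = None,
) -> AmpliconReference:
    """Generate a random-composition amplicon with a forced target adenosine.

    The guide window is centred on the target. Deterministic under ``seed``.
    """
    if not 0 <= target_offset < length:
        raise ValueError(f"target_offset {target_offset} outside [0, {length})")
    start = target_offset - guide_span // 2
    end = start + guide_span
    if start < 0 or end > length:
        raise ValueError(
            f"guide window [{start}, {end}) (span {guide_span} centred on "
            f"{target_offset}) does not fit in [0, {length})"
        )
    rng = np.random.default_rng(seed)
    bases = rng.choice(list("ACGT"), size=length)
    bases[target_offset] = "A"
    return AmpliconReference(
        name=name or f"amplicon-{seed}",
        sequence="".join(bases),
        target_index=target_offset,
        guide_window=(start, end),
    )
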