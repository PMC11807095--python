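"""Per-adenosine A>G allele counting from amplicon reads.

The pipeline is: quality filtering (reads with mean Phred <= 30 discarded;
individual bases with Phred <= 20 masked rather than discarding the read),
orientation-resolved alignment to the sense-strand reference, then a
per-adenosine tally of aligned bases into A / G / other / masked classes.
The editing rate at a site is r = n_G / (n_A + n_G); non-A/G bases are
excluded from the denominator, and masked or gap(-adjacent) columns are
excluded from everything but the masked tally. Thresholds use strict
inequalities ("quality > 30", "> 20") and the arithmetic mean of Phred
values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import DEFAULT_MIN_IDENTITY, AlignedRead, align_read
from .reference import AmpliconReference
from .sequtil import complement_bytes, seq_to_bytes
from .simulate import ReadRecord, read_fastq

DEFAULT_MIN_AVG_Q = 30
DEFAULT_MIN_BASE_Q = 20


@dataclass
class FilterReport:
    """Read-level accounting for one sample; every input read is classified."""

    n_input: int = 0
    n_fail_avg_quality: int = 0
    n_fail_alignment: int = 0
    n_analyzed: int = 0
    bases_masked: int = 0

    def __post_init__(self) -> None:
        total = self.n_fail_avg_quality + self.n_fail_alignment + self.n_analyzed
        if total != self.n_input:
            raise ValueError(
                f"report does not balance: {self.n_input} input != "
                f"{self.n_fail_avg_quality} + {self.n_fail_alignment} + {self.n_analyzed}"
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def filter_reads(
    reads: Sequence[ReadRecord],
    min_avg_q: float = DEFAULT_MIN_AVG_Q,
    min_base_q: int = DEFAULT_MIN_BASE_Q,
) -> tuple[list[ReadRecord], FilterReport]:
    """Discard low-mean-quality reads and mask individual low-quality bases.

    Returned reads carry 'N' at masked positions. The report's alignment
    tally is zero at this stage (filled in by :func:`quantify_sample`).
    """
    kept: list[ReadRecord] = []
    n_fail = 0
    masked = 0
    for r in reads:
        if len(r) == 0 or r.quals.mean() <= min_avg_q:
            n_fail += 1
            continue
        low = r.quals <= min_base_q
        if low.any():
            arr = seq_to_bytes(r.bases).copy()
            arr[low] = b"N"
            masked += int(low.sum())
            r = ReadRecord(id=r.id, bases=arr.tobytes().decode(), quals=r.quals)
        kept.append(r)
    report = FilterReport(
        n_input=len(reads),
        n_fail_avg_quality=n_fail,
        n_analyzed=len(kept),
        bases_masked=masked,
    )
    return kept, report


class AlignmentSet:
    """Reads projected onto reference columns, stored as an (n, L) byte matrix.

    Each row is one retained read: aligned base, 'N' (masked) or '-' (gap /
    uncovered). Rows from the ungapped fast route and the DP route are
    interchangeable.
    """

    def __init__(self, matrix: np.ndarray, ids: list[str], orientations: np.ndarray):
        self.matrix = matrix
        self.ids = ids
        self.orientations = orientations

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def __iter__(self):
        for i in range(len(self)):
            yield AlignedRead(
                id=self.ids[i],
                bases=self.matrix[i].tobytes().decode(),
                orientation=self.orientations[i],
                identity=float("nan"),
            )

    @classmethod
    def from_aligned(cls, aligned: Iterable[AlignedRead]) -> "AlignmentSet":
        aligned = list(aligned)
        if not aligned:
            return cls(np.empty((0, 0), dtype="S1"), [], np.empty(0, dtype="U1"))
        matrix = np.stack([seq_to_bytes(a.bases) for a in aligned])
        return cls(
            matrix,
            [a.id for a in aligned],
            np.array([a.orientation for a in aligned], dtype="U1"),
        )


def align_sample(
    reads: Sequence[ReadRecord],
    ref: AmpliconReference,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[AlignmentSet, int]:
    """Align filtered reads; returns the alignment set and the failure count.

    Full-length reads take a vectorised ungapped route; reads it cannot
    place (and reads of other lengths) fall back to affine-gap DP.
    """
    L = len(ref)
    full = [i for i, r in enumerate(reads) if len(r) == L]
    other = [i for i, r in enumerate(reads) if len(r) != L]

    results: dict[int, AlignedRead] = {}
    need_dp = list(other)

    if full:
        mat = np.stack([seq_to_bytes(reads[i].bases) for i in full])
        refb = seq_to_bytes(ref.sequence)
        informative = mat != b"N"
        denom = informative.sum(axis=1)
        denom_safe = np.maximum(denom, 1)
        id_f = (informative & (mat == refb)).sum(axis=1) / denom_safe
        rc = complement_bytes(mat)[:, ::-1]
        id_r = ((rc != b"N") & (rc == refb)).sum(axis=1) / denom_safe
        use_rev = id_r > id_f
        best = np.where(use_rev, id_r, id_f)
        ok = (best >= min_identity) & (denom > 0)
        for k, i in enumerate(full):
            if ok[k]:
                row = rc[k] if use_rev[k] else mat[k]
                results[i] = AlignedRead(
                    id=reads[i].id,
                    bases=row.tobytes().decode(),
                    orientation="-" if use_rev[k] else "+",
                    identity=float(best[k]),
                )
            else:
                need_dp.append(i)

    n_fail = 0
    for i in need_dp:
        aligned = align_read(reads[i], ref, min_identity=min_identity)
        if aligned is None:
            n_fail += 1
        else:
            results[i] = aligned
    ordered = [results[i] for i in sorted(results)]
    return AlignmentSet.from_aligned(ordered), n_fail


@dataclass
class SiteCountTable:
    """Per-adenosine allele counts and editing rates for one sample.

    ``counts`` is indexed by 0-based reference position with columns
    ``label`` (A_k), ``n_A``, ``n_G``, ``n_other``, ``n_masked``, ``depth``
    and ``rate``; ``rate`` is NaN where no A or G base was observed.
    """

    sample_id: str
    counts: pd.DataFrame

    @property
    def rates(self) -> pd.Series:
        return self.counts["rate"]

    def rate_at(self, position: int) -> float:
        return float(self.counts.loc[position, "rate"])

    def to_tsv(self, path) -> None:
        out = self.counts.reset_index().rename(columns={"index": "position"})
        out.insert(0, "sample_id", self.sample_id)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "SiteCountTable":
        df = pd.read_csv(path, sep="\t")
        sample_id = str(df["sample_id"].iloc[0]) if len(df) else Path(path).stem
        df = df.drop(columns=["sample_id"]).set_index("position")
        return cls(sample_id=sample_id, counts=df)


def count_alleles(
    alignments: AlignmentSet | Iterable[AlignedRead],
    ref: AmpliconReference,
    sample_id: str = "sample",
) -> SiteCountTable:
    """Tally aligned bases at every reference adenosine."""
    if not isinstance(alignments, AlignmentSet):
        alignments = AlignmentSet.from_aligned(alignments)
    positions = list(ref.adenosine_positions)
    if len(alignments) == 0:
        cols = np.zeros(len(positions), dtype=int)
        df = pd.DataFrame(
            {
                "label": [ref.site_label(p) for p in positions],
                "n_A": cols,
                "n_G": cols,
                "n_other": cols,
                "n_masked": cols,
            },
            index=positions,
        )
    else:
        sub = alignments.matrix[:, positions]
        n_a = (sub == b"A").sum(axis=0)
        n_g = (sub == b"G").sum(axis=0)
        n_masked = ((sub == b"N") | (sub == b"-")).sum(axis=0)
        n_other = sub.shape[0] - n_a - n_g - n_masked
        df = pd.DataFrame(
            {
                "label": [ref.site_label(p) for p in positions],
                "n_A": n_a,
                "n_G": n_g,
                "n_other": n_other,
                "n_masked": n_masked,
            },
            index=positions,
        )
    df["depth"] = df["n_A"] + df["n_G"] + df["n_other"]
    denom = (df["n_A"] + df["n_G"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["rate"] = np.where(denom > 0, df["n_G"] / np.where(denom > 0, denom, 1), np.nan)
    df.index.name = "position"
    return SiteCountTable(sample_id=sample_id, counts=df)


def quantify_sample(
    source,
    ref: AmpliconReference,
    min_avg_q: float = DEFAULT_MIN_AVG_Q,
    min_base_q: int = DEFAULT_MIN_BASE_Q,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    sample_id: str | None = None,
) -> tuple[SiteCountTable, FilterReport]:
    """FASTQ (path) or read list -> per-adenosine counts plus filter report."""
    if isinstance(source, (str, Path)):
        reads = read_fastq(source)
        sample_id = sample_id or Path(source).stem
    else:
        reads = list(source)
        sample_id = sample_id or "sample"
    kept, report = filter_reads(reads, min_avg_q=min_avg_q, min_base_q=min_base_q)
    alignments, n_fail = align_sample(kept, ref, min_identity=min_identity)
    final = FilterReport(
        n_input=report.n_input,
        n_fail_avg_quality=report.n_fail_avg_quality,
        n_fail_alignment=n_fail,
        n_analyzed=len(alignments),
        bases_masked=report.bases_masked,
    )
    table = count_alleles(alignments, ref, sample_id=sample_id)
    return table, final
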