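"""Cas13 gRNA spacer tiling across a G>A editing target.

A spacer is the reverse complement of a window of the sense-strand target,
except that the base pairing opposite the target adenosine is set to 'C' to
form the A-C mismatch that directs ADAR deamination. Guides in a tiling
series differ by their *mismatch distance* d: the number of spacer
nucleotides from the mismatched base to the scaffold-proximal spacer end,
counted inclusively (a mismatch at the terminal base has d = 1). The
direct-repeat scaffold is appended 3' of the spacer by default; its
sequence and side are supplied per orthologue via a scaffold table, since
they differ among Cas13 families.

Guides are emitted as DNA (cloning-oligo sense); use
:func:`amped.sequtil.to_rna` for the RNA form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .reference import AmpliconReference
from .sequtil import revcomp, to_rna

ORTHOLOGUES = ("PspCas13b", "PspCas13b-del", "Cas13bt1", "Cas13bt3", "Cas13bt5")
SPACER_LENGTHS = (30, 50)
MIN_NONTARGETING_MATCH = 15


@dataclass(frozen=True)
class GuideRNA:
    """A tiled Cas13 spacer with its A-C mismatch geometry."""

    name: str
    spacer: str
    mismatch_distance: int | None
    orthologue: str
    window: tuple[int, int] | None = None  # reference coords covered
    has_direct_repeat: bool = False
    full_sequence: str | None = None

    @property
    def spacer_length(self) -> int:
        return len(self.spacer)

    @property
    def spacer_rna(self) -> str:
        return to_rna(self.spacer)


def _build_spacer(ref: AmpliconReference, spacer_length: int, d: int) -> tuple[str, tuple[int, int]]:
    """Spacer with the mismatch at distance d from the 3' (scaffold) end."""
    t = ref.target_index
    w_start = t - d + 1
    w_end = w_start + spacer_length
    if w_start < 0 or w_end > len(ref):
        raise ValueError(
            f"d={d}: window [{w_start}, {w_end}) overruns reference "
            f"[0, {len(ref)})"
        )
    window_seq = ref.sequence[w_start:w_end]
    spacer = list(revcomp(window_seq))
    # spacer index of the base opposite the target adenosine
    i = spacer_length - d
    assert spacer[i] == "T", "complement of target A must be T before mismatching"
    spacer[i] = "C"
    return "".join(spacer), (w_start, w_end)


def tile_guides(
    ref: AmpliconReference,
    spacer_length: int = 50,
    d_min: int = 18,
    d_max: int = 42,
    step: int = 6,
    orthologue: str = "PspCas13b",
) -> list[GuideRNA]:
    """One guide per mismatch distance d in [d_min, d_max] stepped by `step`.

    Distances whose window would overrun the reference are skipped with a
    warning.
    """
    if orthologue not in ORTHOLOGUES:
        raise ValueError(f"unknown orthologue {orthologue!r}; known: {ORTHOLOGUES}")
    if spacer_length not in SPACER_LENGTHS:
        raise ValueError(f"spacer_length must be one of {SPACER_LENGTHS}")
    if d_min > d_max:
        raise ValueError(f"d_min {d_min} > d_max {d_max}")
    if not 1 <= d_min and d_max <= spacer_length:
        raise ValueError(
            f"mismatch distances must lie in [1, {spacer_length}] for a "
            f"{spacer_length} nt spacer"
        )
    guides = []
    for d in range(d_min, d_max + 1, step):
        try:
            spacer, window = _build_spacer(ref, spacer_length, d)
        except ValueError as exc:
            warnings.warn(f"skipping guide: {exc}", stacklevel=2)
            continue
        guides.append(
            GuideRNA(
                name=f"{ref.name}-{spacer_length}nt-{d}",
                spacer=spacer,
                mismatch_distance=d,
                orthologue=orthologue,
                window=window,
            )
        )
    return guides


def attach_scaffold(
    guide: GuideRNA,
    scaffold_table: dict[str, dict | str],
    include_dr: bool = True,
) -> GuideRNA:
    """Append the orthologue's direct repeat; include_dr=False gives a DR-less
    control guide (full_sequence == spacer)."""
    if not include_dr:
        return replace(guide, has_direct_repeat=False, full_sequence=guide.spacer)
    if guide.orthologue not in scaffold_table:
        raise KeyError(
            f"orthologue {guide.orthologue!r} not in scaffold table; known: "
            f"{sorted(scaffold_table)}"
        )
    entry = scaffold_table[guide.orthologue]
    if isinstance(entry, str):
        dr, side = entry, "3prime"
    else:
        dr, side = entry["sequence"], entry.get("side", "3prime")
    if side == "3prime":
        full = guide.spacer + dr
    elif side == "5prime":
        full = dr + guide.spacer
    else:
        raise ValueError(f"scaffold side must be '3prime' or '5prime', got {side!r}")
    return replace(guide, has_direct_repeat=True, full_sequence=full)


def nontargeting_guide(
    spacer_length: int,
    forbidden: list[AmpliconReference | str],
    seed: int = 0,
    max_attempts: int = 1000,
) -> GuideRNA:
    """Random control spacer with no exact >=15 nt match to any forbidden
    reference (either strand). Deterministic under seed."""
    if not forbidden:
        raise ValueError("at least one forbidden reference is required")
    k = MIN_NONTARGETING_MATCH
    kmers: set[str] = set()
    for f in forbidden:
        seq = f.sequence if isinstance(f, AmpliconReference) else str(f)
        for s in (seq, revcomp(seq)):
            kmers.update(s[i : i + k] for i in range(len(s) - k + 1))
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        spacer = "".join(rng.choice(list("ACGT"), size=spacer_length))
        if any(spacer[i : i + k] in kmers for i in range(spacer_length - k + 1)):
            continue
        return GuideRNA(
            name=f"nontargeting-{spacer_length}nt-seed{seed}",
            spacer=spacer,
            mismatch_distance=None,
            orthologue="PspCas13b",
        )
    raise RuntimeError(
        f"no qualifying non-targeting spacer after {max_attempts} attempts"
    )


def guide_manifest(guides: list[GuideRNA]) -> pd.DataFrame:
    rows = []
    for g in guides:
        w = g.window or (None, None)
        rows.append(
            {
                "name": g.name,
                "mismatch_distance": g.mismatch_distance,
                "orthologue": g.orthologue,
                "spacer_length": g.spacer_length,
                "window_start": w[0],
                "window_end": w[1],
                "has_direct_repeat": g.has_direct_repeat,
                "spacer": g.spacer,
            }
        )
    return pd.DataFrame(rows)


def write_guides(guides: list[GuideRNA], fasta_path, manifest_path=None, rna: bool = False) -> None:
    with open(fasta_path, "w") as fh:
        for g in guides:
            seq = g.full_sequence or g.spacer
            fh.write(f">{g.name}\n{to_rna(seq) if rna else seq}\n")
    if manifest_path is not None:
        guide_manifest(guides).to_csv(manifest_path, sep="\t", index=False)
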