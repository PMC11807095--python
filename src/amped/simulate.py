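"""Synthetic targeted-amplicon sequencing under an engagement editing model.

The generator emulates deep sequencing of a ~200 bp amplicon around a G>A
premature-stop site after treatment with a Cas13-ADAR editor. Each
transcript (read) is either *engaged* by the editing complex (probability
``engagement_prob``) or not. Engaged transcripts carry the intended target
A>G edit with probability ``on_target_prob_given_engaged`` and flip each
other adenosine *j* independently with its bystander probability ``q_j``;
unengaged transcripts flip adenosines with the (usually zero) baseline
probability ``q0_j``. The engagement structure makes bystander edits
co-occur on the same molecules, which is what per-read precision metrics
are sensitive to — a fully independent per-site model cannot produce
realistic bystander-free fractions.

Sequencing is modelled as uniform substitution error (rate ``seq_error``,
to a uniformly chosen different base) with Phred qualities drawn from a
truncated normal. Output is byte-identical FASTQ under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import AmpliconReference
from .sequtil import (
    BASE_TO_CODE,
    CODE_TO_BASE,
    bytes_to_seq,
    complement_bytes,
    seq_to_bytes,
)

MAX_PHRED = 41


@dataclass
class ReadRecord:
    """A single sequencing read (bases possibly containing N)."""

    id: str
    bases: str
    quals: np.ndarray  # per-base Phred scores, int

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"{self.id}: {len(self.bases)} bases but {len(self.quals)} quals"
            )
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > MAX_PHRED):
            raise ValueError(f"{self.id}: Phred scores outside [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class SimConfig:
    """Generative model for one simulated sample.

    ``bystander_probs`` and ``baseline_probs`` are keyed by reference
    adenosine position (0-based). ``read_length=None`` emits full-amplicon
    reads; shorter reads start at uniformly chosen offsets.
    """

    n_reads: int = 20000
    read_length: int | None = None
    engagement_prob: float = 0.0
    on_target_prob_given_engaged: float = 1.0
    bystander_probs: dict[int, float] = field(default_factory=dict)
    baseline_probs: dict[int, float] = field(default_factory=dict)
    seq_error: float = 0.001
    indel_prob: float = 0.0
    qual_mean: float = 37.0
    qual_sd: float = 3.0
    orientation_mixed: bool = False
    seed: int = 0

    def validate(self, ref: AmpliconReference | None = None) -> None:
        probs = [self.engagement_prob, self.on_target_prob_given_engaged]
        probs += list(self.bystander_probs.values())
        probs += list(self.baseline_probs.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not 0.0 <= self.seq_error <= 0.1:
            raise ValueError(f"seq_error {self.seq_error} outside [0, 0.1]")
        if not 0.0 <= self.indel_prob <= 0.1:
            raise ValueError(f"indel_prob {self.indel_prob} outside [0, 0.1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if ref is not None:
            sites = set(ref.adenosine_positions)
            for label, table in (
                ("bystander_probs", self.bystander_probs),
                ("baseline_probs", self.baseline_probs),
            ):
                extra = sorted(set(table) - sites)
                if extra:
                    raise ValueError(
                        f"{label} keys {extra} are not reference adenosines"
                    )
            if self.read_length is not None and not (
                0 < self.read_length <= len(ref)
            ):
                raise ValueError(
                    f"read_length {self.read_length} outside (0, {len(ref)}]"
                )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("bystander_probs", "baseline_probs"):
            raw[key] = {int(k): float(v) for k, v in raw.get(key, {}).items()}
        return cls(**raw)


def site_prob_for_observed_rate(rate: float, seq_error: float) -> float:
    """Pre-error edit probability that yields a given measured A>G rate.

    The estimator computes r = n_G / (n_A + n_G). Under uniform substitution
    error eps, a pre-error G is read as G with probability a = 1 - eps and a
    pre-error A is read as G with probability b = eps/3 (and symmetrically
    for A calls), so the expected measured rate of a site edited with
    probability p is r = (p*a + (1-p)*b) / (a + b). This inverts that map.
    """
    a = 1.0 - seq_error
    b = seq_error / 3.0
    p = (rate * (a + b) - b) / (a - b)
    if not -1e-12 <= p <= 1.0:
        raise ValueError(f"rate {rate} unreachable at seq_error {seq_error}")
    return max(p, 0.0)


def expected_observed_rate(p: float, seq_error: float) -> float:
    """Forward map of :func:`site_prob_for_observed_rate`."""
    a = 1.0 - seq_error
    b = seq_error / 3.0
    return (p * a + (1.0 - p) * b) / (a + b)


def simulate_reads(ref: AmpliconReference, cfg: SimConfig) -> list[ReadRecord]:
    """Draw a read set from the engagement model. Deterministic under seed."""
    cfg.validate(ref)
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n_reads, len(ref)
    t = ref.target_index

    mat = np.tile(seq_to_bytes(ref.sequence), (n, 1))

    engaged = rng.random(n) < cfg.engagement_prob
    on_edit = engaged & (rng.random(n) < cfg.on_target_prob_given_engaged)
    mat[on_edit, t] = b"G"
    # fixed sorted iteration so output never depends on dict insertion order
    for j in sorted(cfg.bystander_probs):
        if j == t:
            continue
        flip = engaged & (rng.random(n) < cfg.bystander_probs[j])
        mat[flip, j] = b"G"
    for j in sorted(cfg.baseline_probs):
        flip = ~engaged & (rng.random(n) < cfg.baseline_probs[j])
        mat[flip, j] = b"G"

    if cfg.seq_error > 0:
        err = rng.random((n, L)) < cfg.seq_error
        codes = BASE_TO_CODE[mat.view(np.uint8)]
        shift = rng.integers(1, 4, size=(n, L), dtype=np.uint8)
        codes[err] = (codes[err] + shift[err]) % 4
        mat = CODE_TO_BASE[codes].reshape(n, L)

    quals = np.clip(
        np.rint(rng.normal(cfg.qual_mean, cfg.qual_sd, size=(n, L))), 0, MAX_PHRED
    ).astype(np.int16)

    if cfg.read_length is not None and cfg.read_length < L:
        starts = rng.integers(0, L - cfg.read_length + 1, size=n)
    else:
        starts = np.zeros(n, dtype=np.int64)
    rlen = cfg.read_length or L

    reads: list[ReadRecord] = []
    for i in range(n):
        s = int(starts[i])
        bases_arr = mat[i, s : s + rlen]
        q = quals[i, s : s + rlen]
        if cfg.indel_prob > 0 and rng.random() < cfg.indel_prob:
            pos = int(rng.integers(0, len(bases_arr)))
            if rng.random() < 0.5 and len(bases_arr) > 1:  # deletion
                bases_arr = np.delete(bases_arr, pos)
                q = np.delete(q, pos)
            else:  # insertion of a random base
                ins = CODE_TO_BASE[int(rng.integers(0, 4))]
                bases_arr = np.insert(bases_arr, pos, ins)
                q = np.insert(q, pos, int(np.median(q)) if len(q) else 30)
        if cfg.orientation_mixed and i % 2 == 1:
            bases_arr = complement_bytes(bases_arr)[::-1]
            q = q[::-1]
        reads.append(
            ReadRecord(id=f"{ref.name}:{i:06d}", bases=bytes_to_seq(bases_arr), quals=q)
        )
    return reads


# ---------------------------------------------------------------------------
# FASTQ IO (Phred+33)
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def read_fastq(path) -> list[ReadRecord]:
    reads = []
    with open(path) as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                np.int16
            ) - 33
            reads.append(ReadRecord(id=rid.split()[0], bases=seq.upper(), quals=quals))
    return reads


# ---------------------------------------------------------------------------
# Dual-luciferase plate simulation
# ---------------------------------------------------------------------------

def make_layout(
    conditions: Sequence[str],
    n_replicates: int = 3,
    n_duplicates: int = 2,
    n_control_wells: int = 2,
    n_background_wells: int = 2,
) -> pd.DataFrame:
    """Build a plate layout table with sample, control and background wells."""
    rows = []
    well = 0

    def _add(condition, role, replicate):
        nonlocal well
        rows.append(
            {
                "well_id": f"W{well:03d}",
                "condition": condition,
                "role": role,
                "replicate": replicate,
            }
        )
        well += 1

    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            for _ in range(n_duplicates):
                _add(cond, "sample", rep)
    for i in range(n_control_wells):
        _add("positive_control", "positive_control", 1)
        _add("negative_control", "negative_control", 1)
    for i in range(n_background_wells):
        _add("background", "background", 1)
    return pd.DataFrame(rows)


def simulate_plate(
    layout: pd.DataFrame,
    true_efficiencies: dict[str, float],
    dynamic_range: float = 8.0,
    noise_cv: float = 0.0,
    background: tuple[float, float] = (100.0, 50.0),
    renilla_base: float = 10000.0,
    seed: int = 0,
):
    """Simulate raw Firefly/Renilla luminescence for a plate layout.

    Well ratios are drawn so that the control-normalised efficiency has
    expectation equal to ``true_efficiencies[condition]``; at ``noise_cv=0``
    the round trip through normalisation is exact. Background wells carry
    only the additive luminescence offset applied to every well.
    """
    from .luciferase import LuciferasePlate  # deferred to avoid cycle

    required = {"sample", "positive_control", "negative_control", "background"}
    present = set(layout["role"])
    missing = sorted(required - present)
    if missing:
        raise ValueError(f"layout is missing wells for roles: {missing}")
    unknown_conds = {
        c
        for c, r in zip(layout["condition"], layout["role"])
        if r == "sample" and c not in true_efficiencies
    }
    if unknown_conds:
        raise ValueError(f"no true efficiency given for {sorted(unknown_conds)}")

    rng = np.random.default_rng(seed)
    r_neg = 0.5
    r_pos = r_neg * dynamic_range
    f_bg, r_bg = background

    def _noise(size=None):
        if noise_cv == 0:
            return 1.0 if size is None else np.ones(size)
        return np.clip(rng.normal(1.0, noise_cv, size=size), 0.05, None)

    firefly, renilla = [], []
    for _, row in layout.iterrows():
        role = row["role"]
        if role == "background":
            firefly.append(f_bg)
            renilla.append(r_bg)
            continue
        if role == "positive_control":
            ratio = r_pos
        elif role == "negative_control":
            ratio = r_neg
        else:
            e = true_efficiencies[row["condition"]]
            ratio = r_neg + e * (r_pos - r_neg)
        ren = renilla_base * _noise()
        fire = ratio * ren * _noise()
        firefly.append(fire + f_bg)
        renilla.append(ren + r_bg)

    wells = layout.copy()
    wells["firefly"] = firefly
    wells["renilla"] = renilla
    return LuciferasePlate(wells)
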