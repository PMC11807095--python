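"""Synthetic cohorts emulating the in vivo AAV editing study conditions.

These presets generate amplicon cohorts with the replicate structure and
editing levels of subretinally injected Cas13-ADAR constructs quantified
by targeted deep sequencing: six treated eyes per condition, ~20,000
analysed reads per eye over a 200 bp amplicon, per-base sequencing error
1e-3. The named conditions carry the mean on-target editing rates (and,
for the dual-vector PspCas13b constructs, the mean significant-bystander
rates) that the pipeline is designed to resolve:

* ``RK-dPspCas13b``  — dual-vector PspCas13b-ADAR, photoreceptor-specific
  rhodopsin-kinase promoter: 2.04% on-target, 0.10% off-target mean.
* ``EFS-dPspCas13b`` — dual-vector PspCas13b-ADAR, EFS promoter: 0.93%
  on-target, 0.05% off-target mean.
* ``RK-dCas13bt3``   — all-in-one Cas13bt3-ADAR vector: 0.32% on-target.
* ``PBS``            — buffer-injected control eyes (no editing; the
  measured A>G rate is pure sequencing error).

The hottest single bystander site observed with the RK-driven vector
(0.36%) is available as ``HOT_SITE_PCT`` for single-site power analyses.

Generative truths are stated on the *measured-rate* scale; per-site edit
probabilities are obtained by inverting the sequencing-error model
(:func:`amped.simulate.site_prob_for_observed_rate`), so the expected
pipeline estimate equals the stated truth.
"""

from __future__ import annotations

from dataclasses import dataclass

from .quantify import FilterReport, SiteCountTable, align_sample, count_alleles, filter_reads
from .reference import AmpliconReference, make_reference
from .simulate import SimConfig, simulate_reads, site_prob_for_observed_rate


@dataclass(frozen=True)
class ConditionPreset:
    on_target_pct: float
    off_target_pct: float | None = None


CONDITIONS: dict[str, ConditionPreset] = {
    "RK-dPspCas13b": ConditionPreset(on_target_pct=2.04, off_target_pct=0.10),
    "EFS-dPspCas13b": ConditionPreset(on_target_pct=0.93, off_target_pct=0.05),
    "RK-dCas13bt3": ConditionPreset(on_target_pct=0.32),
    "PBS": ConditionPreset(on_target_pct=0.0),
}

HOT_SITE_PCT = 0.36  # hottest single bystander site, RK-driven vector

AMPLICON_LENGTH = 200
TARGET_OFFSET = 100
GUIDE_SPAN = 50
N_REPLICATES = 6
N_READS = 20000
SEQ_ERROR = 0.001
# Sub-0.1% bystander sites are only statistically separable from the error
# background when the per-base error sits well below the signal (the A>G
# error floor is seq_error / 3); off-target site-calling cohorts therefore
# use a lower error rate, matching the low empirical background such assays
# need in order to detect ~0.05% sites at all.
OFFTARGET_SEQ_ERROR = 2e-4
MAX_WINDOW_BYSTANDERS = 12  # guide-window adenosines besides the target


def default_reference(seed: int = 20) -> AmpliconReference:
    """The 200 bp study amplicon with a centred guide window."""
    return make_reference(
        length=AMPLICON_LENGTH,
        target_offset=TARGET_OFFSET,
        guide_span=GUIDE_SPAN,
        seed=seed,
        name="Ush2a-ex60-syn",
    )


def bystander_sites(ref: AmpliconReference, n_max: int = MAX_WINDOW_BYSTANDERS) -> list[int]:
    """Up to ``n_max`` guide-window adenosines nearest the target (excluded)."""
    candidates = [p for p in ref.window_adenosines if p != ref.target_index]
    candidates.sort(key=lambda p: (abs(p - ref.target_index), p))
    return sorted(candidates[:n_max])


def condition_config(
    ref: AmpliconReference,
    on_target_pct: float,
    off_target_pct: float | None = None,
    bystander_pct: dict[int, float] | None = None,
    n_reads: int = N_READS,
    seq_error: float = SEQ_ERROR,
    seed: int = 0,
) -> SimConfig:
    """Build a SimConfig whose expected measured rates equal the stated truths.

    ``off_target_pct`` spreads one uniform bystander truth over the guide
    window's bystander adenosines; ``bystander_pct`` gives explicit
    per-site truths instead.
    """
    on_rate = on_target_pct / 100.0
    engagement = site_prob_for_observed_rate(on_rate, seq_error) if on_rate > 0 else 0.0

    q: dict[int, float] = {}
    if bystander_pct:
        targets = dict(bystander_pct)
    elif off_target_pct:
        targets = {p: off_target_pct for p in bystander_sites(ref)}
    else:
        targets = {}
    for pos, pct in targets.items():
        p_site = site_prob_for_observed_rate(pct / 100.0, seq_error)
        if engagement <= 0:
            raise ValueError("bystander truths require a non-zero on-target rate")
        if p_site > engagement:
            raise ValueError(
                f"bystander truth {pct}% at site {pos} exceeds the engaged "
                "fraction; unreachable under the engagement model"
            )
        q[pos] = p_site / engagement
    return SimConfig(
        n_reads=n_reads,
        engagement_prob=engagement,
        on_target_prob_given_engaged=1.0,
        bystander_probs=q,
        seq_error=seq_error,
        seed=seed,
    )


def simulate_condition(
    ref: AmpliconReference,
    config: SimConfig,
    n_replicates: int = N_REPLICATES,
    seed: int = 1,
    sample_prefix: str = "rep",
    keep_alignments: bool = False,
):
    """Simulate and quantify one condition cohort.

    Returns ``(tables, reports)`` — or ``(tables, reports, alignment_sets)``
    with ``keep_alignments`` — with replicate seeds ``seed .. seed+n-1``.
    """
    tables: list[SiteCountTable] = []
    reports: list[FilterReport] = []
    alignment_sets = []
    for i in range(n_replicates):
        cfg = SimConfig(**{**config.__dict__, "seed": int(seed) + i})
        reads = simulate_reads(ref, cfg)
        kept, rep = filter_reads(reads)
        alignments, n_fail = align_sample(kept, ref)
        tables.append(
            count_alleles(alignments, ref, sample_id=f"{sample_prefix}{i + 1}")
        )
        reports.append(
            FilterReport(
                n_input=rep.n_input,
                n_fail_avg_quality=rep.n_fail_avg_quality,
                n_fail_alignment=n_fail,
                n_analyzed=len(alignments),
                bases_masked=rep.bases_masked,
            )
        )
        if keep_alignments:
            alignment_sets.append(alignments)
    if keep_alignments:
        return tables, reports, alignment_sets
    return tables, reports
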