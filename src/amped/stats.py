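"""Condition-level inference: off-target site calling and precision.

Off-target calling follows the pooled-replicate design: per-site A/G counts
are summed over all replicates of a condition, each adenosine is tested
against the pooled control counts with a two-tailed Fisher exact test, and
p-values are Benjamini-Hochberg adjusted across all adenosines of the
amplicon for that case/control contrast. Sites with adjusted p < 0.01 are
flagged significant (the 5% family rate is recorded in output metadata;
the stricter threshold is what drives the flags).

Per-read precision asks, of the reads that carry the intended target A>G
correction, what fraction carries no bystander A>G at any other adenosine
of the analysed region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .quantify import AlignmentSet, SiteCountTable
from .reference import AmpliconReference

ALPHA_SIGNIFICANT = 0.01
FDR_FAMILY_RATE = 0.05


def pool_counts(tables: list[SiteCountTable]) -> pd.DataFrame:
    """Element-wise sum of per-site n_G / n_A over replicates of a condition."""
    if not tables:
        raise ValueError("no count tables to pool")
    index = tables[0].counts.index
    for t in tables[1:]:
        if not t.counts.index.equals(index):
            raise ValueError(
                f"sample {t.sample_id} has different sites; all tables must "
                "share one reference"
            )
    pooled = pd.DataFrame(
        {
            "label": tables[0].counts["label"],
            "n_G": sum(t.counts["n_G"] for t in tables),
            "n_A": sum(t.counts["n_A"] for t in tables),
        },
        index=index,
    )
    return pooled


def fisher_site_test(case: tuple[int, int], control: tuple[int, int]) -> float:
    """Two-sided Fisher exact p for a (G, A) case vs control contingency.

    A zero margin (no G anywhere, or no A anywhere) carries no evidence of
    association and returns p = 1.
    """
    cg, ca = case
    kg, ka = control
    if min(cg, ca, kg, ka) < 0:
        raise ValueError("counts must be non-negative")
    if cg + kg == 0 or ca + ka == 0 or cg + ca == 0 or kg + ka == 0:
        return 1.0
    p = float(fisher_exact([[cg, ca], [kg, ka]], alternative="two-sided")[1])
    # extreme tables underflow to 0; keep p in (0, 1] for downstream BH
    return min(max(p, np.finfo(float).tiny), 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_sites(
    pooled_case: pd.DataFrame,
    pooled_control: pd.DataFrame,
    target_index: int | None = None,
    alpha: float = ALPHA_SIGNIFICANT,
) -> pd.DataFrame:
    """Per-adenosine Fisher tests of pooled case vs control counts.

    Returns a table indexed by position with columns label, case_G, case_A,
    control_G, control_A, p, q (BH-adjusted over all amplicon adenosines),
    significant, and is_target.
    """
    if not pooled_case.index.equals(pooled_control.index):
        raise ValueError("case and control tables cover different sites")
    p_values = [
        fisher_site_test(
            (int(pooled_case.loc[pos, "n_G"]), int(pooled_case.loc[pos, "n_A"])),
            (int(pooled_control.loc[pos, "n_G"]), int(pooled_control.loc[pos, "n_A"])),
        )
        for pos in pooled_case.index
    ]
    q_values = bh_adjust(p_values)
    calls = pd.DataFrame(
        {
            "label": pooled_case["label"],
            "case_G": pooled_case["n_G"],
            "case_A": pooled_case["n_A"],
            "control_G": pooled_control["n_G"],
            "control_A": pooled_control["n_A"],
            "p": p_values,
            "q": q_values,
        },
        index=pooled_case.index,
    )
    calls["significant"] = calls["q"] < alpha
    calls["is_target"] = (
        calls.index == target_index if target_index is not None else False
    )
    calls.attrs["alpha"] = alpha
    calls.attrs["fdr_family_rate"] = FDR_FAMILY_RATE
    calls.index.name = "position"
    return calls


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    mean = float(np.nanmean(values)) if values.size else float("nan")
    n = int(np.sum(~np.isnan(values)))
    sem = float(np.nanstd(values, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, sem


@dataclass
class ConditionSummary:
    """On/off-target editing summary for one condition."""

    condition: str
    n_replicates: int
    on_target_mean: float
    on_target_sem: float
    off_target_mean: float
    off_target_sem: float
    off_target_sum_mean: float
    n_significant_off_target: int
    on_off_ratio: float  # NaN (flagged) when no significant off-target signal
    site_rates: pd.DataFrame = field(repr=False, default=None)
    flags: list[str] = field(default_factory=list)


def summarize_condition(
    tables: list[SiteCountTable],
    calls: pd.DataFrame,
    target_index: int,
    condition: str = "condition",
) -> ConditionSummary:
    """Replicate-level on-target and significant-off-target rate summaries.

    The off-target scalar is the per-replicate mean editing rate over
    significant non-target sites, then averaged (± SEM) across replicates;
    a per-replicate sum variant is also reported.
    """
    if not tables:
        raise ValueError("need at least one replicate")
    rates = pd.DataFrame({t.sample_id: t.rates for t in tables})
    per_site_mean = rates.mean(axis=1)
    n_site = rates.notna().sum(axis=1)
    per_site_sem = rates.std(axis=1, ddof=1) / np.sqrt(n_site.clip(lower=1))
    site_rates = pd.DataFrame(
        {"label": tables[0].counts["label"], "mean": per_site_mean, "sem": per_site_sem}
    )

    on_mean, on_sem = _mean_sem(rates.loc[target_index].to_numpy())

    off_sites = calls.index[calls["significant"] & (calls.index != target_index)]
    flags: list[str] = []
    if len(off_sites) == 0:
        off_mean = off_sem = off_sum_mean = 0.0
        ratio = float("nan")
        flags.append("no_significant_off_target_sites")
    else:
        per_rep_mean = rates.loc[off_sites].mean(axis=0).to_numpy()
        per_rep_sum = rates.loc[off_sites].sum(axis=0).to_numpy()
        off_mean, off_sem = _mean_sem(per_rep_mean)
        off_sum_mean, _ = _mean_sem(per_rep_sum)
        if off_mean > 0:
            ratio = on_mean / off_mean
        else:
            ratio = float("nan")
            flags.append("off_target_mean_zero")

    return ConditionSummary(
        condition=condition,
        n_replicates=len(tables),
        on_target_mean=on_mean,
        on_target_sem=on_sem,
        off_target_mean=off_mean,
        off_target_sem=off_sem,
        off_target_sum_mean=off_sum_mean,
        n_significant_off_target=len(off_sites),
        on_off_ratio=ratio,
        site_rates=site_rates,
        flags=flags,
    )


@dataclass
class PrecisionSummary:
    """Bystander-free fraction of target-corrected reads."""

    condition: str
    n_corrected: int
    n_clean: int
    flags: list[str] = field(default_factory=list)

    @property
    def precision(self) -> float:
        if self.n_corrected == 0:
            return float("nan")
        return self.n_clean / self.n_corrected


def read_precision(
    alignments: AlignmentSet,
    target_index: int,
    adenosine_positions,
    region: tuple[int, int] | None = None,
    condition: str = "condition",
) -> PrecisionSummary:
    """Per-read precision: corrected reads carrying no bystander A>G.

    A read is *corrected* if it carries an unmasked G at the target
    adenosine, and *clean* if additionally no other adenosine in the region
    (default: the whole amplicon) carries a G; masked and gap columns are
    ignored for the bystander scan.
    """
    if not isinstance(alignments, AlignmentSet):
        alignments = AlignmentSet.from_aligned(alignments)
    positions = [p for p in adenosine_positions if p != target_index]
    if region is not None:
        lo, hi = region
        positions = [p for p in positions if lo <= p < hi]
    if len(alignments) == 0:
        return PrecisionSummary(condition, 0, 0, flags=["no_corrected_reads"])
    corrected = alignments.matrix[:, target_index] == b"G"
    n_corrected = int(corrected.sum())
    if n_corrected == 0:
        return PrecisionSummary(condition, 0, 0, flags=["no_corrected_reads"])
    if positions:
        bystander = (alignments.matrix[np.ix_(corrected, positions)] == b"G").any(axis=1)
        n_clean = int((~bystander).sum())
    else:
        n_clean = n_corrected
    return PrecisionSummary(condition, n_corrected, n_clean)
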