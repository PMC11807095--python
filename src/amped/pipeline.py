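"""End-to-end orchestration: quantify a cohort, call sites, summarise.

A run is described by a :class:`RunConfig` (JSON-serialisable). Inputs are
an annotated amplicon FASTA and a sample manifest TSV with columns
``sample_id``, ``condition``, ``role`` (case | control) and ``fastq``.
Every stage's outputs are written under the run directory together with a
machine-readable manifest (package version, thresholds, SHA-256 digests of
all inputs and outputs, per-sample read accounting), so identical inputs
yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from . import __version__
from .quantify import (
    DEFAULT_MIN_AVG_Q,
    DEFAULT_MIN_BASE_Q,
    align_sample,
    count_alleles,
    filter_reads,
    FilterReport,
)
from .align import DEFAULT_MIN_IDENTITY
from .reference import AmpliconReference
from .simulate import read_fastq
from .stats import (
    ALPHA_SIGNIFICANT,
    call_sites,
    pool_counts,
    read_precision,
    summarize_condition,
)

MANIFEST_COLUMNS = ("sample_id", "condition", "role", "fastq")


@dataclass
class RunConfig:
    reference: str
    manifest: str
    out_dir: str
    control_condition: str | None = None  # default: the manifest's control rows
    min_avg_q: float = DEFAULT_MIN_AVG_Q
    min_base_q: int = DEFAULT_MIN_BASE_Q
    min_identity: float = DEFAULT_MIN_IDENTITY
    alpha: float = ALPHA_SIGNIFICANT
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute quantify -> pool -> callsites -> summarise; returns the manifest."""
    ref_path = Path(config.reference)
    manifest_path = Path(config.manifest)
    for stage, path in (("load-reference", ref_path), ("load-manifest", manifest_path)):
        if not path.exists():
            raise FileNotFoundError(f"stage {stage}: missing input file {path}")

    ref = AmpliconReference.from_fasta(ref_path)
    samples = pd.read_csv(manifest_path, sep="\t")
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise ValueError(f"stage load-manifest: manifest missing columns {missing_cols}")
    for fq in samples["fastq"]:
        if not Path(fq).exists():
            raise FileNotFoundError(f"stage quantify: missing FASTQ {fq}")

    out_dir = Path(config.out_dir)
    sites_dir = out_dir / "sites"
    sites_dir.mkdir(parents=True, exist_ok=True)

    tables: dict[str, "SiteCountTable"] = {}
    alignments: dict[str, "AlignmentSet"] = {}
    reports: dict[str, FilterReport] = {}
    for _, row in samples.iterrows():
        sid = str(row["sample_id"])
        try:
            reads = read_fastq(row["fastq"])
            kept, rep = filter_reads(
                reads, min_avg_q=config.min_avg_q, min_base_q=config.min_base_q
            )
            aln, n_fail = align_sample(kept, ref, min_identity=config.min_identity)
            tables[sid] = count_alleles(aln, ref, sample_id=sid)
            alignments[sid] = aln
            reports[sid] = FilterReport(
                n_input=rep.n_input,
                n_fail_avg_quality=rep.n_fail_avg_quality,
                n_fail_alignment=n_fail,
                n_analyzed=len(aln),
                bases_masked=rep.bases_masked,
            )
        except Exception as exc:
            raise RuntimeError(f"stage quantify failed for sample {sid}: {exc}") from exc
        tables[sid].to_tsv(sites_dir / f"{sid}.sites.tsv")
        reports[sid].to_json(sites_dir / f"{sid}.filter.json")

    is_control = samples["role"].str.lower() == "control"
    if config.control_condition is not None:
        is_control |= samples["condition"] == config.control_condition
    control_ids = [str(s) for s in samples.loc[is_control, "sample_id"]]
    if not control_ids:
        raise ValueError("stage callsites: manifest defines no control samples")
    pooled_control = pool_counts([tables[s] for s in control_ids])

    summary_rows = []
    precision_rows = []
    for cond, grp in samples.loc[~is_control].groupby("condition", sort=True):
        ids = [str(s) for s in grp["sample_id"]]
        cond_tables = [tables[s] for s in ids]
        try:
            calls = call_sites(
                pool_counts(cond_tables),
                pooled_control,
                target_index=ref.target_index,
                alpha=config.alpha,
            )
            summary = summarize_condition(
                cond_tables, calls, ref.target_index, condition=str(cond)
            )
        except Exception as exc:
            raise RuntimeError(f"stage callsites failed for condition {cond}: {exc}") from exc
        calls.reset_index().to_csv(
            out_dir / f"{cond}.sitecalls.tsv", sep="\t", index=False, float_format="%.6g"
        )
        summary_rows.append(
            {
                "condition": summary.condition,
                "n_replicates": summary.n_replicates,
                "on_target_mean": summary.on_target_mean,
                "on_target_sem": summary.on_target_sem,
                "on_target_pct": 100 * summary.on_target_mean,
                "off_target_mean": summary.off_target_mean,
                "off_target_sem": summary.off_target_sem,
                "off_target_sum_mean": summary.off_target_sum_mean,
                "n_significant_off_target": summary.n_significant_off_target,
                "on_off_ratio": summary.on_off_ratio,
                "flags": ";".join(summary.flags),
            }
        )
        for sid in ids:
            prec = read_precision(
                alignments[sid], ref.target_index, ref.adenosine_positions,
                condition=str(cond),
            )
            precision_rows.append(
                {
                    "condition": cond,
                    "sample_id": sid,
                    "n_corrected": prec.n_corrected,
                    "n_clean": prec.n_clean,
                    "precision": prec.precision,
                    "flags": ";".join(prec.flags),
                }
            )

    pd.DataFrame(summary_rows).to_csv(
        out_dir / "condition_summary.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(precision_rows).to_csv(
        out_dir / "precision.tsv", sep="\t", index=False, float_format="%.6g"
    )

    inputs = {str(ref_path): _sha256(ref_path), str(manifest_path): _sha256(manifest_path)}
    for fq in samples["fastq"]:
        inputs[str(fq)] = _sha256(Path(fq))
    outputs = {
        str(p.relative_to(out_dir)): _sha256(p)
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and p.name != "run_manifest.json"
    }
    manifest = {
        "package": "amped",
        "version": __version__,
        "config": asdict(config),
        "inputs": inputs,
        "outputs": outputs,
        "read_accounting": {sid: asdict(rep) for sid, rep in reports.items()},
        "fdr_family_rate": 0.05,
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
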