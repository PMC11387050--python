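"""Sample-normality definitions, panel-level gates and batch failure logic.

A sample is *free of GC bias* only when its class is NO_BIAS (warnings count
as biased) and it was actually scored. A sample is *copy neutral* when fewer
than 5 and fewer than 5% of its autosomal CNV calls are nondiploid. A panel's
gates are evaluated only once it holds at least 5 samples; the GC gate needs
strictly more than 70% bias-free samples, the CNV gate strictly more than 50%
copy-neutral ones. A batch fails only when every batch-critical panel has
failed an evaluated gate.
"""

from __future__ import annotations

import json
import logging
import uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .gc_model import BiasClass, BiasScores, ScoreStatus
from .io_formats import is_autosomal

logger = logging.getLogger("panelgc")


@dataclass(frozen=True)
class PanelConfig:
    """Per-panel gate configuration."""

    panel_name: str
    min_total: int = 5
    gc_pass_ratio_min: float = 0.70
    cnv_pass_ratio_min: float = 0.50
    uses_cnv_gate: bool = True
    batch_critical: bool = True


# CNV normality cut-offs (counts OR fractions of autosomal calls)
CNV_FAIL_COUNT, CNV_FAIL_FRACTION = 10, 0.10
CNV_WARN_COUNT, CNV_WARN_FRACTION = 5, 0.05


def cnv_normality(n_nondiploid: int, n_autosomal: int) -> str:
    """Classify a sample's autosomal CNV call profile.

    "fail" with >=10 or >=10% nondiploid autosomal calls, "warn" at >=5 or
    >=5%; "neutral" (copy neutral) requires <5 and <5%. A sample with no
    autosomal calls is neutral (0 of 0 nondiploid).
    """
    frac = n_nondiploid / n_autosomal if n_autosomal else 0.0
    if n_nondiploid >= CNV_FAIL_COUNT or frac >= CNV_FAIL_FRACTION:
        return "fail"
    if n_nondiploid >= CNV_WARN_COUNT or frac >= CNV_WARN_FRACTION:
        return "warn"
    return "neutral"


@dataclass
class SampleQC:
    sample_id: str
    panel_name: str
    bias_class: Optional[BiasClass]
    gc_bias_free: bool
    n_autosomal_calls: Optional[int] = None
    n_nondiploid_autosomal: Optional[int] = None
    copy_neutral: Optional[bool] = None  # None: no CNV gate / no table
    cnv_status: Optional[str] = None
    notes: list[str] = field(default_factory=list)


def assess_sample(
    scores: BiasScores,
    cnv_calls: Optional[pd.DataFrame],
    panel_config: PanelConfig,
) -> SampleQC:
    """Combine a sample's bias class with its CNV call profile.

    ``gc_bias_free`` is true only for a scored NO_BIAS sample. Copy
    neutrality uses autosomal calls only. A sample missing from a supplied
    CNV table is conservatively counted as not copy neutral (with a note);
    when no table is supplied, or the panel does not use a CNV gate,
    ``copy_neutral`` stays undefined.
    """
    gc_free = (
        scores.status == ScoreStatus.SCORED
        and scores.bias_class == BiasClass.NO_BIAS
    )
    qc = SampleQC(scores.sample_id, panel_config.panel_name, scores.bias_class, gc_free)
    if not panel_config.uses_cnv_gate or cnv_calls is None:
        return qc
    rows = cnv_calls[cnv_calls["sample_id"] == scores.sample_id]
    if rows.empty:
        qc.copy_neutral = False
        qc.notes.append("sample absent from CNV call table; counted as not copy neutral")
        logger.warning("sample %s absent from CNV table", scores.sample_id)
        return qc
    auto = rows[rows["chrom"].map(is_autosomal)]
    qc.n_autosomal_calls = len(auto)
    qc.n_nondiploid_autosomal = int((auto["copy_state"] != 2).sum())
    qc.cnv_status = cnv_normality(qc.n_nondiploid_autosomal, qc.n_autosomal_calls)
    qc.copy_neutral = qc.cnv_status == "neutral"
    return qc


@dataclass
class PanelGate:
    """Gate evaluation results for one panel within a batch."""

    panel_name: str
    total_samples: int
    min_total: int
    gc_pass_count: int
    gc_pass_ratio: Optional[float]
    gc_pass_ratio_min: float
    gc_gate_evaluated: bool
    gc_gate_pass: Optional[bool]
    cnv_pass_count: Optional[int]
    cnv_pass_ratio: Optional[float]
    cnv_pass_ratio_min: float
    cnv_gate_evaluated: bool
    cnv_gate_pass: Optional[bool]
    uses_cnv_gate: bool
    batch_critical: bool

    @property
    def gc_pass_over_total(self) -> str:
        return f"{self.gc_pass_count}/{self.total_samples}"

    @property
    def cnv_pass_over_total(self) -> Optional[str]:
        if self.cnv_pass_count is None:
            return None
        return f"{self.cnv_pass_count}/{self.total_samples}"

    @property
    def failed(self) -> bool:
        """A panel fails when any evaluated gate fails; unevaluated gates
        never fail a panel."""
        if self.gc_gate_evaluated and not self.gc_gate_pass:
            return True
        if self.uses_cnv_gate and self.cnv_gate_evaluated and not self.cnv_gate_pass:
            return True
        return False


def evaluate_panel(samples: list[SampleQC], config: PanelConfig) -> PanelGate:
    """Evaluate the GC-bias and CNV-calls gates for one panel.

    Gates run only with at least ``min_total`` samples. Pass ratios are
    compared with strict inequalities: a panel passes its GC gate only when
    *more than* 70% of samples are bias-free (equivalently, it fails when
    over 30% are biased), and its CNV gate only when more than 50% are copy
    neutral. The CNV gate additionally requires copy-neutrality to be
    defined for the panel (a CNV table was supplied and the panel uses the
    gate).
    """
    mismatched = [s.sample_id for s in samples if s.panel_name != config.panel_name]
    if mismatched:
        raise ValueError(f"samples not in panel {config.panel_name!r}: {mismatched}")
    total = len(samples)
    gc_pass = sum(1 for s in samples if s.gc_bias_free)
    enough = total >= config.min_total
    if not enough:
        logger.warning(
            "panel %s: %d sample(s) < minimum %d; gates not evaluated",
            config.panel_name, total, config.min_total,
        )
    gc_ratio = gc_pass / total if total else None
    gc_evaluated = enough
    gc_gate_pass = (gc_ratio > config.gc_pass_ratio_min) if gc_evaluated else None

    cnv_defined = config.uses_cnv_gate and any(s.copy_neutral is not None for s in samples)
    if cnv_defined:
        cnv_pass = sum(1 for s in samples if s.copy_neutral)
        cnv_ratio = cnv_pass / total if total else None
        cnv_evaluated = enough
        cnv_gate_pass = (cnv_ratio > config.cnv_pass_ratio_min) if cnv_evaluated else None
    else:
        cnv_pass, cnv_ratio, cnv_evaluated, cnv_gate_pass = None, None, False, None

    return PanelGate(
        panel_name=config.panel_name,
        total_samples=total,
        min_total=config.min_total,
        gc_pass_count=gc_pass,
        gc_pass_ratio=gc_ratio,
        gc_pass_ratio_min=config.gc_pass_ratio_min,
        gc_gate_evaluated=gc_evaluated,
        gc_gate_pass=gc_gate_pass,
        cnv_pass_count=cnv_pass,
        cnv_pass_ratio=cnv_ratio,
        cnv_pass_ratio_min=config.cnv_pass_ratio_min,
        cnv_gate_evaluated=cnv_evaluated,
        cnv_gate_pass=cnv_gate_pass,
        uses_cnv_gate=config.uses_cnv_gate,
        batch_critical=config.batch_critical,
    )


@dataclass
class BatchReport:
    batch_id: str
    panels: list[PanelGate]
    batch_fail: bool
    report_uuid: str


def evaluate_batch(
    batch_id: str,
    panels: list[PanelGate],
    report_uuid: Optional[str] = None,
) -> BatchReport:
    """Batch verdict: fail only when *every* batch-critical panel has failed.

    Panels whose gates were not evaluated (too few samples, or no gate
    defined) count as not-failed, so they veto a batch failure.
    """
    if not panels:
        raise ValueError("empty batch: no panels to evaluate")
    critical = [p for p in panels if p.batch_critical]
    batch_fail = bool(critical) and all(p.failed for p in critical)
    return BatchReport(
        batch_id=batch_id,
        panels=panels,
        batch_fail=batch_fail,
        report_uuid=report_uuid or str(uuid.uuid4()),
    )


def _panel_record(gate: PanelGate) -> dict:
    return {
        "panel": gate.panel_name,
        "total sample count": gate.total_samples,
        "total sample count minimum": gate.min_total,
        "GC bias pass over total": gate.gc_pass_over_total,
        "GC bias pass ratio": gate.gc_pass_ratio,
        "GC bias pass ratio exclusive minimum": gate.gc_pass_ratio_min,
        "GC bias pass": gate.gc_gate_pass,
        "GC bias gate evaluated": gate.gc_gate_evaluated,
        "CNV calls pass over total": gate.cnv_pass_over_total,
        "CNV calls pass ratio": gate.cnv_pass_ratio,
        "CNV calls pass ratio exclusive minimum": gate.cnv_pass_ratio_min,
        "CNV calls pass": gate.cnv_gate_pass,
        "CNV calls gate evaluated": gate.cnv_gate_evaluated,
        "GC bias status": "fail" if gate.failed else "pass",
    }


def write_report(report: BatchReport, json_path: str | Path, tsv_path: str | Path | None = None) -> dict:
    """Serialize a batch report as JSON (and optionally a per-panel TSV).

    The JSON is deterministic for identical inputs apart from the report
    UUID, which callers may inject. Returns the report dictionary.
    """
    payload = {
        "report UUID": report.report_uuid,
        "batch": report.batch_id,
        "batch status": "fail" if report.batch_fail else "pass",
        "panels": [_panel_record(g) for g in report.panels],
    }
    json_path = Path(json_path)
    json_path.parent.mkdir(parents=True, exist_ok=True)
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    if tsv_path is not None:
        pd.DataFrame([_panel_record(g) for g in report.panels]).to_csv(
            tsv_path, sep="\t", index=False
        )
    return payload
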