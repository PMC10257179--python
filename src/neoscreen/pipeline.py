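"""End-to-end pipeline: simulate/load -> QC -> litter exclusion -> fits -> report."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import io, model, outliers, report
from .io import QcReport, TrialDataset
from .model import ModelSpec, PosteriorDraws
from .outliers import ExclusionTrace


@dataclass
class PipelineResult:
    dataset: TrialDataset  # after QC and litter exclusion
    qc: QcReport
    exclusion: ExclusionTrace
    pooled: PosteriorDraws
    concurrent: dict[str, PosteriorDraws]
    table: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def run_pipeline(
    dataset: TrialDataset,
    spec: ModelSpec | None = None,
    alpha_kw: float = 0.05,
    alpha_perm: float = 0.05,
    n_perm: int = 10_000,
    exclusion_seed: int = 0,
) -> PipelineResult:
    """Run the full analysis on a validated trial dataset.

    Order of operations: the moderate-injury QC gate drops whole experiments,
    the iterative procedure drops outlier control litters (grouped by litter
    within experiment), the borrowing model is fitted to everything retained,
    a concurrent-control fit is run per experiment, and the ranked efficacy
    table is assembled.
    """
    spec = spec or ModelSpec()
    notes: list[str] = []

    gated, qc_report = io.qc_filter(dataset)
    if qc_report.n_excluded:
        notes.append(f"QC gate removed {qc_report.n_excluded} experiment(s)")

    by_litter = gated.control_values_by_litter(group_by="litter")
    trace = outliers.iterative_exclusion(
        by_litter,
        alpha_kw=alpha_kw,
        alpha_perm=alpha_perm,
        n_perm=n_perm,
        seed=exclusion_seed,
    )
    cleaned = gated.drop_litters(trace.excluded) if trace.excluded else gated
    if trace.excluded:
        notes.append(f"excluded control litters: {trace.excluded}")

    pooled = model.fit_pooled(cleaned, spec)
    concurrent: dict[str, PosteriorDraws] = {}
    for exp in cleaned.experiments:
        sub = cleaned.experiment(exp)
        if set(sub["treatment"]) - {io.CONTROL_LABEL}:
            concurrent[exp] = model.fit_concurrent(cleaned, exp, spec)

    table = report.build_report(pooled, concurrent, cleaned)
    return PipelineResult(cleaned, qc_report, trace, pooled, concurrent, table, notes)
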