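"""End-to-end convenience chain over the library modules."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import MatureRef, PrecursorRef, SmallRead, StageSet
from .isomir_quant import ClassifiedRead, build_isomir_table, classify_assignments
from .read_annotation import (
    Assignment,
    LegitimacyResult,
    apply_legitimacy_filters,
    assign_reads,
    count_matrix,
    filter_contaminants,
)


@dataclass
class PipelineResult:
    contaminants: list[SmallRead]
    assignments: list[Assignment]
    unassigned: list[SmallRead]
    legitimacy: LegitimacyResult
    classified: list[ClassifiedRead]
    isomir_table: pd.DataFrame
    counts: pd.DataFrame


def run_pipeline(
    reads_by_stage: dict[str, list[SmallRead]],
    refs: tuple[list[MatureRef], list[PrecursorRef]],
    contaminant_refs: list[tuple[str, str]],
    stages: StageSet,
    min_count: int = 5,
) -> PipelineResult:
    """Contaminant screen -> assignment -> legitimacy -> isomiR table."""
    reads = [r for stage in stages for r in reads_by_stage.get(stage, [])]
    cont, remaining = filter_contaminants(reads, contaminant_refs)
    assignments, unassigned = assign_reads(remaining, refs[0])
    legit = apply_legitimacy_filters(assignments, stages, min_count=min_count)
    classified = classify_assignments(legit.retained, refs[1])
    table = build_isomir_table(classified, stages)
    counts = count_matrix(legit.retained, stages, antisense=legit.antisense)
    return PipelineResult(
        contaminants=cont, assignments=assignments, unassigned=unassigned,
        legitimacy=legit, classified=classified, isomir_table=table,
        counts=counts,
    )
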