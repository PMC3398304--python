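"""isomiR classification, relative-frequency quantification and tail stats.

An isomiR is identified by (miRNA, 5' offset, 3' offset, tail sequence), so
"+1A" and "+1U" are distinct variants.  Bases added beyond the canonical 3'
end are labelled *templated* when they equal the precursor base at the
corresponding downstream position and *untemplated* otherwise ("unknown"
when no precursor is linked).  The relative frequency of an isomiR in a
stage is its read count divided by the total read count of its parent
miRNA in that stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    PrecursorRef,
    StageSet,
    ValidationError,
    to_rna,
)
from .read_annotation import Assignment

TEMPLATED, UNTEMPLATED, UNKNOWN = "t", "u", "?"


@dataclass(frozen=True)
class ClassifiedRead:
    """One retained assignment classified relative to its canonical miRNA."""

    mirna: str
    five_prime_offset: int
    three_prime_offset: int
    tail_seq: str
    tail_status: str   # one of t/u/? per tail base
    head_seq: str      # bases added upstream of the canonical 5' end
    head_status: str
    stage: str
    count: int

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.mirna, self.five_prime_offset,
                self.three_prime_offset, self.tail_seq)


def _arm_interval(precursor: PrecursorRef, mature_seq: str,
                  mature_name: str) -> tuple[int, int]:
    start = precursor.sequence.find(mature_seq)
    if start < 0:
        raise ValidationError(
            f"{precursor.name}: mature {mature_name} not found in precursor"
        )
    return start, start + len(mature_seq)


def classify_isomir(
    assignment: Assignment, precursor: PrecursorRef | None = None
) -> ClassifiedRead:
    """Classify a retained assignment into its isomiR identity.

    With a linked precursor each added base (3' tail and 5' head) is checked
    against the flanking precursor sequence for template status; without
    one the status is unknown.
    """
    seq = assignment.oriented_sequence
    fp, tp = assignment.five_prime_offset, assignment.three_prime_offset
    tail = seq[len(seq) - tp:] if tp > 0 else ""
    head = seq[:fp] if fp > 0 else ""

    if precursor is None:
        t_status = UNKNOWN * len(tail)
        h_status = UNKNOWN * len(head)
    else:
        a, b = _arm_interval(precursor, assignment.ref.sequence,
                             assignment.ref.name)
        pre = precursor.sequence
        t_status = "".join(
            (TEMPLATED if b + k < len(pre) and pre[b + k] == base
             else UNTEMPLATED) if b + k < len(pre) else UNKNOWN
            for k, base in enumerate(tail)
        )
        h_status = "".join(
            (TEMPLATED if a - len(head) + k >= 0
             and pre[a - len(head) + k] == base else UNTEMPLATED)
            if a - len(head) + k >= 0 else UNKNOWN
            for k, base in enumerate(head)
        )
    return ClassifiedRead(
        mirna=assignment.ref.name,
        five_prime_offset=fp, three_prime_offset=tp,
        tail_seq=tail, tail_status=t_status,
        head_seq=head, head_status=h_status,
        stage=assignment.read.stage, count=assignment.read.count,
    )


def classify_assignments(
    assignments: list[Assignment],
    precursors: list[PrecursorRef] | None = None,
) -> list[ClassifiedRead]:
    """Classify every retained assignment, resolving precursors by name."""
    by_name = {p.name: p for p in precursors or []}
    out = []
    for a in assignments:
        pre = by_name.get(a.ref.hairpin_name) if a.ref.hairpin_name else None
        out.append(classify_isomir(a, pre))
    return out


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def build_isomir_table(
    classified: list[ClassifiedRead], stages: StageSet
) -> pd.DataFrame:
    """Aggregate classified reads into an isomiR-by-stage count table.

    The index is (mirna, five_prime_offset, three_prime_offset, tail_seq);
    stage columns hold summed counts and ``tail_status`` the per-base
    template flags (a function of tail and precursor, hence constant within
    a key).
    """
    rows: dict[tuple, dict] = {}
    for c in classified:
        if c.count < 0:
            raise ValidationError("negative read count")
        row = rows.setdefault(
            c.key, {s: 0 for s in stages} | {"tail_status": c.tail_status}
        )
        row[c.stage] = row.get(c.stage, 0) + c.count
    idx = pd.MultiIndex.from_tuples(
        sorted(rows), names=["mirna", "five_prime_offset",
                             "three_prime_offset", "tail_seq"],
    )
    df = pd.DataFrame(
        [[rows[k][s] for s in stages] + [rows[k]["tail_status"]]
         for k in idx],
        index=idx, columns=list(stages) + ["tail_status"],
    )
    return df


def isomir_relative_frequency(table: pd.DataFrame,
                              stages: StageSet) -> pd.DataFrame:
    """Relative frequency of each isomiR within its parent miRNA per stage.

    f(isomiR, stage) = reads(isomiR, stage) / reads(miRNA, stage).  Stages
    where the miRNA has zero total reads yield NaN (undefined), never 0.
    """
    counts = table[list(stages)].astype(float)
    if (counts.values < 0).any():
        raise ValidationError("negative counts in isomiR table")
    totals = counts.groupby(level="mirna").transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / totals.replace(0.0, np.nan)
    return freq


def select_isomirs_for_profiling(
    table: pd.DataFrame,
    stages: StageSet,
    min_reads: int = 1000,
    min_freq: float = 0.05,
    top_n_mirnas: int = 9,
    per_stage_reads: bool = False,
) -> pd.DataFrame:
    """Select the isomiRs worth profiling, as in the published analysis.

    Keeps the ``top_n_mirnas`` miRNAs by total read count, then within them
    the isomiRs with more than ``min_reads`` reads (summed over stages by
    default; per-stage when ``per_stage_reads``) *and* relative frequency
    above ``min_freq`` in at least one stage — both strict inequalities.
    5'-extended isomiRs beyond +1 are excluded, mirroring the 5' strictness
    of the legitimacy filter.
    """
    counts = table[list(stages)]
    mirna_totals = counts.groupby(level="mirna").sum().sum(axis=1)
    top = set(mirna_totals.sort_values(ascending=False)
              .head(top_n_mirnas).index)
    freq = isomir_relative_frequency(table, stages)
    if per_stage_reads:
        reads_ok = (counts > min_reads).any(axis=1)
    else:
        reads_ok = counts.sum(axis=1) > min_reads
    freq_ok = (freq > min_freq).any(axis=1)
    fp = table.index.get_level_values("five_prime_offset")
    keep = (
        table.index.get_level_values("mirna").isin(top)
        & reads_ok.values & freq_ok.values & (fp <= 1)
    )
    return table[keep]


def tail_composition_stats(
    classified: list[ClassifiedRead], stages: StageSet | None = None
) -> pd.DataFrame:
    """Per-miRNA percentages of 5'/3' added bases split by template status.

    One row per (mirna, end, base, status) with: ``reads`` = reads carrying
    at least one such addition, ``pct_reads`` = that as a percentage of the
    miRNA's total reads, and ``base_occurrences`` = total added-base count
    (a 2-nt tail contributes twice).  Bases are reported in the RNA
    alphabet (U, not T).
    """
    totals: dict[str, int] = {}
    carry: dict[tuple, int] = {}
    occ: dict[tuple, int] = {}
    status_names = {TEMPLATED: "templated", UNTEMPLATED: "untemplated",
                    UNKNOWN: "unknown"}
    for c in classified:
        totals[c.mirna] = totals.get(c.mirna, 0) + c.count
        for end, seq, status in (("5p", c.head_seq, c.head_status),
                                 ("3p", c.tail_seq, c.tail_status)):
            seen: set[tuple] = set()
            for base, st in zip(seq, status):
                key = (c.mirna, end, to_rna(base), status_names[st])
                occ[key] = occ.get(key, 0) + c.count
                if key not in seen:
                    carry[key] = carry.get(key, 0) + c.count
                    seen.add(key)
    rows = []
    for key in sorted(occ):
        mirna, end, base, status = key
        rows.append(dict(
            mirna=mirna, end=end, base=base, status=status,
            reads=carry[key],
            pct_reads=100.0 * carry[key] / totals[mirna],
            base_occurrences=occ[key],
        ))
    return pd.DataFrame(
        rows, columns=["mirna", "end", "base", "status", "reads",
                       "pct_reads", "base_occurrences"],
    )
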