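"""Readers, writers and the canonical in-memory data model.

Everything downstream sees DNA-alphabet sequences (``U`` is converted to
``T`` on input), 0-based half-open coordinates, and a fixed ordered set of
developmental-stage labels.  The default stage order is the eight Atlantic
halibut stages: blastula (BL), epiboly (EP), somitogenesis (SS), hatching
(HA), first feeding (FF), early metamorphosis (EM), climax metamorphosis
(CM) and juvenile (JU).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("mirdev")

#: Default developmental-stage order (blastula ... juvenile).
DEFAULT_STAGES = ("BL", "EP", "SS", "HA", "FF", "EM", "CM", "JU")

#: Seed region of a mature miRNA: positions 2-8, 1-based (0-based [1, 8)).
SEED_SLICE = slice(1, 8)

_DNA = set("ACGT")
_DNA_N = set("ACGTN")
_IUPAC = set("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file or record."""


class ValidationError(ValueError):
    """Input parsed but violates a data-model invariant."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render an internal DNA-alphabet sequence in the RNA alphabet."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement in the internal DNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSet:
    """Ordered, unique developmental-stage labels.

    The order is fixed at construction and preserved in every table the
    pipeline writes; the eight halibut stages are a default, not a
    constraint.
    """

    labels: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError(f"duplicate stage labels: {self.labels}")

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class MatureRef:
    """A canonical mature miRNA reference sequence.

    ``family`` groups references sharing an identical 7-mer seed
    (positions 2-8 from the 5' end); ``hairpin_name`` optionally links the
    mature to its precursor.
    """

    name: str
    sequence: str
    family: str = ""
    hairpin_name: str | None = None

    def __post_init__(self) -> None:
        if not set(self.sequence) <= _DNA:
            raise ValidationError(
                f"{self.name}: non-ACGT character in mature sequence"
            )
        if len(self.sequence) < 8:
            raise ValidationError(f"{self.name}: mature shorter than 8 nt")

    @property
    def seed(self) -> str:
        """7-mer seed, positions 2-8 (1-based) of the mature."""
        return self.sequence[SEED_SLICE]


@dataclass(frozen=True)
class PrecursorRef:
    """A pre-miRNA hairpin with the anatomy of its processed products.

    Coordinates are 0-based half-open intervals on ``sequence``: the guide
    mature arm, the optional star (passenger) arm, and the terminal loop.
    """

    name: str
    sequence: str
    mature_start: int
    mature_end: int
    star_start: int | None = None
    star_end: int | None = None
    loop_start: int | None = None
    loop_end: int | None = None

    def __post_init__(self) -> None:
        if not set(self.sequence) <= _DNA:
            raise ValidationError(f"{self.name}: non-ACGT character in precursor")
        if not (0 <= self.mature_start < self.mature_end <= len(self.sequence)):
            raise ValidationError(f"{self.name}: mature interval out of bounds")
        if self.loop_start is not None and self.loop_end is not None:
            if max(self.loop_start, self.mature_start) < min(
                self.loop_end, self.mature_end
            ):
                raise ValidationError(f"{self.name}: loop overlaps mature arm")

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature_start:self.mature_end]


@dataclass(frozen=True)
class SmallRead:
    """A collapsed small-RNA read: unique sequence with a copy count."""

    sequence: str
    count: int
    stage: str
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError(f"{self.read_id}: count must be >= 1")
        if not self.sequence or not set(self.sequence) <= _DNA_N:
            raise ValidationError(
                f"{self.read_id}: sequence must be non-empty over ACGTN"
            )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_reads(path: str | Path, stage: str, format: str = "fasta") -> list[SmallRead]:
    """Load a per-stage small-RNA library, collapsing identical sequences.

    FASTQ qualities are parsed (Sanger offset 33) but ignored.  Returns one
    :class:`SmallRead` per distinct sequence with counts summed, in order of
    first appearance.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown read format: {format!r} (use fasta or fastq)")
    counts: dict[str, int] = {}
    first_id: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), format):
            seq = normalize_sequence(str(rec.seq))
            if not seq or not set(seq) <= _DNA_N:
                raise FormatError(f"{path}: record {rec.id}: non-ACGTN sequence")
            counts[seq] = counts.get(seq, 0) + 1
            first_id.setdefault(seq, rec.id)
    except ValueError as exc:  # Bio.SeqIO signals malformed records this way
        raise FormatError(f"{path}: {exc}") from exc
    return [
        SmallRead(sequence=s, count=c, stage=stage, read_id=first_id[s])
        for s, c in counts.items()
    ]


def _seed_families(refs: Sequence[MatureRef]) -> list[MatureRef]:
    """Assign family labels: references sharing a 7-mer seed share a family.

    The family label is the lexicographically smallest member name, which
    makes the relation a plain equivalence over seeds.
    """
    by_seed: dict[str, list[MatureRef]] = {}
    for ref in refs:
        by_seed.setdefault(ref.seed, []).append(ref)
    out = []
    for ref in refs:
        label = min(r.name for r in by_seed[ref.seed])
        out.append(MatureRef(ref.name, ref.sequence, family=label,
                             hairpin_name=ref.hairpin_name))
    return out


def load_mirbase_fasta(
    path: str | Path, merge_duplicates: bool = False
) -> list[MatureRef]:
    """Load a mature-miRNA FASTA in the miRBase dialect.

    Headers are ``name accession species description``; the first
    whitespace-delimited token is the name.  The RNA alphabet is converted
    to DNA and seed families (identical positions 2-8) are assigned.

    With ``merge_duplicates`` cross-species entries with identical sequences
    collapse to one reference (first name wins); otherwise a duplicate
    *name* is a validation error while duplicate sequences under different
    names are kept.
    """
    refs: list[MatureRef] = []
    seen_names: set[str] = set()
    seen_seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        seq = normalize_sequence(str(rec.seq))
        if not set(seq) <= _IUPAC:
            raise ValidationError(f"{path}: {name}: non-IUPAC character")
        if not set(seq) <= _DNA:
            raise ValidationError(
                f"{path}: {name}: ambiguous bases not allowed in mature reference"
            )
        if name in seen_names:
            raise ValidationError(f"{path}: duplicate reference name {name}")
        seen_names.add(name)
        if merge_duplicates and seq in seen_seqs:
            continue
        seen_seqs.setdefault(seq, name)
        refs.append(MatureRef(name=name, sequence=seq))
    if not refs:
        logger.warning("%s: empty reference file", path)
    return _seed_families(refs)


def load_hairpin_fasta(path: str | Path) -> list[PrecursorRef]:
    """Load hairpin (precursor) sequences from a miRBase-dialect FASTA.

    Mature/star/loop coordinates are unknown for plain miRBase hairpin
    files; they can be attached later by matching a mature set.  The whole
    sequence is recorded with a trivial mature interval covering it.
    """
    out: list[PrecursorRef] = []
    names: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in names:
            raise ValidationError(f"{path}: duplicate precursor name {name}")
        names.add(name)
        seq = normalize_sequence(str(rec.seq))
        if not set(seq) <= _DNA:
            raise ValidationError(f"{path}: {name}: non-ACGT character")
        out.append(PrecursorRef(name=name, sequence=seq,
                                mature_start=0, mature_end=len(seq)))
    if not out:
        logger.warning("%s: empty hairpin file", path)
    return out


def load_fasta_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Plain FASTA loader for contaminant / EST-like sequence sets."""
    return [
        (rec.id, normalize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_reads_fasta(reads: Iterable[SmallRead], path: str | Path) -> None:
    """Write collapsed reads as FASTA; the count is carried in the header."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id} count={r.count} stage={r.stage}\n{r.sequence}\n")


def write_count_matrix(matrix: pd.DataFrame, path: str | Path,
                       stages: StageSet | None = None) -> None:
    """Write a feature-by-stage count matrix as TSV.

    The column order must equal the stage order; the first column holds the
    feature name.  Round-trips losslessly through :func:`read_count_matrix`.
    """
    if stages is not None and tuple(matrix.columns) != tuple(stages):
        raise ValidationError(
            f"matrix stage order {tuple(matrix.columns)} != {tuple(stages)}"
        )
    matrix.to_csv(path, sep="\t", index_label="feature")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV count matrix written by :func:`write_count_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative counts")
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: Default analysis thresholds (overridable via the YAML run config).
DEFAULT_THRESHOLDS = {
    "min_count": 5,
    "min_len": 17,
    "max_len": 26,
    "max_mismatch": 2,
    "min_isomir_reads": 1000,
    "min_isomir_freq": 0.05,
    "top_n_mirnas": 9,
    "energy_threshold": -25.0,
    "min_support": 50,
    "min_variant_reads": 1000,
    "reference_stage": "HA",
}


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration: paths, stage order, thresholds.

    Recognized top-level keys: ``reads`` (stage -> path map), ``mirbase``,
    ``hairpins``, ``contaminants``, ``stages`` (ordered list) and
    ``thresholds`` (any subset of :data:`DEFAULT_THRESHOLDS`).  Unknown
    threshold names are rejected; missing ones take their defaults.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    thresholds = dict(DEFAULT_THRESHOLDS)
    for key, value in (raw.get("thresholds") or {}).items():
        if key not in DEFAULT_THRESHOLDS:
            raise ValidationError(f"{path}: unknown threshold {key!r}")
        thresholds[key] = value
    stages = StageSet(tuple(raw["stages"])) if "stages" in raw else StageSet()
    return {
        "reads": dict(raw.get("reads") or {}),
        "mirbase": raw.get("mirbase"),
        "hairpins": raw.get("hairpins"),
        "contaminants": raw.get("contaminants"),
        "stages": stages,
        "thresholds": thresholds,
    }
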