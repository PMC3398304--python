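"""Read partitioning and seed-anchored assignment to mature miRNAs.

Reads are first screened against contaminant references (tRNA/rRNA/mt),
then assigned to the best-matching mature miRNA by exhaustive ungapped
alignment in both orientations, and finally passed through the legitimacy
filters (length 17-26 nt, bounded 5'/3' truncation, and a minimum per-stage
count).  The historical color-space contracts are reinterpreted in
nucleotide space: "2 color mismatches" becomes at most 2 substitutions and
the 20/25 color seed lengths become minimum nucleotide overlaps.

All inner loops are vectorized over collapsed reads grouped by length, so
libraries of ~10^5 distinct sequences annotate in seconds; the semantics
are identical to the brute-force per-read scan the tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MatureRef, SmallRead, StageSet, revcomp

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Assignment:
    """A read placed on a mature reference by ungapped alignment.

    Offsets follow the added/missing convention: a positive
    ``five_prime_offset`` means the read carries bases upstream of the
    canonical 5' end, a negative one that canonical 5' bases are missing
    (same at the 3' end).  For antisense assignments the placed sequence is
    the reverse complement of the read and mismatch bases refer to it.
    """

    read: SmallRead
    ref: MatureRef
    five_prime_offset: int
    three_prime_offset: int
    mismatches: tuple[tuple[int, str], ...]
    strand: str  # "sense" | "antisense"

    @property
    def oriented_sequence(self) -> str:
        return (self.read.sequence if self.strand == "sense"
                else revcomp(self.read.sequence))


@dataclass
class LegitimacyResult:
    """Outcome of the legitimacy filters.

    ``retained`` are the sense assignments that passed every rule;
    ``antisense`` are routed onward to novel-miRNA discovery rather than
    dropped; ``rejected`` are sense assignments that failed a rule.
    """

    retained: list[Assignment] = field(default_factory=list)
    antisense: list[Assignment] = field(default_factory=list)
    rejected: list[Assignment] = field(default_factory=list)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# Contaminant filtering
# ---------------------------------------------------------------------------

def filter_contaminants(
    reads: list[SmallRead],
    contaminant_refs: list[tuple[str, str]],
    min_match: int = 25,
    max_mismatch: int = 2,
) -> tuple[list[SmallRead], list[SmallRead]]:
    """Partition reads into (contaminant, remaining).

    A read is a contaminant when it matches some contaminant reference over
    at least ``min_match`` consecutive bases with at most ``max_mismatch``
    substitutions, or over its full length if it is shorter than
    ``min_match``.  The partition is exhaustive and disjoint.
    """
    if not contaminant_refs:
        import logging
        logging.getLogger("mirdev").warning(
            "empty contaminant set: all reads pass through"
        )
        return [], list(reads)

    ref_arrays = [_encode(seq) for _name, seq in contaminant_refs]
    # windows of each needed width, built lazily
    window_cache: dict[int, np.ndarray] = {}

    def windows(w: int) -> np.ndarray:
        if w not in window_cache:
            parts = [
                np.lib.stride_tricks.sliding_window_view(a, w)
                for a in ref_arrays if len(a) >= w
            ]
            window_cache[w] = (
                np.vstack(parts) if parts else np.empty((0, w), dtype=np.uint8)
            )
        return window_cache[w]

    # k-mer prefilter (pigeonhole: <=2 mismatches over >=24 bases implies an
    # exact shared 8-mer); only applied to reads long enough for it.
    kmer = 8
    ref_kmers: set[bytes] = set()
    for _name, seq in contaminant_refs:
        b = seq.encode("ascii")
        for i in range(len(b) - kmer + 1):
            ref_kmers.add(b[i:i + kmer])

    verdict: dict[str, bool] = {}
    contaminant, remaining = [], []
    for read in reads:
        seq = read.sequence
        if seq not in verdict:
            L = len(seq)
            w = min(min_match, L)
            hit = False
            candidate = True
            if w >= 3 * kmer:
                b = seq.encode("ascii")
                candidate = any(
                    b[i:i + kmer] in ref_kmers
                    for i in range(len(b) - kmer + 1)
                )
            if candidate:
                win = windows(w)
                if len(win):
                    arr = _encode(seq)
                    for start in range(L - w + 1):
                        sub = arr[start:start + w]
                        mism = (win != sub).sum(axis=1)
                        if (mism <= max_mismatch).any():
                            hit = True
                            break
            verdict[seq] = hit
        (contaminant if verdict[seq] else remaining).append(read)
    return contaminant, remaining


# ---------------------------------------------------------------------------
# Assignment to mature references
# ---------------------------------------------------------------------------

# score packing: (mismatches, |5' off|, |3' off|, strand, ref rank), all
# minimized lexicographically; sense sorts before antisense, ties between
# references break lexicographically by name.
_INVALID = np.int64(1) << 60


def assign_reads(
    reads: list[SmallRead],
    mature_refs: list[MatureRef],
    max_mismatch: int = 2,
    min_overlap: int = 16,
    max_added_5p: int = 3,
    max_added_3p: int = 6,
) -> tuple[list[Assignment], list[SmallRead]]:
    """Assign each read to its best mature reference, trying both strands.

    The best placement minimizes (mismatches, |five_prime_offset|,
    |three_prime_offset|), requires an ungapped overlap of at least
    ``min_overlap`` nt with at most ``max_mismatch`` substitutions, and
    bounds *added* bases by the alignment window (missing bases are bounded
    later by the legitimacy filters).  ``N`` bases count as mismatches.
    Returns (assignments, unassigned reads).
    """
    if not mature_refs:
        raise ValueError("assign_reads requires a non-empty reference set")
    refs = sorted(mature_refs, key=lambda r: r.name)
    ref_arr = [_encode(r.sequence) for r in refs]

    # group distinct sequences by length
    uniq: dict[str, list[int]] = {}
    for i, r in enumerate(reads):
        uniq.setdefault(r.sequence, []).append(i)
    by_len: dict[int, list[str]] = {}
    for seq in uniq:
        by_len.setdefault(len(seq), []).append(seq)

    best_for_seq: dict[str, tuple[int, int, int]] = {}  # seq -> (ref_i, strand, shift)
    for L, seqs in by_len.items():
        fwd = np.vstack([_encode(s) for s in seqs])
        rev = np.vstack([_encode(revcomp(s)) for s in seqs])
        n = len(seqs)
        best = np.full(n, _INVALID, dtype=np.int64)
        meta = np.zeros((n, 3), dtype=np.int32)  # ref_i, strand, shift
        for ref_i, ra in enumerate(ref_arr):
            M = len(ra)
            lo = max(-max_added_5p, min_overlap - L)
            hi = min(M - L + max_added_3p, M - min_overlap)
            for s in range(lo, hi + 1):
                a_ref, b_ref = max(0, s), min(M, s + L)
                if b_ref - a_ref < min_overlap:
                    continue
                fp, tp = -s, s + L - M
                ref_slice = ra[a_ref:b_ref]
                a_rd = a_ref - s
                for strand, mat in ((0, fwd), (1, rev)):
                    mism = (mat[:, a_rd:a_rd + (b_ref - a_ref)]
                            != ref_slice).sum(axis=1).astype(np.int64)
                    score = (
                        (mism << 40)
                        | (np.int64(abs(fp)) << 32)
                        | (np.int64(abs(tp)) << 24)
                        | (np.int64(strand) << 20)
                        | np.int64(ref_i)
                    )
                    score = np.where(mism <= max_mismatch, score, _INVALID)
                    better = score < best
                    if better.any():
                        best[better] = score[better]
                        meta[better] = (ref_i, strand, s)
        for j, seq in enumerate(seqs):
            if best[j] < _INVALID:
                best_for_seq[seq] = tuple(int(v) for v in meta[j])

    assignments: list[Assignment] = []
    unassigned: list[SmallRead] = []
    for read in reads:
        hit = best_for_seq.get(read.sequence)
        if hit is None:
            unassigned.append(read)
            continue
        ref_i, strand, s = hit
        ref = refs[ref_i]
        oriented = (read.sequence if strand == 0
                    else read.sequence.translate(_COMP)[::-1])
        M, L = len(ref.sequence), len(oriented)
        mism = tuple(
            (p, oriented[p - s])
            for p in range(max(0, s), min(M, s + L))
            if oriented[p - s] != ref.sequence[p]
        )
        assignments.append(Assignment(
            read=read, ref=ref,
            five_prime_offset=-s, three_prime_offset=s + L - M,
            mismatches=mism,
            strand="sense" if strand == 0 else "antisense",
        ))
    return assignments, unassigned


# ---------------------------------------------------------------------------
# Legitimacy filters
# ---------------------------------------------------------------------------

def apply_legitimacy_filters(
    assignments: list[Assignment],
    stages: StageSet,
    min_count: int = 5,
    min_len: int = 17,
    max_len: int = 26,
    max_missing_3p: int = 5,
    max_missing_5p: int = 1,
) -> LegitimacyResult:
    """Apply the legitimacy rules to sense assignments.

    A sense assignment is retained when the read length lies in
    [``min_len``, ``max_len``], at most ``max_missing_3p`` canonical bases
    are missing at the 3' end (``three_prime_offset >= -max_missing_3p``,
    boundary inclusive), at most ``max_missing_5p`` at the 5' end, and its
    miRNA accumulates at least ``min_count`` reads in at least one stage
    (summed over the assignments passing the per-read rules).  Antisense
    assignments are routed to discovery, never silently dropped.
    """
    result = LegitimacyResult()
    passing: list[Assignment] = []
    for a in assignments:
        if a.strand == "antisense":
            result.antisense.append(a)
            continue
        ok = (
            min_len <= len(a.read.sequence) <= max_len
            and a.three_prime_offset >= -max_missing_3p
            and a.five_prime_offset >= -max_missing_5p
        )
        (passing if ok else result.rejected).append(a)

    per_stage: dict[str, dict[str, int]] = {}
    for a in passing:
        d = per_stage.setdefault(a.ref.name, {})
        d[a.read.stage] = d.get(a.read.stage, 0) + a.read.count
    kept_refs = {
        name for name, d in per_stage.items()
        if max(d.values(), default=0) >= min_count
    }
    for a in passing:
        (result.retained if a.ref.name in kept_refs
         else result.rejected).append(a)
    return result


def count_matrix(
    sense: list[Assignment],
    stages: StageSet,
    antisense: list[Assignment] | None = None,
    antisense_suffix: str = "(AS)",
) -> pd.DataFrame:
    """Per-miRNA per-stage count matrix from assignments.

    Antisense assignments, if given, appear as separate features named
    ``<miRNA><suffix>`` so that sense/antisense trajectories can be
    compared in one table.
    """
    counts: dict[str, dict[str, int]] = {}
    def add(feature: str, stage: str, n: int) -> None:
        d = counts.setdefault(feature, {})
        d[stage] = d.get(stage, 0) + n

    for a in sense:
        add(a.ref.name, a.read.stage, a.read.count)
    for a in antisense or []:
        add(a.ref.name + antisense_suffix, a.read.stage, a.read.count)
    features = sorted(counts)
    mat = pd.DataFrame(
        [[counts[f].get(s, 0) for s in stages] for f in features],
        index=features, columns=list(stages), dtype=float,
    )
    return mat
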