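"""Rule-based discovery of novel miRNA candidates.

EST/GSS-like sequences are scanned with sliding windows for pre-miRNA
hairpins satisfying composition and structure gates (length 62-132 nt,
GC% in [30, 70], folding energy below a threshold, a single terminal loop,
no ambiguous bases, homopolymer runs or tandem repeats), deduplicated
against known precursors and each other, and validated by read support on
the stem.  Separately, reads left unassigned by annotation are searched for
homolog variants of known matures (seed mismatches) and for antisense
miRNAs (reverse complements with one mismatch and a 3' extension).

Folding is pluggable: the default backend is the ViennaRNA minimum
free-energy fold (kcal/mol); a lightweight weighted base-pair-maximization
dynamic program is the fallback and can be selected explicitly.  Because
simplified energies are not on the kcal/mol scale, the energy gate is
configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from functools import lru_cache

from .io_formats import MatureRef, SmallRead, SEED_SLICE, revcomp, to_rna

_DNA = set("ACGT")


# ---------------------------------------------------------------------------
# Folding backends
# ---------------------------------------------------------------------------

_PAIR_SCORES = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}
_STACK_BONUS = -0.5
MIN_LOOP = 3


def fold_stacking_dp(sequence: str) -> tuple[str, float]:
    """Weighted base-pair maximization with a stacking bonus.

    Pairs score GC=-3, AU=-2, GU=-1, with an extra -0.5 when two pairs
    stack; hairpin loops have at least 3 unpaired bases.  The score is a
    dimensionless stand-in for an energy (always <= 0, 0 for an unpairable
    sequence), not a thermodynamic free energy.
    """
    n = len(sequence)
    seq = sequence

    # E[i][j][stacked]: best score of seq[i..j], stacked=1 when (i,j) is
    # constrained to pair (used for the stacking bonus of the outer pair).
    import numpy as np
    NEG = 0.0
    E = np.zeros((n + 1, n + 1))          # open best for seq[i..j)
    P = np.full((n + 1, n + 1), np.inf)   # best with i..j-1 endpoints paired

    for span in range(MIN_LOOP + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # half-open
            pair = _PAIR_SCORES.get((seq[i], seq[j - 1]))
            if pair is not None:
                inner_open = E[i + 1][j - 1]
                inner_paired = P[i + 1][j - 1]
                best_in = min(
                    inner_open,
                    inner_paired + _STACK_BONUS
                    if inner_paired < np.inf else np.inf,
                )
                P[i][j] = pair + best_in
            best = min(E[i + 1][j], E[i][j - 1])
            if P[i][j] < np.inf:
                best = min(best, P[i][j])
            for k in range(i + 1, j):
                v = E[i][k] + E[k][j]
                if v < best:
                    best = v
            E[i][j] = min(best, 0.0)

    # traceback
    structure = ["."] * n

    def trace(i, j, must_pair):
        if j - i < MIN_LOOP + 2:
            return
        if must_pair:
            structure[i] = "("
            structure[j - 1] = ")"
            pair = _PAIR_SCORES[(seq[i], seq[j - 1])]
            inner_open = E[i + 1][j - 1]
            inner_paired = P[i + 1][j - 1]
            if inner_paired + _STACK_BONUS <= inner_open:
                trace(i + 1, j - 1, True)
            else:
                trace(i + 1, j - 1, False)
            return
        target = E[i][j]
        if target == 0.0 and P[i][j] > 0.0:
            return
        if P[i][j] == target:
            trace(i, j, True)
            return
        if E[i + 1][j] == target:
            trace(i + 1, j, False)
            return
        if E[i][j - 1] == target:
            trace(i, j - 1, False)
            return
        for k in range(i + 1, j):
            if E[i][k] + E[k][j] == target:
                trace(i, k, False)
                trace(k, j, False)
                return

    trace(0, n, False)
    return "".join(structure), float(E[0][n])


def _viennarna_backend():
    import RNA

    def fold(sequence: str) -> tuple[str, float]:
        structure, energy = RNA.fold(to_rna(sequence))
        return structure, float(energy)

    return fold


@lru_cache(maxsize=1)
def default_backend():
    """ViennaRNA MFE folding when available, else the stacking DP."""
    try:
        return _viennarna_backend()
    except ImportError:
        return fold_stacking_dp


def fold_hairpin(sequence: str, backend=None) -> tuple[str, float]:
    """Fold a candidate precursor; returns (dot-bracket, energy <= 0)."""
    if len(sequence) < 40:
        raise ValueError("fold_hairpin expects sequences of >= 40 nt")
    if not set(sequence) <= _DNA:
        raise ValueError("non-ACGT character in sequence to fold")
    backend = backend or default_backend()
    structure, energy = backend(sequence)
    return structure, min(energy, 0.0)


# ---------------------------------------------------------------------------
# Structure parsing
# ---------------------------------------------------------------------------

_HAIRPIN_LOOP = re.compile(r"\(\.*\)")


def terminal_loops(structure: str) -> list[tuple[int, int]]:
    """0-based half-open unpaired intervals enclosed by innermost pairs."""
    return [(m.start() + 1, m.end() - 1)
            for m in _HAIRPIN_LOOP.finditer(structure)]


def big_loop(structure: str) -> tuple[int, int] | None:
    """The terminal loop of a single-loop hairpin (None otherwise)."""
    loops = terminal_loops(structure)
    return loops[0] if len(loops) == 1 else None


def has_homopolymer(seq: str, max_run: int = 7) -> bool:
    return re.search(r"(.)\1{%d,}" % max_run, seq) is not None


def has_tandem_repeat(seq: str, min_span: int = 12, max_unit: int = 6) -> bool:
    """True when some >= ``min_span`` stretch is periodic with a short unit."""
    n = len(seq)
    for u in range(1, max_unit + 1):
        need = min_span - u
        run = 0
        for i in range(n - u):
            if seq[i] == seq[i + u]:
                run += 1
                if run >= need:
                    return True
            else:
                run = 0
    return False


# ---------------------------------------------------------------------------
# Candidate scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinCandidate:
    """A folded precursor candidate with its gate evidence."""

    source_id: str
    sequence: str
    structure: str
    energy: float
    gc_percent: float
    loop_interval: tuple[int, int]
    window_start: int = 0
    support_reads: int = 0
    support_position: tuple[int, int] | None = None


def scan_hairpin_candidates(
    sequences: list[tuple[str, str]],
    min_len: int = 62,
    max_len: int = 132,
    gc_range: tuple[float, float] = (30.0, 70.0),
    energy_threshold: float = -25.0,
    max_homopolymer: int = 7,
    min_repeat_span: int = 12,
    len_step: int = 8,
    pos_step: int = 4,
    backend=None,
) -> list[HairpinCandidate]:
    """Slide windows over EST/GSS-like sequences and keep hairpin windows.

    A window passes when its length is in [min_len, max_len], GC% within
    ``gc_range`` (inclusive), folding energy strictly below
    ``energy_threshold``, the fold has exactly one terminal loop, and the
    sequence has no ambiguous base, no homopolymer run longer than
    ``max_homopolymer`` and no tandem repeat spanning ``min_repeat_span``.
    Overlapping passing windows of one source collapse to the lowest-energy
    window.
    """
    backend = backend or default_backend()
    out: list[HairpinCandidate] = []
    for source_id, seq in sequences:
        n = len(seq)
        if n < min_len:
            continue
        lengths = sorted({
            *range(min_len, min(max_len, n) + 1, len_step),
            min(max_len, n),
        })
        accepted: list[HairpinCandidate] = []
        seen: set[tuple[int, int]] = set()
        for L in lengths:
            starts = sorted({*range(0, n - L + 1, pos_step), n - L})
            for start in starts:
                if (start, L) in seen:
                    continue
                seen.add((start, L))
                window = seq[start:start + L]
                if not set(window) <= _DNA:
                    continue
                if has_homopolymer(window, max_homopolymer):
                    continue
                if has_tandem_repeat(window, min_repeat_span):
                    continue
                gc = 100.0 * sum(window.count(b) for b in "GC") / L
                if not gc_range[0] <= gc <= gc_range[1]:
                    continue
                structure, energy = fold_hairpin(window, backend=backend)
                if energy >= energy_threshold:
                    continue
                loop = big_loop(structure)
                if loop is None:
                    continue
                accepted.append(HairpinCandidate(
                    source_id=source_id, sequence=window,
                    structure=structure, energy=energy,
                    gc_percent=gc, loop_interval=loop, window_start=start,
                ))
        # merge overlapping windows: keep the lowest-energy representative
        accepted.sort(key=lambda c: (c.energy, -len(c.sequence), c.window_start))
        chosen: list[HairpinCandidate] = []
        for cand in accepted:
            s0, e0 = cand.window_start, cand.window_start + len(cand.sequence)
            if any(max(s0, c.window_start)
                   < min(e0, c.window_start + len(c.sequence))
                   for c in chosen):
                continue
            chosen.append(cand)
        out.extend(sorted(chosen, key=lambda c: c.window_start))
    return out


# ---------------------------------------------------------------------------
# Redundancy collapse
# ---------------------------------------------------------------------------

def _ungapped_match(query: str, target: str,
                    per_nt: int = 14, min_cov: float = 0.8) -> bool:
    """Best ungapped local overlap test: mismatch density <= 1 per ``per_nt``
    aligned nt and aligned span > ``min_cov`` of the query length."""
    lq, lt = len(query), len(target)
    for shift in range(-lq + 1, lt):
        a_t, b_t = max(0, shift), min(lt, shift + lq)
        span = b_t - a_t
        if span <= min_cov * lq:
            continue
        qs = query[a_t - shift:b_t - shift]
        ts = target[a_t:b_t]
        mism = sum(1 for x, y in zip(qs, ts) if x != y)
        if mism * per_nt <= span:
            return True
    return False


def deduplicate_candidates(
    candidates: list[HairpinCandidate],
    known_precursors: list[tuple[str, str]] | None = None,
) -> tuple[list[HairpinCandidate], list[HairpinCandidate]]:
    """Split candidates into (known-matched, putative-novel) and collapse
    duplicates among the novel ones, keeping the longest representative.

    A candidate matches a known precursor (or another candidate) when its
    best ungapped overlap has at most 1 mismatch per 14 aligned nt and
    covers more than 80% of the candidate length.
    """
    known_matched: list[HairpinCandidate] = []
    novel: list[HairpinCandidate] = []
    for cand in candidates:
        if any(_ungapped_match(cand.sequence, seq)
               for _name, seq in known_precursors or []):
            known_matched.append(cand)
        else:
            novel.append(cand)
    novel.sort(key=lambda c: (-len(c.sequence), c.source_id, c.window_start))
    representatives: list[HairpinCandidate] = []
    for cand in novel:
        if any(_ungapped_match(cand.sequence, rep.sequence)
               for rep in representatives):
            continue
        representatives.append(cand)
    return known_matched, representatives


# ---------------------------------------------------------------------------
# Read-support validation
# ---------------------------------------------------------------------------

def validate_by_reads(
    candidate: HairpinCandidate,
    reads: list[SmallRead],
    min_support: int = 50,
    max_mismatch: int = 1,
) -> tuple[HairpinCandidate, bool]:
    """Count reads mapping to a common position on the candidate stem.

    Reads are placed by exhaustive ungapped alignment fully inside the
    candidate with at most ``max_mismatch`` substitutions; reads starting
    within +-1 of a common position pool together.  The candidate is
    accepted when the best position gathers strictly more than
    ``min_support`` reads and the supported interval stays outside the
    terminal loop.
    """
    seq = candidate.sequence
    placements: dict[int, tuple[int, int]] = {}  # start -> (count, max_end)
    for read in reads:
        r = read.sequence
        if len(r) > len(seq):
            continue
        best = None
        for start in range(len(seq) - len(r) + 1):
            mism = sum(1 for a, b in zip(r, seq[start:start + len(r)])
                       if a != b)
            if mism <= max_mismatch and (best is None or mism < best[0]):
                best = (mism, start)
        if best is None:
            continue
        start = best[1]
        c, e = placements.get(start, (0, 0))
        placements[start] = (c + read.count, max(e, start + len(r)))

    best_pos, best_support, best_interval = None, 0, None
    for p in sorted(placements):
        group = [q for q in (p - 1, p, p + 1) if q in placements]
        support = sum(placements[q][0] for q in group)
        if support > best_support:
            best_pos = p
            best_support = support
            best_interval = (min(group),
                             max(placements[q][1] for q in group))
    updated = replace(
        candidate, support_reads=best_support, support_position=best_interval
    )
    if best_interval is None:
        return updated, False
    lo, hi = candidate.loop_interval
    outside_loop = best_interval[1] <= lo or best_interval[0] >= hi
    return updated, best_support > min_support and outside_loop


# ---------------------------------------------------------------------------
# Homolog / antisense variant detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NovelVariantCall:
    """A read group called as a novel mature-miRNA variant."""

    sequence: str
    nearest_mature: str
    seed_mismatches: int
    orientation: str  # "sense" | "antisense"
    total_reads: int


def _sense_seed_variant(read: str, mature: str) -> int | None:
    """Mismatch count when the read matches with <= 2 mismatches all inside
    the seed (positions 2-8); None otherwise."""
    if abs(len(read) - len(mature)) > 2:
        return None
    overlap = min(len(read), len(mature))
    mism = [i for i in range(overlap) if read[i] != mature[i]]
    if not mism or len(mism) > 2:
        return None
    if all(SEED_SLICE.start <= i < SEED_SLICE.stop for i in mism):
        return len(mism)
    return None


def _antisense_variant(read: str, mature: str,
                       max_extension: int = 4) -> bool:
    """True for the reverse-complement-with-one-mismatch-and-3'-extension
    pattern: revcomp(read) equals the mature with <= 1 substitution after
    trimming up to ``max_extension`` extension bases."""
    rc = revcomp(read)
    for ext in range(0, max_extension + 1):
        core = rc[ext:]
        overlap = min(len(core), len(mature))
        if overlap < 16:
            continue
        mism = sum(1 for a, b in zip(core, mature) if a != b)
        if mism <= 1:
            return True
    return False


def detect_homolog_variants(
    reads: list[SmallRead],
    known_matures: list[MatureRef],
    min_total: int = 1000,
) -> list[NovelVariantCall]:
    """Find novel mature variants among unassigned reads.

    Sense calls carry at most two mismatches, all inside the seed
    (positions 2-8); antisense calls match the reverse complement of a
    known mature with at most one mismatch plus a 3' extension.  A call
    requires strictly more than ``min_total`` reads summed over the group
    sharing the exact sequence.
    """
    totals: dict[str, int] = {}
    for r in reads:
        totals[r.sequence] = totals.get(r.sequence, 0) + r.count
    calls = []
    for seq in sorted(totals):
        if totals[seq] <= min_total:
            continue
        for ref in sorted(known_matures, key=lambda m: m.name):
            n_seed = _sense_seed_variant(seq, ref.sequence)
            if n_seed is not None:
                calls.append(NovelVariantCall(
                    sequence=seq, nearest_mature=ref.name,
                    seed_mismatches=n_seed, orientation="sense",
                    total_reads=totals[seq],
                ))
                break
            if _antisense_variant(seq, ref.sequence):
                rc = revcomp(seq)
                seed_mm = sum(
                    1 for i in range(SEED_SLICE.start,
                                     min(SEED_SLICE.stop, len(ref.sequence)))
                    if i < len(rc) and rc[i] != ref.sequence[i]
                )
                calls.append(NovelVariantCall(
                    sequence=seq, nearest_mature=ref.name,
                    seed_mismatches=min(seed_mm, 2),
                    orientation="antisense", total_reads=totals[seq],
                ))
                break
    return calls
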