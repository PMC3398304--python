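"""Independent brute-force oracles used by the test suite.

Each oracle restates a pipeline contract in the most literal way possible
(exhaustive scans, recursive enumeration) without sharing code with the
implementation it checks.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_assign(read_seq, refs, max_mismatch=2, min_overlap=16,
                       max_added_5p=3, max_added_3p=6):
    """Exhaustive scan over references, orientations and shifts.

    Returns (ref_name, strand, five_prime_offset, three_prime_offset,
    n_mismatches) for the placement minimizing (mismatches, |5' offset|,
    |3' offset|, strand, name), or None.
    """
    best = None
    for ref in refs:
        M = len(ref.sequence)
        for strand, seq in (("sense", read_seq), ("antisense", rc(read_seq))):
            L = len(seq)
            for s in range(-L + 1, M):
                a, b = max(0, s), min(M, s + L)
                if b - a < min_overlap:
                    continue
                fp, tp = -s, s + L - M
                if fp > max_added_5p or tp > max_added_3p:
                    continue
                mism = sum(
                    1 for p in range(a, b)
                    if seq[p - s] != ref.sequence[p]
                )
                if mism > max_mismatch:
                    continue
                key = (mism, abs(fp), abs(tp),
                       0 if strand == "sense" else 1, ref.name, s)
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    mism, _afp, _atp, strand_i, name, s = best
    L = len(read_seq)
    M = len(next(r for r in refs if r.name == name).sequence)
    return (name, "sense" if strand_i == 0 else "antisense",
            -s, s + L - M, mism)


def brute_force_legitimacy(rows, min_count=5, min_len=17, max_len=26,
                           max_missing_3p=5, max_missing_5p=1):
    """Literal re-statement of the legitimacy rules.

    ``rows``: (idx, mirna, strand, read_len, fp, tp, stage, count).
    Returns the set of retained row indices.
    """
    per_read_ok = {}
    for idx, mirna, strand, read_len, fp, tp, stage, count in rows:
        per_read_ok[idx] = (
            strand == "sense"
            and min_len <= read_len <= max_len
            and tp >= -max_missing_3p
            and fp >= -max_missing_5p
        )
    stage_counts = {}
    for idx, mirna, strand, read_len, fp, tp, stage, count in rows:
        if per_read_ok[idx]:
            key = (mirna, stage)
            stage_counts[key] = stage_counts.get(key, 0) + count
    kept_mirnas = set()
    for (mirna, _stage), total in stage_counts.items():
        if total >= min_count:
            kept_mirnas.add(mirna)
    return {
        idx for idx, mirna, strand, read_len, fp, tp, stage, count in rows
        if per_read_ok[idx] and mirna in kept_mirnas
    }


def brute_force_upgma(points: np.ndarray):
    """Average-linkage agglomeration by direct recomputation.

    Returns the sorted list of merge heights.  At every step the pair of
    clusters with the smallest average inter-point Euclidean distance is
    merged (ties by smallest indices).
    """
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([
                    np.linalg.norm(points[a] - points[b])
                    for a in clusters[i] for b in clusters[j]
                ])
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


def enumerate_fold_score(seq: str, pair_scores, stack_bonus, min_loop=3):
    """Best score over ALL nested structures by exhaustive enumeration.

    A structure is a non-crossing set of pairs with hairpin loops of at
    least ``min_loop`` unpaired bases; its score is the sum of pair scores
    plus ``stack_bonus`` for every pair whose immediate inner neighbour is
    also paired.  Exponential: only for short sequences.
    """

    def enum(i, j):
        # all matchings on seq[i:j]
        if j - i < min_loop + 2:
            yield frozenset()
            return
        yield from enum(i + 1, j)
        for k in range(i + min_loop + 1, j):
            if (seq[i], seq[k]) in pair_scores:
                for inner in enum(i + 1, k):
                    for rest in enum(k + 1, j):
                        yield inner | rest | {(i, k)}

    def score(matching):
        total = sum(pair_scores[(seq[i], seq[j])] for i, j in matching)
        total += stack_bonus * sum(
            1 for i, j in matching if (i + 1, j - 1) in matching
        )
        return total

    return min(score(m) for m in enum(0, len(seq)))
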