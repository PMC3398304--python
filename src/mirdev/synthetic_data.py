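"""Seeded generator of staged small-RNA libraries with planted ground truth.

The generator emulates the structure of a developmental small-RNA study in
a teleost: eight stage libraries in which each miRNA follows one of four
temporal expression classes (early/embryonic/feeding/metamorphosis), reads
derive from guide and star arms plus optional antisense transcription with
a monotone temporal trend, and each read is an isomiR drawn from a planted
5'/3'-offset distribution with A/U-biased untemplated tail additions.
Contaminant reads (tRNA/rRNA/mt-like fragments) and a 10-11 nt degradation
class complete the libraries.  Every emitted read carries exactly one
ground-truth provenance label, so each downstream stage of the pipeline can
be scored against the truth.

Design notes
------------
* Counts are Poisson around planted expectations (one library per stage,
  no overdispersion estimate available to fit anything richer).
* Sequencing error is substitution-only at a configurable rate
  (default 0.5%); collapsed small-RNA reads are short, so indels are
  ignored.
* Precursor bases flanking each arm are fixed to G/C while the untemplated
  tail alphabet is A/U-biased, so templated and untemplated additions are
  identifiable by construction (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    MatureRef,
    PrecursorRef,
    SmallRead,
    StageSet,
    ValidationError,
    revcomp,
)

TEMPORAL_CLASSES = ("early", "embryonic", "feeding", "metamorphosis")

# Per-class relative expression trajectory over the 8 default stages
# (BL EP SS HA FF EM CM JU).  Early-class expression peaks at blastula/
# epiboly and decays ~100-fold by first feeding (miR-430-like maternal
# clearance); the other classes peak at organogenesis/hatching, first
# feeding, and metamorphosis respectively.
CLASS_SHAPES: dict[str, tuple[float, ...]] = {
    "early":         (1.00, 1.20, 0.35, 0.10, 0.010, 0.006, 0.004, 0.003),
    "embryonic":     (0.05, 0.15, 1.00, 1.10, 0.30, 0.15, 0.10, 0.08),
    "feeding":       (0.02, 0.03, 0.10, 0.30, 1.00, 0.50, 0.30, 0.25),
    "metamorphosis": (0.01, 0.02, 0.05, 0.10, 0.30, 1.00, 1.10, 0.80),
}

#: Planted antisense:sense expression ratios across the 8 stages, strictly
#: decreasing and crossing 1.0 at first feeding (index 4), emulating the
#: blastula-high / juvenile-low antisense trend of a miR-204AS-like locus.
DEFAULT_ANTISENSE_RATIOS = (200.0, 50.0, 12.0, 3.0, 0.8, 0.30, 0.12, 0.05)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class IsomirModel:
    """Planted isomiR distribution for one miRNA.

    ``offset_probs`` maps (five_prime_offset, three_prime_offset) pairs to
    probabilities (positive offsets = added bases, negative = missing).
    Added bases are untemplated with probability ``untemplated_prob``, in
    which case they are drawn from ``tail_alphabet_probs``; otherwise they
    copy the precursor flank (templated).
    """

    offset_probs: dict[tuple[int, int], float]
    tail_alphabet_probs: dict[str, float]
    untemplated_prob: float = 0.3
    internal_mismatch_rate: float = 0.0

    def __post_init__(self) -> None:
        for p in list(self.offset_probs.values()) + list(
            self.tail_alphabet_probs.values()
        ) + [self.untemplated_prob, self.internal_mismatch_rate]:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability out of [0,1]: {p}")
        if abs(sum(self.offset_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("offset_probs must sum to 1")
        if abs(sum(self.tail_alphabet_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("tail_alphabet_probs must sum to 1")


DEFAULT_OFFSET_PROBS: dict[tuple[int, int], float] = {
    (0, 0): 0.55,
    (0, 1): 0.16,
    (0, -1): 0.10,
    (0, 2): 0.06,
    (0, -2): 0.05,
    (0, -3): 0.03,
    (-1, 0): 0.03,
    (1, 0): 0.02,
}

DEFAULT_TAIL_PROBS = {"A": 0.6, "T": 0.4}


def default_isomir_model(untemplated_prob: float = 0.3) -> IsomirModel:
    return IsomirModel(
        offset_probs=dict(DEFAULT_OFFSET_PROBS),
        tail_alphabet_probs=dict(DEFAULT_TAIL_PROBS),
        untemplated_prob=untemplated_prob,
    )


@dataclass
class GroundTruth:
    """Planted truth for one simulated study.

    ``expected_counts`` holds the per-locus (guide name) per-stage expected
    read totals, covering guide + star + antisense reads of that locus;
    ``star_fraction`` and ``antisense_fraction`` say how that total splits.
    """

    expected_counts: pd.DataFrame
    isomir_models: dict[str, IsomirModel]
    star_fraction: dict[str, float]
    antisense_fraction: pd.DataFrame
    temporal_class: dict[str, str]
    stages: StageSet = field(default_factory=StageSet)

    def __post_init__(self) -> None:
        if (self.expected_counts.values < 0).any():
            raise ValidationError("expected counts must be >= 0")
        for df in (self.antisense_fraction,):
            if len(df) and ((df.values < 0) | (df.values > 1)).any():
                raise ValidationError("fractions must lie in [0,1]")
        for f in self.star_fraction.values():
            if not 0.0 <= f <= 1.0:
                raise ValidationError("star fractions must lie in [0,1]")


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, bases: str = "ACGT") -> str:
    return "".join(rng.choice(list(bases), size=n))


def star_name(guide: str) -> str:
    return guide + "*"


def antisense_name(guide: str) -> str:
    return guide + "(AS)"


def make_reference_set(
    n_mirna: int, seed: int, loop_len: int = 12
) -> tuple[list[MatureRef], list[PrecursorRef]]:
    """Generate ``n_mirna`` synthetic miRNA loci.

    Each precursor carries a guide arm (20-23 nt, unique across loci), a
    terminal loop of at least 8 nt, and a star arm that is the reverse
    complement of the guide with two substitutions.  Both guide and star
    are returned as mature references (star names carry a ``*`` suffix).
    Precursor bases adjacent to the arms are fixed to G/C so that A/U
    untemplated tail additions never coincide with the templated flank.
    """
    if n_mirna < 1:
        raise ValidationError("n_mirna must be >= 1")
    if loop_len < 8:
        raise ValidationError("terminal loop must be >= 8 nt")
    rng = np.random.default_rng(seed)
    matures: list[MatureRef] = []
    precursors: list[PrecursorRef] = []
    seen: set[str] = set()
    for i in range(n_mirna):
        while True:
            mature = _random_seq(rng, int(rng.integers(20, 24)))
            if mature not in seen:
                seen.add(mature)
                break
        # star arm: revcomp of guide with 2 substitutions away from the ends
        star = list(revcomp(mature))
        pos = rng.choice(np.arange(3, len(star) - 3), size=2, replace=False)
        for p in sorted(pos):
            alternatives = [b for b in "ACGT" if b != star[p]]
            star[p] = alternatives[int(rng.integers(3))]
        star = "".join(star)
        flank5 = _random_seq(rng, 2) + "CG"
        loop = "GC" + _random_seq(rng, loop_len - 3) + "C"
        flank3 = "GC" + _random_seq(rng, 2)
        seq = flank5 + mature + loop + star + flank3
        name = f"syn-mir-{i + 1:03d}"
        ms = len(flank5)
        me = ms + len(mature)
        ss = me + len(loop)
        se = ss + len(star)
        precursors.append(
            PrecursorRef(
                name=f"{name}-hp", sequence=seq,
                mature_start=ms, mature_end=me,
                star_start=ss, star_end=se,
                loop_start=me, loop_end=ss,
            )
        )
        matures.append(MatureRef(name, mature, hairpin_name=f"{name}-hp"))
        matures.append(MatureRef(star_name(name), star, hairpin_name=f"{name}-hp"))
    return matures, precursors


def make_contaminant_refs(seed: int) -> list[tuple[str, str]]:
    """tRNA/rRNA/mitochondrial-like random contaminant reference sequences."""
    rng = np.random.default_rng(seed)
    refs = []
    for i in range(3):
        refs.append((f"tRNA-{i + 1}", _random_seq(rng, 75)))
    for i in range(2):
        refs.append((f"rRNA-{i + 1}", _random_seq(rng, 300)))
    refs.append(("mt-1", _random_seq(rng, 500)))
    return refs


# ---------------------------------------------------------------------------
# Stage profiles
# ---------------------------------------------------------------------------

def make_stage_profiles(
    refs: tuple[list[MatureRef], list[PrecursorRef]],
    stages: StageSet,
    class_assignment: dict[str, str],
    depth: float | Sequence[float],
    seed: int,
    antisense_mirnas: tuple[str, ...] = (),
    antisense_ratios: tuple[float, ...] = DEFAULT_ANTISENSE_RATIOS,
    high_star_mirnas: tuple[str, ...] = (),
    star_fraction: float = 0.08,
    high_star_fraction: float = 0.75,
    isomir_model: IsomirModel | None = None,
) -> GroundTruth:
    """Plant per-locus per-stage expected counts and variant structure.

    ``depth`` is the expected number of miRNA-locus reads per stage library
    (a scalar, or one value per stage — in the kind of study this emulates
    the miRNA-mapped depth rises steeply across development); within a
    stage it is split across loci according to their temporal-class
    trajectory and a per-locus lognormal abundance factor.  Loci named in
    ``antisense_mirnas`` carry a strictly decreasing antisense:sense
    expression ratio across stages (``antisense_ratios``); loci in
    ``high_star_mirnas`` express the star arm above the guide.
    """
    depths = np.broadcast_to(np.asarray(depth, dtype=float), (len(stages),))
    if (depths < 0).any():
        raise ValidationError("depth must be >= 0")
    guides = [m.name for m in refs[0] if not m.name.endswith("*")]
    for g in guides:
        cls = class_assignment.get(g)
        if cls not in CLASS_SHAPES:
            raise ValidationError(f"{g}: unknown temporal class {cls!r}")
    if len(antisense_ratios) != len(stages):
        raise ValidationError("antisense_ratios must have one value per stage")
    if not all(a > b for a, b in zip(antisense_ratios, antisense_ratios[1:])):
        raise ValidationError("antisense_ratios must be strictly decreasing")

    rng = np.random.default_rng(seed)
    abundance = {g: float(rng.lognormal(0.0, 0.5)) for g in guides}
    shape_cols = {
        s: np.array([CLASS_SHAPES[class_assignment[g]][j] for g in guides])
        for j, s in enumerate(stages)
    }
    weights = pd.DataFrame(
        {s: shape_cols[s] * np.array([abundance[g] for g in guides])
         for s in stages},
        index=guides,
    )
    totals = weights.sum(axis=0)
    expected = weights / totals.replace(0.0, np.nan) * depths
    expected = expected.fillna(0.0)

    ratios = np.asarray(antisense_ratios, dtype=float)
    as_frac = pd.DataFrame(
        np.tile(ratios / (1.0 + ratios), (len(antisense_mirnas), 1)),
        index=list(antisense_mirnas),
        columns=list(stages),
    )
    model = isomir_model or default_isomir_model()
    return GroundTruth(
        expected_counts=expected,
        isomir_models={g: model for g in guides},
        star_fraction={
            g: (high_star_fraction if g in high_star_mirnas else star_fraction)
            for g in guides
        },
        antisense_fraction=as_frac,
        temporal_class=dict(class_assignment),
        stages=stages,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _arm_variants(
    precursor: PrecursorRef,
    arm_start: int,
    arm_end: int,
    model: IsomirModel,
) -> list[tuple[str, float, int, int, str, str]]:
    """Enumerate the concrete sequence variants of one arm with probabilities.

    Returns (sequence, probability, fp_off, tp_off, tail_seq, tail_status)
    where tail_status is one character per tail base: 't' templated /
    'u' untemplated.  Head (5') additions are handled the same way but are
    not part of the tail record.
    """
    pre = precursor.sequence
    arm = pre[arm_start:arm_end]
    out = []
    for (fp, tp), p_off in sorted(model.offset_probs.items()):
        if p_off == 0.0:
            continue
        core_start = arm_start + max(-fp, 0)
        core_end = arm_end + min(tp, 0)
        if core_end - core_start < 16:
            raise ValidationError("offset removes too much of the arm")
        core = pre[core_start:core_end]
        # enumerate added-base realizations on each side
        head_opts = [("", 1.0)]
        for k in range(1, max(fp, 0) + 1):
            pos = arm_start - k
            templ = pre[pos] if pos >= 0 else "A"
            new = []
            for h, ph in head_opts:
                new.append((templ + h, ph * (1.0 - model.untemplated_prob)))
                for b, pb in model.tail_alphabet_probs.items():
                    if pb > 0:
                        new.append((b + h, ph * model.untemplated_prob * pb))
            head_opts = new
        tail_opts = [("", "", 1.0)]
        for k in range(max(tp, 0)):
            pos = arm_end + k
            templ = pre[pos] if pos < len(pre) else "A"
            new = []
            for t, st, pt in tail_opts:
                new.append((t + templ, st + "t",
                            pt * (1.0 - model.untemplated_prob)))
                for b, pb in model.tail_alphabet_probs.items():
                    if pb > 0:
                        new.append((t + b, st + "u",
                                    pt * model.untemplated_prob * pb))
            tail_opts = new
        # merge identical sequences arising from templated == untemplated draws
        merged: dict[tuple[str, str, str], float] = {}
        for h, ph in head_opts:
            for t, st, pt in tail_opts:
                merged[(h, t, st)] = merged.get((h, t, st), 0.0) + ph * pt
        for (h, t, st), pht in merged.items():
            out.append((h + core + t, p_off * pht, fp, tp, t, st))
    return out


_SUBSTITUTES = {b: [c for c in "ACGT" if c != b] for b in "ACGTN"}


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Substitution-only sequencing error for a read known to carry >= 1:
    one guaranteed substitution plus Binomial(L-1, rate) extras."""
    L = len(seq)
    m = 1 + (rng.binomial(L - 1, rate) if L > 1 else 0)
    pos = rng.choice(L, size=m, replace=False)
    arr = list(seq)
    for p in pos:
        arr[p] = _SUBSTITUTES[arr[p]][int(rng.integers(3))]
    return "".join(arr)


def simulate_reads(
    truth: GroundTruth,
    refs: tuple[list[MatureRef], list[PrecursorRef]],
    contaminant_fraction: float = 0.05,
    seed: int = 0,
    error_rate: float = 0.005,
    contaminant_refs: list[tuple[str, str]] | None = None,
    degradation_fraction: float = 0.3,
) -> tuple[dict[str, list[SmallRead]], pd.DataFrame]:
    """Draw per-stage read libraries from the planted ground truth.

    Returns ``(reads_by_stage, provenance)`` where provenance has one row
    per emitted (collapsed) read: read_id, stage, source (guide name, star
    name, antisense name, contaminant, degradation), offsets, tail sequence
    and per-base template status, and the copy count.  Reads from distinct
    ground-truth categories are never merged, so every read has exactly one
    provenance row.
    """
    if not 0.0 <= contaminant_fraction < 1.0:
        raise ValidationError("contaminant_fraction must be in [0,1)")
    rng = np.random.default_rng(seed)
    matures, precursors = refs
    pre_by_name = {p.name: p for p in precursors}
    guide_refs = {m.name: m for m in matures if not m.name.endswith("*")}
    star_refs = {m.name: m for m in matures if m.name.endswith("*")}
    if contaminant_refs is None:
        contaminant_refs = make_contaminant_refs(seed + 1)

    # Pre-enumerate sequence variants per locus (guide and star arms).
    variants: dict[str, list[tuple[str, float, int, int, str, str]]] = {}
    for g, model in truth.isomir_models.items():
        hp = pre_by_name[guide_refs[g].hairpin_name]
        variants[g] = _arm_variants(hp, hp.mature_start, hp.mature_end, model)
        sname = star_name(g)
        if sname in star_refs and hp.star_start is not None:
            variants[sname] = _arm_variants(
                hp, hp.star_start, hp.star_end, model
            )
    # Fixed antisense variant per designated locus: revcomp of the guide
    # with one substitution and two extra 3' bases (miR-204AS-like).
    as_variant: dict[str, str] = {}
    for g in truth.antisense_fraction.index:
        base = list(revcomp(guide_refs[g].sequence))
        hp = pre_by_name[guide_refs[g].hairpin_name]
        star_mm = {
            i for i, (a, b) in enumerate(
                zip(revcomp(guide_refs[g].sequence),
                    hp.sequence[hp.star_start:hp.star_end])
            ) if a != b
        }
        free = [i for i in range(2, len(base) - 2) if i not in star_mm]
        p = int(rng.choice(free))
        base[p] = [b for b in "ACGT" if b != base[p]][int(rng.integers(3))]
        as_variant[g] = "".join(base) + _random_seq(rng, 2)

    reads_by_stage: dict[str, list[SmallRead]] = {s: [] for s in truth.stages}
    prov_rows: list[dict] = []
    counter = 0

    def emit(stage, seq, count, source, ref, fp, tp, tail, status):
        nonlocal counter
        if count <= 0:
            return
        counter += 1
        rid = f"r{counter:07d}"
        reads_by_stage[stage].append(
            SmallRead(sequence=seq, count=int(count), stage=stage, read_id=rid)
        )
        prov_rows.append(dict(
            read_id=rid, stage=stage, source=source, ref=ref,
            five_prime_offset=fp, three_prime_offset=tp,
            tail_seq=tail, tail_status=status, count=int(count),
        ))

    def emit_arm(stage, arm_name, source_kind, n):
        """Split n reads of one arm across its sequence variants + errors."""
        var = variants[arm_name]
        probs = np.array([v[1] for v in var])
        probs = probs / probs.sum()
        split = rng.multinomial(n, probs)
        for (seq, _p, fp, tp, tail, status), k in zip(var, split):
            if k == 0:
                continue
            p_err = 1.0 - (1.0 - error_rate) ** len(seq) if error_rate else 0.0
            n_err = rng.binomial(k, p_err) if p_err else 0
            emit(stage, seq, k - n_err, source_kind, arm_name,
                 fp, tp, tail, status)
            for _ in range(n_err):
                emit(stage, _apply_errors(seq, rng, error_rate), 1,
                     source_kind, arm_name, fp, tp, tail, status)

    for stage in truth.stages:
        for g in truth.expected_counts.index:
            lam = float(truth.expected_counts.loc[g, stage])
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n == 0:
                continue
            af = (
                float(truth.antisense_fraction.loc[g, stage])
                if g in truth.antisense_fraction.index else 0.0
            )
            sf = truth.star_fraction.get(g, 0.0)
            n_as = rng.binomial(n, af) if af > 0 else 0
            n_star = rng.binomial(n - n_as, sf) if sf > 0 else 0
            n_guide = n - n_as - n_star
            emit_arm(stage, g, g, n_guide)
            if n_star and star_name(g) in variants:
                emit_arm(stage, star_name(g), star_name(g), n_star)
            if n_as:
                emit(stage, as_variant[g], n_as, antisense_name(g), g,
                     0, 0, "", "")
        # contaminants + degradation
        depth_stage = float(truth.expected_counts[stage].sum())
        if contaminant_fraction > 0 and depth_stage > 0:
            lam_c = depth_stage * contaminant_fraction / (1 - contaminant_fraction)
            n_c = int(rng.poisson(lam_c))
            n_deg = rng.binomial(n_c, degradation_fraction)
            for kind, n_k, lens in (
                ("contaminant", n_c - n_deg, (18, 36)),
                ("degradation", n_deg, (10, 12)),
            ):
                if n_k == 0:
                    continue
                ref_idx = rng.integers(len(contaminant_refs), size=n_k)
                groups: dict[tuple, int] = {}
                for ri in ref_idx:
                    _name, rseq = contaminant_refs[int(ri)]
                    ln = int(rng.integers(*lens))
                    ln = min(ln, len(rseq))
                    start = int(rng.integers(0, len(rseq) - ln + 1))
                    key = (int(ri), start, ln)
                    groups[key] = groups.get(key, 0) + 1
                for (ri, start, ln), k in groups.items():
                    name, rseq = contaminant_refs[ri]
                    emit(stage, rseq[start:start + ln], k, kind, name,
                         0, 0, "", "")

    provenance = pd.DataFrame(
        prov_rows,
        columns=["read_id", "stage", "source", "ref", "five_prime_offset",
                 "three_prime_offset", "tail_seq", "tail_status", "count"],
    )
    return reads_by_stage, provenance


def sample_count_matrix(truth: GroundTruth, seed: int) -> pd.DataFrame:
    """Poisson-sampled per-locus per-stage count matrix around the planted
    expectations (no read-level structure)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.poisson(truth.expected_counts.values).astype(float),
        index=truth.expected_counts.index,
        columns=list(truth.stages),
    )


# ---------------------------------------------------------------------------
# Hairpin-gate fixture
# ---------------------------------------------------------------------------

def _design_hairpin(rng: np.random.Generator, stem: int, loop: int,
                    gc: float = 0.5, flank: int = 0) -> str:
    """A perfect stem-loop: complementary arms around an A/C-only loop."""
    arm = "".join(
        rng.choice(["G", "C"]) if rng.random() < gc
        else rng.choice(["A", "T"])
        for _ in range(stem)
    )
    loop_seq = _random_seq(rng, loop, "AC")
    flank5 = _random_seq(rng, flank, "AC")
    flank3 = _random_seq(rng, flank, "AC")
    return flank5 + arm + loop_seq + revcomp(arm) + flank3


def make_hairpin_fixture(seed: int, n_good: int = 25, n_per_violation: int = 5):
    """Constructed hairpin set for exercising the discovery gates.

    Returns ``(sources, reads, labels)``: ``n_good`` sources satisfy every
    gate of the scan -> validate chain (including read support strictly
    above the threshold, the first one exactly at threshold+1), and
    ``n_per_violation`` sources each violate exactly one of
    length / GC / energy / single-loop / read-support.  Each design is
    certified at construction time by running the gates, with rejection
    sampling over fresh random sequences until the intended gate pattern
    holds.
    """
    from . import novel_discovery as nd

    rng = np.random.default_rng(seed)
    sources: list[tuple[str, str]] = []
    reads: dict[str, list[SmallRead]] = {}
    labels: dict[str, str] = {}

    def certify(seq: str, want_candidates: int) -> list:
        cands = nd.scan_hairpin_candidates([("x", seq)])
        return cands if len(cands) == want_candidates else None

    def sample(builder, want_candidates, extra_check=None, max_tries=200):
        for _ in range(max_tries):
            seq = builder()
            cands = certify(seq, want_candidates)
            if cands is None:
                continue
            if extra_check is None or extra_check(seq, cands):
                return seq, cands
        raise RuntimeError("fixture rejection sampling did not converge")

    def stem_reads(source_id: str, seq: str, cand, count: int,
                   in_loop: bool = False) -> list[SmallRead]:
        lo, hi = cand.loop_interval
        if in_loop:
            start = max(0, lo - 2)  # read spans the terminal loop
        else:
            start = 2  # 5' stem arm, well outside the loop
        frag = seq[cand.window_start + start:
                   cand.window_start + start + 20]
        return [SmallRead(sequence=frag, count=count, stage="BL",
                          read_id=f"{source_id}-sup")]

    idx = 0
    def add(kind, seq, cands, read_list):
        nonlocal idx
        idx += 1
        sid = f"hp{idx:03d}"
        sources.append((sid, seq))
        labels[sid] = kind
        reads[sid] = read_list
        return sid

    # good hairpins: pass every structural gate and carry >50 stem reads
    for i in range(n_good):
        seq, cands = sample(
            lambda: _design_hairpin(rng, stem=30, loop=12), 1
        )
        support = 51 if i == 0 else int(rng.integers(60, 200))
        add("good", seq, cands, stem_reads("g", seq, cands[0], support))

    # length violators: perfect hairpins shorter than the minimum window
    for _ in range(n_per_violation):
        seq, _ = sample(
            lambda: _design_hairpin(rng, stem=int(rng.integers(16, 21)),
                                    loop=10), 0
        )
        add("length", seq, [], [])

    # GC violators: all-GC stems, structurally ideal but >70% GC
    for _ in range(n_per_violation):
        seq, _ = sample(
            lambda: _design_hairpin(rng, stem=30, loop=12, gc=1.0), 0
        )
        add("gc", seq, [], [])

    # energy violators: short weak stems padded to window length
    for _ in range(n_per_violation):
        def build():
            return _design_hairpin(rng, stem=11, loop=10,
                                   gc=0.5, flank=16)
        def weak(seq, _cands):
            _s, e = nd.fold_hairpin(seq)
            gc = 100.0 * sum(seq.count(b) for b in "GC") / len(seq)
            return -25.0 < e < -5.0 and 30.0 <= gc <= 70.0
        seq, _ = sample(build, 0, extra_check=weak)
        add("energy", seq, [], [])

    # loop violators: two modest hairpins in one window (two terminal
    # loops; combined energy still below the gate)
    for _ in range(n_per_violation):
        def build():
            return (_design_hairpin(rng, stem=13, loop=8)
                    + _random_seq(rng, 8, "AC")
                    + _design_hairpin(rng, stem=13, loop=8))
        def twoloop(seq, _cands):
            s, e = nd.fold_hairpin(seq)
            return e < -25.0 and len(nd.terminal_loops(s)) >= 2
        seq, _ = sample(build, 0, extra_check=twoloop)
        add("loop", seq, [], [])

    # support violators: structurally good, but reads either exactly at
    # the threshold or inside the terminal loop
    for i in range(n_per_violation):
        seq, cands = sample(
            lambda: _design_hairpin(rng, stem=30, loop=12), 1
        )
        if i % 2 == 0:
            rl = stem_reads("s", seq, cands[0], 50)       # boundary: reject
        else:
            rl = stem_reads("s", seq, cands[0], 100, in_loop=True)
        add("support", seq, cands, rl)

    return sources, reads, labels


# ---------------------------------------------------------------------------
# Canned scenario
# ---------------------------------------------------------------------------

def default_class_assignment(guides: list[str]) -> dict[str, str]:
    """Cycle the four temporal classes over the loci in order."""
    return {g: TEMPORAL_CLASSES[i % 4] for i, g in enumerate(guides)}

@dataclass
class Scenario:
    """A fully drawn synthetic study: references, truth, reads, labels."""

    refs: tuple[list[MatureRef], list[PrecursorRef]]
    truth: GroundTruth
    reads: dict[str, list[SmallRead]]
    provenance: pd.DataFrame
    contaminant_refs: list[tuple[str, str]]
    stages: StageSet


def default_scenario(
    seed: int,
    n_mirna: int = 20,
    depth: float = 125_000.0,
    contaminant_fraction: float = 0.05,
    error_rate: float = 0.005,
    stages: StageSet | None = None,
) -> Scenario:
    """The default study conditions: 20 loci x 4 temporal classes, one
    antisense pair, two high-star loci, ~1M miRNA-locus reads over 8 stages.
    """
    stages = stages or StageSet()
    refs = make_reference_set(n_mirna, seed)
    guides = [m.name for m in refs[0] if not m.name.endswith("*")]
    # The antisense pair sits on an embryonic-class locus: like miR-204 it
    # stays measurable at every stage, so both strands can be quantified.
    anti = guides[1] if n_mirna >= 2 else guides[0]
    truth = make_stage_profiles(
        refs, stages, default_class_assignment(guides), depth, seed + 1,
        antisense_mirnas=(anti,),
        high_star_mirnas=tuple(guides[2:4]) if n_mirna >= 4 else (),
    )
    contaminant_refs = make_contaminant_refs(seed + 3)
    reads, prov = simulate_reads(
        truth, refs, contaminant_fraction=contaminant_fraction,
        seed=seed + 2, error_rate=error_rate,
        contaminant_refs=contaminant_refs,
    )
    return Scenario(refs=refs, truth=truth, reads=reads, provenance=prov,
                    contaminant_refs=contaminant_refs, stages=stages)
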