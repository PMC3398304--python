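"""Efficiency-corrected RT-qPCR quantification and platform correlation.

Relative expression follows the Pfaffl model,
ratio = E_target^dCq_target / E_ref^dCq_ref with dCq = Cq(calibrator) -
Cq(sample), which reduces to the classical 2^(-ddCq) when both assays
amplify with efficiency 2.  Multi-reference normalization divides each
sample's target quantity by the geometric mean of the reference assays'
relative quantities (5S rRNA and U6 snoRNA in the study this emulates).
Digital (sequencing) and qPCR stage profiles are compared with the Pearson
product-moment correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError

#: Cq detection cut-off: measurements at or beyond this cycle are censored.
CQ_CUTOFF = 40.0


@dataclass(frozen=True)
class QpcrMeasurement:
    """One well: assay x sample x technical replicate."""

    assay: str
    sample: str
    replicate: int
    cq: float
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not 1.0 < self.efficiency <= 2.2:
            raise ValidationError(
                f"{self.assay}: efficiency {self.efficiency} outside (1, 2.2]"
            )
        if self.cq > CQ_CUTOFF:
            raise ValidationError(
                f"{self.assay}/{self.sample}: Cq beyond detection cut-off"
            )

    @property
    def censored(self) -> bool:
        return self.cq >= CQ_CUTOFF


def pfaffl_ratio(e_target: float, dcq_target: float,
                 e_ref: float, dcq_ref: float) -> float:
    """Pfaffl relative expression ratio E_t^dCq_t / E_r^dCq_r."""
    for e in (e_target, e_ref):
        if e <= 1.0:
            raise ValidationError(f"amplification efficiency must be > 1, got {e}")
    return float(e_target ** dcq_target / e_ref ** dcq_ref)


def measurements_frame(measurements: list[QpcrMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(assay=m.assay, sample=m.sample, replicate=m.replicate,
              cq=m.cq, efficiency=m.efficiency, censored=m.censored)
         for m in measurements]
    )


def relative_quantities(
    measurements: list[QpcrMeasurement], calibrator: str
) -> pd.DataFrame:
    """Per-assay per-sample relative quantity E^(Cq_cal - Cq_sample).

    Technical replicates are averaged on the Cq scale before the
    exponential transform.  Samples censored at the detection cut-off get
    NaN quantities and censored=True.
    """
    df = measurements_frame(measurements)
    agg = df.groupby(["assay", "sample"]).agg(
        cq=("cq", "mean"), efficiency=("efficiency", "first"),
        censored=("censored", "any"),
    ).reset_index()
    out = []
    for assay, sub in agg.groupby("assay"):
        sub = sub.set_index("sample")
        if calibrator not in sub.index:
            raise ValidationError(f"{assay}: calibrator {calibrator!r} missing")
        cq_cal = sub.loc[calibrator, "cq"]
        for sample, row in sub.iterrows():
            q = (np.nan if row["censored"]
                 else row["efficiency"] ** (cq_cal - row["cq"]))
            out.append(dict(assay=assay, sample=sample, quantity=q,
                            censored=bool(row["censored"])))
    return pd.DataFrame(out)


def normalize_multi_reference(
    measurements: list[QpcrMeasurement],
    target_assays: list[str],
    reference_assays: list[str],
    calibrator: str,
) -> pd.DataFrame:
    """Normalized relative quantities against multiple reference assays.

    The per-sample normalization factor is the geometric mean of the
    reference assays' relative quantities; each target quantity is divided
    by it.  Censored targets stay NaN (flagged); a reference missing in a
    sample is an error naming the sample.
    """
    rq = relative_quantities(measurements, calibrator)
    refs = rq[rq["assay"].isin(reference_assays)]
    samples = sorted(rq["sample"].unique())
    factor: dict[str, float] = {}
    for sample in samples:
        vals = refs.loc[refs["sample"] == sample, "quantity"]
        if len(vals) < len(reference_assays) or vals.isna().any():
            raise ValidationError(f"reference assay missing in sample {sample}")
        factor[sample] = float(stats.gmean(vals))
    rows = []
    for assay in target_assays:
        sub = rq[rq["assay"] == assay].set_index("sample")
        for sample in samples:
            if sample not in sub.index:
                continue
            q = sub.loc[sample, "quantity"]
            rows.append(dict(
                assay=assay, sample=sample,
                normalized=q / factor[sample],
                censored=bool(sub.loc[sample, "censored"]),
            ))
    return pd.DataFrame(rows)


def correlate_platforms(
    digital: pd.Series, qpcr: pd.Series, log_scale: bool = False
) -> float:
    """Pearson r between stage-matched digital and qPCR profiles.

    Only stages with finite values on both platforms enter; fewer than 3
    paired stages is an error; zero variance on either side yields NaN
    (undefined) rather than an arbitrary value.
    """
    joined = pd.concat([digital, qpcr], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValidationError("need >= 3 paired stages with defined values")
    x, y = joined.iloc[:, 0].values, joined.iloc[:, 1].values
    if log_scale:
        if (x <= 0).any() or (y <= 0).any():
            raise ValidationError("log-scale correlation requires positive values")
        x, y = np.log2(x), np.log2(y)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def simulate_cq(
    expression: pd.Series, efficiency: float, calibrator: str,
    base_cq: float = 25.0, noise_sd: float = 0.0, replicates: int = 2,
    assay: str = "target", seed: int = 0,
) -> list[QpcrMeasurement]:
    """Generate Cq values whose Pfaffl back-transform recovers a profile.

    Cq(sample) = Cq(calibrator) - log_E(expression ratio) plus optional
    Gaussian replicate noise; used for round-trip checks of the
    quantification chain.
    """
    if efficiency <= 1.0:
        raise ValidationError("efficiency must be > 1")
    rng = np.random.default_rng(seed)
    cal = expression[calibrator]
    out = []
    for sample, value in expression.items():
        dcq = np.log(value / cal) / np.log(efficiency)
        for rep in range(replicates):
            cq = base_cq - dcq + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            out.append(QpcrMeasurement(
                assay=assay, sample=str(sample), replicate=rep + 1,
                cq=float(cq), efficiency=efficiency,
            ))
    return out
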