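"""Two-step normalization of FPKM time courses.

Step 1 scales every (condition, replicate, timepoint) column by a constant
so all column sums agree, removing library-depth differences between
samples.  Step 2 divides each transcript's series by its own pre-shift
baseline (t = 0), so every surviving series starts at 1 a.u. (0 in log2)
and later values are relative binding changes.  Transcripts whose
normalized series is not finite at every point are dropped and reported —
never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import TC_COLUMNS, TimeCourseMatrix


class NormalizedTimeCourse(TimeCourseMatrix):
    """Baseline-relative binding series; ``scale`` is 'linear' or 'log2'.

    In linear scale every series equals 1 at t = 0; in log2 scale, 0.
    """

    def __init__(self, data: pd.DataFrame, scale: str = "linear", validate: bool = False):
        if scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {scale!r}")
        super().__init__(data, validate=False)
        self.scale = scale
        if validate:
            self._validate_normalized()

    def _validate_normalized(self) -> None:
        if not np.isfinite(self.data["value"]).all():
            raise ValueError("normalized values must be finite")
        t0 = self.data.loc[self.data["timepoint_min"] == 0, "value"]
        anchor = 1.0 if self.scale == "linear" else 0.0
        if not np.allclose(t0, anchor):
            raise ValueError(f"t=0 values must equal {anchor} in {self.scale} scale")

    def copy_with(self, data: pd.DataFrame) -> "NormalizedTimeCourse":
        return NormalizedTimeCourse(data, scale=self.scale)


def scale_timepoints(
    matrix: TimeCourseMatrix, target: float | str = "auto"
) -> tuple[TimeCourseMatrix, dict[tuple, float]]:
    """Scale each sample column so all column sums equal ``target``.

    A column is one (condition, replicate, timepoint) sample.  With
    ``target='auto'`` the target is the mean of the observed column sums.
    Returns the scaled matrix and the per-column factors.
    """
    df = matrix.data.copy()
    keys = ["condition", "replicate", "timepoint_min"]
    sums = df.groupby(keys)["value"].sum()
    zero = sums[sums <= 0]
    if not zero.empty:
        raise ValueError(f"zero-sum column(s): {list(zero.index)}")
    tgt = float(sums.mean()) if target == "auto" else float(target)
    factors = (tgt / sums).to_dict()
    df["value"] = df["value"] * df[keys].apply(tuple, axis=1).map(factors)
    return matrix.copy_with(df), factors


def relative_to_baseline(
    matrix: TimeCourseMatrix,
) -> tuple[NormalizedTimeCourse, list[str]]:
    """Divide each replicate series by its own value at t = 0.

    Transcripts with any non-finite normalized value (e.g. a zero
    baseline) are dropped and listed — only series with real values at all
    timepoints in all replicates are kept.
    """
    if 0 not in matrix.timepoints:
        raise ValueError("timepoint grid does not include t = 0")
    df = matrix.data.copy()
    keys = ["gene_id", "condition", "replicate"]
    base = (
        df[df["timepoint_min"] == 0]
        .set_index(keys)["value"]
        .rename("baseline")
    )
    df = df.join(base, on=keys)
    with np.errstate(divide="ignore", invalid="ignore"):
        df["value"] = df["value"] / df["baseline"]
    finite = df.groupby("gene_id")["value"].transform(
        lambda v: np.isfinite(v).all()
    )
    dropped = sorted(df.loc[~finite, "gene_id"].unique())
    df = df.loc[finite, TC_COLUMNS]
    if df.empty:
        raise ValueError("no transcript survived baseline normalization")
    return NormalizedTimeCourse(df, scale="linear"), dropped


def to_log2(ntc: NormalizedTimeCourse) -> NormalizedTimeCourse:
    """log2-transform a linear-scale normalized time course."""
    if ntc.scale != "linear":
        raise ValueError("to_log2 expects a linear-scale input")
    bad = ntc.data.loc[ntc.data["value"] <= 0, "gene_id"]
    if not bad.empty:
        raise ValueError(f"non-positive value for transcript {bad.iloc[0]}")
    df = ntc.data.copy()
    df["value"] = np.log2(df["value"])
    # enforce the exact-zero anchor despite float log rounding
    df.loc[df["timepoint_min"] == 0, "value"] = 0.0
    return NormalizedTimeCourse(df, scale="log2")


def normalize_pipeline(
    matrix: TimeCourseMatrix, target: float | str = "auto", log2: bool = True
) -> tuple[NormalizedTimeCourse, dict]:
    """Convenience: scale columns, divide by baseline, optionally log2.

    Returns the normalized time course and a report dict with the scaling
    factors and the dropped-transcript list.
    """
    scaled, factors = scale_timepoints(matrix, target=target)
    ntc, dropped = relative_to_baseline(scaled)
    if log2:
        ntc = to_log2(ntc)
    return ntc, {"factors": factors, "dropped": dropped}
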