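"""Relative DNA quantification by 2^-ddCt and breakpoint localization.

A duplication breakpoint is mapped by qPCR on an ordered panel of marker
genes along a chromosome arm: each marker's relative copy number in the
test line versus the originating line is estimated by the 2^-ddCt method
(one threshold cycle ~ a factor of two of template), and the boundary
between the single-copy and duplicated segments appears as a step in the
marker-ordered copy profile. The step is located by exhaustive
single-changepoint least squares on log2 ratios, with a BIC comparison
against the no-step model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QpcrPlate",
    "CopyProfile",
    "BreakpointCall",
    "delta_delta_ct",
    "relative_copy_profile",
    "detect_breakpoint",
]

PLATE_COLUMNS = ["marker_id", "sample", "target", "experiment", "replicate", "ct"]


def delta_delta_ct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_origin: float,
    ct_ref_origin: float,
) -> float:
    """Relative quantity 2^-ddCt of a target in the test vs origin sample.

    dCt(test) = Ct(target, test) - Ct(reference, test); dCt(origin)
    analogous; ddCt = dCt(test) - dCt(origin); the relative quantity is
    2^-ddCt. A one-cycle earlier target Ct in the test sample doubles the
    result.
    """
    values = (ct_target_test, ct_ref_test, ct_target_origin, ct_ref_origin)
    if not all(math.isfinite(v) for v in values):
        raise ValueError("Ct values must be finite")
    d_test = ct_target_test - ct_ref_test
    d_origin = ct_target_origin - ct_ref_origin
    return 2.0 ** -(d_test - d_origin)


@dataclass
class QpcrPlate:
    """Long-format Ct measurements plus the chromosome-arm marker order.

    ``wells`` columns: marker_id, sample ("test"/"origin"), target
    ("marker"/"reference"), experiment, replicate, ct. Reference wells are
    shared per (sample, experiment); every marker needs target and
    reference wells for both samples in every experiment it appears in.
    """

    wells: pd.DataFrame
    marker_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"plate missing columns: {missing}")
        if (self.wells["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if not self.marker_order:
            markers = self.wells.loc[
                self.wells["target"] == "marker", "marker_id"
            ]
            self.marker_order = list(dict.fromkeys(markers))
        self.validate()

    def validate(self) -> None:
        """Check that every (marker, sample, experiment) has reference wells."""
        marker_wells = self.wells[self.wells["target"] == "marker"]
        ref_wells = self.wells[self.wells["target"] == "reference"]
        ref_keys = set(
            zip(ref_wells["sample"], ref_wells["experiment"])
        )
        for (marker, sample, exp), _ in marker_wells.groupby(
            ["marker_id", "sample", "experiment"]
        ):
            if (sample, exp) not in ref_keys:
                raise ValueError(
                    f"no reference wells for sample={sample!r} "
                    f"experiment={exp!r} (needed by marker {marker!r})"
                )

    @classmethod
    def from_csv(
        cls, path: str | Path, marker_order: Sequence[str] | None = None
    ) -> "QpcrPlate":
        df = pd.read_csv(path)
        return cls(df, list(marker_order) if marker_order else [])

    def to_csv(self, path: str | Path) -> None:
        self.wells.to_csv(path, index=False)


@dataclass
class CopyProfile:
    """Per-marker relative copy number R_i = 2^-ddCt, in panel order.

    ``data`` columns: marker_id, r (mean over experiments), r_sd
    (dispersion over experiments), n_experiments.
    """

    data: pd.DataFrame

    @property
    def marker_ids(self) -> list[str]:
        return list(self.data["marker_id"])

    @property
    def r(self) -> np.ndarray:
        return self.data["r"].to_numpy(float)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def relative_copy_profile(
    plate: QpcrPlate,
    test_sample: str = "test",
    origin_sample: str = "origin",
) -> CopyProfile:
    """Marker-ordered relative copy numbers from a qPCR plate.

    Per (marker, experiment): replicate Ct values are averaged on the Ct
    scale, ddCt is formed against the reference wells of the same sample
    and experiment, giving one R per experiment; the marker's R is the mean
    over experiments and the dispersion its standard deviation.
    """
    wells = plate.wells
    # reference wells pooled per (sample, experiment); replicate means on Ct scale
    ref = (
        wells[wells["target"] == "reference"]
        .groupby(["sample", "experiment"])["ct"]
        .mean()
    )
    marker = (
        wells[wells["target"] == "marker"]
        .groupby(["marker_id", "sample", "experiment"])["ct"]
        .mean()
    )

    rows = []
    for marker_id in plate.marker_order:
        try:
            sub = marker.xs(marker_id, level="marker_id")
        except KeyError:
            raise ValueError(f"marker {marker_id!r} has no wells") from None
        experiments = sorted(sub.xs(test_sample, level="sample").index)
        r_values = []
        for exp in experiments:
            try:
                r_values.append(
                    delta_delta_ct(
                        sub.loc[(test_sample, exp)],
                        ref.loc[(test_sample, exp)],
                        sub.loc[(origin_sample, exp)],
                        ref.loc[(origin_sample, exp)],
                    )
                )
            except KeyError as exc:
                raise ValueError(
                    f"marker {marker_id!r}: missing wells for experiment "
                    f"{exp!r}: {exc}"
                ) from None
        r_values = np.asarray(r_values)
        rows.append(
            {
                "marker_id": marker_id,
                "r": float(r_values.mean()),
                "r_sd": float(r_values.std(ddof=1)) if len(r_values) > 1 else 0.0,
                "n_experiments": len(r_values),
            }
        )
    return CopyProfile(pd.DataFrame(rows))


@dataclass
class BreakpointCall:
    """Single-step changepoint fit to a marker-ordered copy profile.

    ``changepoint`` = j means the copy-number step lies between marker j
    and marker j+1 (1-based panel positions); None means the no-step model
    was preferred. Fitted levels are on the ratio scale; ``left_call`` /
    ``right_call`` snap them to the nearest candidate level (default
    candidates 1.0 and 2.0, i.e. 2:2 vs 2:4 copies).
    """

    changepoint: int | None
    left_level: float
    right_level: float
    left_call: float | None
    right_call: float | None
    sse_two_segment: float
    sse_one_segment: float
    bic_two_segment: float
    bic_one_segment: float

    @property
    def step_called(self) -> bool:
        return self.changepoint is not None

    def to_dict(self) -> dict:
        return {
            "changepoint": self.changepoint,
            "step_called": self.step_called,
            "left_level": self.left_level,
            "right_level": self.right_level,
            "left_call": self.left_call,
            "right_call": self.right_call,
            "sse_two_segment": self.sse_two_segment,
            "sse_one_segment": self.sse_one_segment,
            "bic_two_segment": self.bic_two_segment,
            "bic_one_segment": self.bic_one_segment,
        }


def _bic(sse: float, n: int, k_params: int, eps: float = 1e-12) -> float:
    return n * math.log(max(sse, eps) / n) + k_params * math.log(n)


def _snap(level: float, candidates: Iterable[float]) -> float:
    # nearest in log2 space, matching the fitting scale
    return min(candidates, key=lambda c: abs(math.log2(level) - math.log2(c)))


def detect_breakpoint(
    profile: CopyProfile,
    candidate_levels: Iterable[float] = (1.0, 2.0),
) -> BreakpointCall:
    """Locate a single copy-number step in a marker-ordered profile.

    All changepoints j in 1..n-1 are scanned exhaustively; left/right
    levels are the means of log2 R on each side and j minimizes the
    residual sum of squares in log2 space (ties to smaller j). A step is
    called only when the two-segment model beats the one-segment model by
    BIC; otherwise the call is "no step within panel".
    """
    r = profile.r
    n = len(r)
    if n < 2:
        raise ValueError("breakpoint detection needs >= 2 markers")
    if (r <= 0).any():
        raise ValueError("relative quantities must be positive")
    y = np.log2(r)

    sse_one = float(((y - y.mean()) ** 2).sum())

    best_j, best_sse, best_left, best_right = None, math.inf, 0.0, 0.0
    prefix = np.cumsum(y)
    prefix_sq = np.cumsum(y**2)
    for j in range(1, n):
        left_sum, left_sq = prefix[j - 1], prefix_sq[j - 1]
        right_sum = prefix[-1] - left_sum
        right_sq = prefix_sq[-1] - left_sq
        mu_l, mu_r = left_sum / j, right_sum / (n - j)
        sse = (left_sq - j * mu_l**2) + (right_sq - (n - j) * mu_r**2)
        if sse < best_sse - 1e-15:
            best_j, best_sse, best_left, best_right = j, sse, mu_l, mu_r
    best_sse = max(best_sse, 0.0)

    bic_one = _bic(sse_one, n, 1)
    bic_two = _bic(best_sse, n, 2)
    candidates = tuple(candidate_levels)

    left_level = 2.0**best_left
    right_level = 2.0**best_right
    if bic_two < bic_one and not math.isclose(left_level, right_level):
        return BreakpointCall(
            changepoint=best_j,
            left_level=left_level,
            right_level=right_level,
            left_call=_snap(left_level, candidates),
            right_call=_snap(right_level, candidates),
            sse_two_segment=best_sse,
            sse_one_segment=sse_one,
            bic_two_segment=bic_two,
            bic_one_segment=bic_one,
        )
    flat = 2.0 ** y.mean()
    return BreakpointCall(
        changepoint=None,
        left_level=flat,
        right_level=flat,
        left_call=_snap(flat, candidates),
        right_call=_snap(flat, candidates),
        sse_two_segment=best_sse,
        sse_one_segment=sse_one,
        bic_two_segment=bic_two,
        bic_one_segment=bic_one,
    )
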