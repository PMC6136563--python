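"""Stress-to-movement calibration, prediction and clinical validation.

The core quantity of the package is the quadratic law linking von Mises
stress X (N/mm^2 = MPa) in the periodontal ligament at a root landmark to
the clinical tooth movement Y (mm) observed over the following month:

    Y = a * X**2 + b * X + c

The canonical coefficients, calibrated on the first patient's twelve
(stress, movement) pairs, are a = 2960, b = -254.56, c = 5.667.  The law is
non-monotone: movement is high at low stress, dips near X ~ 0.043 MPa and
rises again -- consistent with pressure-tension physiology (moderate stress
throttles blood flow and remodelling; higher stress recruits undermining
resorption).

This module also provides the measurement emulation used to obtain Y
clinically: rigid best-fit superimposition of serial dental models
(Kabsch algorithm on a stable palatal patch), per-landmark displacement,
and Dahlberg's method error for repeated measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuadraticLaw",
    "CalibrationPoint",
    "MovementRecord",
    "RigidTransform",
    "ValidationSummary",
    "FitReport",
    "CANONICAL_LAW",
    "predict",
    "fit",
    "rigid_superimpose",
    "landmark_displacement",
    "validate",
    "dahlberg_error",
    "round_half_away",
    "load_calibration_table",
    "load_validation_table",
]

LANDMARKS = ("C1D", "C2D", "C1M")


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero at `ndigits` decimals (display convention)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class QuadraticLaw:
    """Coefficients of Y = a X^2 + b X + c (Y in mm, X in N/mm^2)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.a, self.b, self.c)):
            raise ValueError("quadratic law coefficients must be finite")

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.a * np.square(x) + self.b * np.asarray(x) + self.c


#: Calibration on the first patient's twelve stress/movement pairs.
CANONICAL_LAW = QuadraticLaw(a=2960.0, b=-254.56, c=5.667)


@dataclass(frozen=True)
class CalibrationPoint:
    """One (landmark, period) calibration observation: stress and movement."""

    landmark: str
    period: str
    stress: float  # N/mm^2, measured at the period start
    movement: float  # mm, clinical movement over the following month

    def __post_init__(self) -> None:
        if self.stress <= 0:
            raise ValueError(f"stress must be > 0, got {self.stress}")
        if self.movement < 0:
            raise ValueError(f"movement must be >= 0, got {self.movement}")


@dataclass(frozen=True)
class MovementRecord:
    """Predicted vs clinical movement for one landmark and period.

    `predicted` is the unrounded law output; `diff` and `percent` are computed
    from the unrounded prediction against the (printed) clinical value.
    Display rounding: movement at 3 decimals, percent at 2.
    """

    landmark: str
    period: str
    stress: float
    predicted: float
    clinical: float

    @property
    def diff(self) -> float:
        return abs(self.predicted - self.clinical)

    @property
    def percent(self) -> float:
        return 100.0 * self.diff / self.predicted

    @property
    def predicted_display(self) -> float:
        return round_half_away(self.predicted, 3)

    @property
    def diff_display(self) -> float:
        return round_half_away(self.diff, 3)

    @property
    def percent_display(self) -> float:
        return round_half_away(self.percent, 2)


def predict(law: QuadraticLaw, stress: float) -> float:
    """Evaluate the movement law at stress X (N/mm^2); returns mm, unrounded.

    A negative result indicates X far outside the calibrated stress range;
    it is returned as-is (callers may warn).
    """
    if not math.isfinite(stress):
        raise ValueError("stress must be finite")
    return float(law(stress))


@dataclass(frozen=True)
class FitReport:
    law: QuadraticLaw
    residuals: np.ndarray  # observed - fitted, per point
    rmse: float
    n_points: int


def fit(
    points: Sequence[CalibrationPoint],
    exclude_landmarks: Iterable[str] = (),
) -> FitReport:
    """Ordinary least-squares quadratic fit of movement on stress.

    Parameters
    ----------
    points
        Calibration observations; at least 3 with 3 distinct stresses after
        filtering.
    exclude_landmarks
        Landmark ids to drop before fitting (e.g. ``["C1M"]`` to reproduce
        the sensitivity fit without the first patient's noisiest landmark).
    """
    excl = set(exclude_landmarks)
    pts = [p for p in points if p.landmark not in excl]
    x = np.array([p.stress for p in pts], dtype=float)
    y = np.array([p.movement for p in pts], dtype=float)
    if len(pts) < 3 or len(np.unique(x)) < 3:
        raise ValueError(
            "quadratic fit needs >= 3 points with >= 3 distinct stresses; "
            f"got {len(pts)} points, {len(np.unique(x))} distinct"
        )
    # highest degree first, as numpy returns it
    coeffs = np.polyfit(x, y, deg=2)
    law = QuadraticLaw(a=float(coeffs[0]), b=float(coeffs[1]), c=float(coeffs[2]))
    fitted = law(x)
    residuals = y - fitted
    rmse = float(np.sqrt(np.mean(residuals**2)))
    return FitReport(law=law, residuals=residuals, rmse=rmse, n_points=len(pts))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R @ x + t (rotation + translation, no scale)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or np.abs(R.T @ R - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation must be 3x3 orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.ndim(points) == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying `other` first, then `self`."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(rotation=np.eye(3), translation=np.zeros(3))


def rigid_superimpose(fixed: np.ndarray, moving: np.ndarray) -> RigidTransform:
    """Least-squares rigid registration (Kabsch) mapping `moving` onto `fixed`.

    Returns the proper rigid transform minimising
    sum_i || R @ moving_i + t - fixed_i ||^2.  Scaling is not estimated;
    serial dental models are metrically calibrated.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need matched (n, 3) point sets with n >= 3")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    # collinear (or coincident) clouds leave a rotation dof undetermined
    if np.linalg.matrix_rank(Pc, tol=1e-9 * max(1.0, np.abs(Pc).max())) < 2:
        raise ValueError("degenerate point set: points are collinear or coincident")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return RigidTransform(rotation=R, translation=t)


def landmark_displacement(
    transform: RigidTransform,
    landmarks_before: dict[str, np.ndarray],
    landmarks_after: dict[str, np.ndarray],
) -> dict[str, float]:
    """Per-landmark Euclidean displacement (mm) after superimposition.

    `transform` maps the later model into the earlier model's frame (the
    best-fit registration of the stable palatal region); each later landmark
    is brought into that frame and compared with its earlier position.
    """
    if set(landmarks_before) != set(landmarks_after):
        missing = set(landmarks_before) ^ set(landmarks_after)
        raise KeyError(f"landmark ids do not match: {sorted(missing)}")
    out = {}
    for name, before in landmarks_before.items():
        after = transform.apply(np.asarray(landmarks_after[name], dtype=float))
        out[name] = float(np.linalg.norm(after - np.asarray(before, dtype=float)))
    return out


@dataclass(frozen=True)
class ValidationSummary:
    """Range summary of predicted-vs-clinical agreement over all records."""

    records: tuple[MovementRecord, ...]
    min_diff: float
    max_diff: float
    min_percent: float
    max_percent: float
    min_predicted: float
    max_predicted: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "landmark": [r.landmark for r in self.records],
                "period": [r.period for r in self.records],
                "stress_MPa": [r.stress for r in self.records],
                "predicted_mm": [r.predicted_display for r in self.records],
                "clinical_mm": [r.clinical for r in self.records],
                "diff_mm": [r.diff_display for r in self.records],
                "percent": [r.percent_display for r in self.records],
            }
        )


def validate(records: Sequence[MovementRecord]) -> ValidationSummary:
    """Summarise agreement between predicted (F) and clinical (C) movement.

    Diffs |F - C| use the unrounded prediction; percent = 100 |F - C| / F.
    Display rounding (3 dp mm, 2 dp percent) is applied to the reported
    extremes, matching how such tables are printed.
    """
    if not records:
        raise ValueError("need at least one movement record")
    diffs = [r.diff for r in records]
    pcts = [r.percent for r in records]
    preds = [r.predicted for r in records]
    return ValidationSummary(
        records=tuple(records),
        min_diff=round_half_away(min(diffs), 3),
        max_diff=round_half_away(max(diffs), 3),
        min_percent=round_half_away(min(pcts), 2),
        max_percent=round_half_away(max(pcts), 2),
        min_predicted=round_half_away(min(preds), 3),
        max_predicted=round_half_away(max(preds), 3),
    )


def dahlberg_error(first: Sequence[float], second: Sequence[float]) -> float:
    """Dahlberg's method error sqrt(sum d_i^2 / 2n) over paired repeats (mm)."""
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("need two equal-length 1-d measurement lists, n >= 1")
    d = a - b
    return float(np.sqrt(np.sum(d * d) / (2.0 * d.size)))


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("orthofem.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_calibration_table(path: str | None = None) -> list[CalibrationPoint]:
    """Load the first patient's calibration table (packaged copy by default).

    Schema: landmark, stress_period, stress_MPa, movement_period, movement_mm.
    """
    df = pd.read_csv(path) if path is not None else _read_packaged_csv("calibration_patient1.csv")
    required = {"landmark", "stress_period", "stress_MPa", "movement_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"calibration table missing columns {sorted(required - set(df.columns))}")
    return [
        CalibrationPoint(
            landmark=row.landmark,
            period=row.stress_period,
            stress=float(row.stress_MPa),
            movement=float(row.movement_mm),
        )
        for row in df.itertuples()
    ]


def load_validation_table(path: str | None = None) -> pd.DataFrame:
    """Load the second patient's validation table (packaged copy by default).

    Schema: landmark, stress_period, stress_MPa, movement_period,
    predicted_mm, clinical_mm, diff_mm, percent (the last three as printed,
    used only for cross-checking recomputation).
    """
    df = pd.read_csv(path) if path is not None else _read_packaged_csv("validation_patient2.csv")
    required = {"landmark", "stress_period", "stress_MPa", "clinical_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"validation table missing columns {sorted(required - set(df.columns))}")
    return df


def records_from_table(df: pd.DataFrame, law: QuadraticLaw) -> list[MovementRecord]:
    """Build MovementRecords by evaluating `law` on a validation table."""
    return [
        MovementRecord(
            landmark=row.landmark,
            period=row.stress_period,
            stress=float(row.stress_MPa),
            predicted=predict(law, float(row.stress_MPa)),
            clinical=float(row.clinical_mm),
        )
        for row in df.itertuples()
    ]
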