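"""Y-chromosome detection-rate calibration and engraftment correction.

Sectioned nuclei are frequently truncated, so chromogenic in situ
hybridisation misses the Y chromosome in a compartment- and marker-dependent
fraction of truly male cells. The detection rate ``d`` is estimated from male
control tissue — where every cell is male — as the *unweighted* mean of the
per-sample Y+ fractions (each control sample counts as one unit, regardless
of how many cells it contributed; pooling counts would weight large sections
more heavily). Observed engraftment percentages from sex-mismatched
transplant cases are then corrected by division: ``corrected = raw / d``,
clamped at 100 % with an explicit flag when the clamp fires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import (
    CalibrationFallbackWarning,
    MissingCalibrationError,
    SchemaError,
    ZeroDetectionError,
)

__all__ = [
    "DetectionRate",
    "DetectionRateCalibrator",
    "estimate_detection_rate",
    "correct_engraftment",
]


@dataclass(frozen=True)
class DetectionRate:
    """Calibrated Y-chromosome detection rate for one (compartment, marker)."""

    compartment: str
    marker: str
    rate: float
    n_samples: int
    per_sample_fractions: tuple[float, ...]


def _rate_from_rows(rows: pd.DataFrame, compartment: str, marker: str) -> DetectionRate:
    if (rows["n_marker_pos"] <= 0).any():
        raise SchemaError(
            f"control rows for ({compartment}, {marker}) contain n_marker_pos <= 0"
        )
    fractions = (rows["n_y_pos"] / rows["n_marker_pos"]).to_numpy(dtype=float)
    rate = float(fractions.mean())
    if rate == 0.0:
        raise ZeroDetectionError(
            f"all control samples for ({compartment}, {marker}) have zero Y+ cells; "
            "the detection-rate correction is undefined"
        )
    return DetectionRate(
        compartment=compartment,
        marker=marker,
        rate=rate,
        n_samples=len(rows),
        per_sample_fractions=tuple(float(f) for f in fractions),
    )


def estimate_detection_rate(
    controls: pd.DataFrame, compartment: str, marker: str
) -> DetectionRate:
    """Estimate the detection rate for one (compartment, marker) from controls.

    ``controls`` follows the section-count schema; only rows with
    ``is_male_control`` true and matching labels are used. The rate is the
    unweighted arithmetic mean of per-sample fractions ``n_y_pos /
    n_marker_pos``.

    Raises
    ------
    MissingCalibrationError : no matching control rows.
    ZeroDetectionError : every matching control detected zero Y+ cells.
    """
    mask = (
        controls["is_male_control"].astype(bool)
        & (controls["compartment"] == compartment)
        & (controls["marker"] == marker)
    )
    rows = controls.loc[mask]
    if rows.empty:
        raise MissingCalibrationError(
            f"no male-control rows for compartment {compartment!r}, marker {marker!r}"
        )
    return _rate_from_rows(rows, compartment, marker)


def correct_engraftment(
    raw_pct: float, rate: "DetectionRate | float"
) -> tuple[float, bool]:
    """Divide a raw Y+ percentage by the detection rate, clamping at 100 %.

    Returns ``(corrected_pct, clamped)``; ``clamped`` is True when the
    division exceeded 100 % (a calibration artifact — the value is capped,
    never silently altered below 100).
    """
    r = rate.rate if isinstance(rate, DetectionRate) else float(rate)
    if not (0.0 <= raw_pct <= 100.0):
        raise ValueError(f"raw_pct: must lie in [0, 100], got {raw_pct}")
    if r <= 0:
        raise ZeroDetectionError("detection rate must be positive to correct")
    corrected = raw_pct / r
    if corrected > 100.0:
        return 100.0, True
    return corrected, False


class DetectionRateCalibrator(BaseEstimator):
    """Estimate per-(compartment, marker) detection rates and correct counts.

    scikit-learn style: ``fit`` consumes a male-control section-count table,
    ``transform`` converts a transplant section-count table into corrected
    engraftment percentages.

    Parameters
    ----------
    fallback_marker : marker whose compartment rate substitutes when a
        transplant marker has no marker-specific calibration (the pan-myeloid
        Iba1 stain by default). The substitution raises
        :class:`CalibrationFallbackWarning`.

    Attributes
    ----------
    rates_ : dict mapping ``(compartment, marker)`` to :class:`DetectionRate`.
    summary_ : tidy DataFrame (compartment, marker, rate, n_samples).
    """

    def __init__(self, fallback_marker: str = "Iba1"):
        self.fallback_marker = fallback_marker

    def fit(self, controls: pd.DataFrame, y=None) -> "DetectionRateCalibrator":
        rows = controls.loc[controls["is_male_control"].astype(bool)]
        if rows.empty:
            raise MissingCalibrationError("no male-control rows in the calibration table")
        rates: dict[tuple[str, str], DetectionRate] = {}
        for (compartment, marker), grp in rows.groupby(["compartment", "marker"], sort=True):
            rates[(compartment, marker)] = _rate_from_rows(grp, compartment, marker)
        self.rates_ = rates
        self.summary_ = pd.DataFrame(
            [
                {
                    "compartment": dr.compartment,
                    "marker": dr.marker,
                    "rate": dr.rate,
                    "n_samples": dr.n_samples,
                }
                for dr in rates.values()
            ]
        )
        return self

    def rate_for(self, compartment: str, marker: str) -> DetectionRate:
        """Look up a rate, falling back to the compartment's pan-myeloid rate."""
        if not hasattr(self, "rates_"):
            raise MissingCalibrationError("calibrator is not fitted")
        key = (compartment, marker)
        if key in self.rates_:
            return self.rates_[key]
        fallback = (compartment, self.fallback_marker)
        if fallback in self.rates_:
            warnings.warn(
                f"no control calibration for ({compartment}, {marker}); "
                f"falling back to the {self.fallback_marker} rate of {compartment}",
                CalibrationFallbackWarning,
                stacklevel=2,
            )
            return self.rates_[fallback]
        raise MissingCalibrationError(
            f"no calibration for compartment {compartment!r} "
            f"(marker {marker!r} or fallback {self.fallback_marker!r})"
        )

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        """Correct a transplant section-count table.

        Returns one row per input row with ``raw_pct`` (= 100 * n_y_pos /
        n_marker_pos), ``corrected_pct`` and the ``clamped`` flag, keeping
        patient, compartment, marker and time columns.
        """
        rows = counts.loc[~counts["is_male_control"].astype(bool)]
        if (rows["n_marker_pos"] <= 0).any():
            raise SchemaError("transplant rows with n_marker_pos <= 0 cannot be corrected")
        out = []
        for _, row in rows.iterrows():
            rate = self.rate_for(row["compartment"], row["marker"])
            raw = 100.0 * row["n_y_pos"] / row["n_marker_pos"]
            corrected, clamped = correct_engraftment(raw, rate)
            out.append(
                {
                    "patient_id": row["patient_id"],
                    "compartment": row["compartment"],
                    "marker": row["marker"],
                    "days_post_transplant": row["days_post_transplant"],
                    "raw_pct": raw,
                    "corrected_pct": corrected,
                    "clamped": clamped,
                }
            )
        return pd.DataFrame(
            out,
            columns=[
                "patient_id",
                "compartment",
                "marker",
                "days_post_transplant",
                "raw_pct",
                "corrected_pct",
                "clamped",
            ],
        )

    def fit_transform(self, controls: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
        return self.fit(controls).transform(counts)
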