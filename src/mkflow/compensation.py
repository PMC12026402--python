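"""Spillover estimation from single-stain controls and compensation.

Fluorophores emit into more than their primary detection channel; the
spillover matrix S (entry ``S[i, j]`` = fraction of fluorophore-i signal
detected in channel j, diagonal 1) is estimated from single-stained
control events by zero-intercept least squares — for control i, the slope
of channel-j total intensity regressed on channel-i total intensity.
Compensation right-multiplies each event's intensity vector by S⁻¹.

Compensation acts on scalar per-event channel intensities, not on pixel
rasters: the gates downstream consume intensities.  The Raw Max Pixel
feature is by contract a *raw* (pre-compensation) feature and is never
touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .event_model import EventSet

__all__ = ["SpilloverMatrix", "estimate_spillover", "apply_compensation"]

MIN_CONTROL_EVENTS = 30


@dataclass(frozen=True)
class SpilloverMatrix:
    """Square spillover matrix with its channel (marker) order."""

    matrix: np.ndarray
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        k = len(self.markers)
        if m.shape != (k, k):
            raise ValueError("matrix must be square over the declared markers")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("spillover diagonal must be 1")
        if (m < 0).any():
            raise ValueError("spillover entries must be non-negative")
        if not np.isfinite(np.linalg.cond(m)):
            raise ValueError("spillover matrix is singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "markers", tuple(self.markers))

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.matrix, index=list(self.markers), columns=list(self.markers)
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), tuple(df.columns))


def _control_intensities(
    control: EventSet | pd.DataFrame, markers: list[str]
) -> pd.DataFrame:
    if isinstance(control, EventSet):
        from .morphometry import compute_features

        control = compute_features(control)
    cols = [f"intensity_{m}" for m in markers]
    missing = [c for c in cols if c not in control.columns]
    if missing:
        raise ValueError(f"control table lacks columns {missing}")
    return control[cols]


def estimate_spillover(
    controls: dict[str, EventSet | pd.DataFrame],
    markers: list[str] | None = None,
    min_events: int = MIN_CONTROL_EVENTS,
) -> SpilloverMatrix:
    """Estimate spillover from single-stain controls.

    ``controls`` maps marker → events (EventSet, or a feature table with
    ``intensity_<marker>`` columns) stained for exactly that fluorophore.
    Entry (i, j) is the zero-intercept least-squares slope of channel-j
    intensity on channel-i intensity over control-i events; the diagonal
    is forced to 1 and negative slopes are clamped to 0.
    """
    if markers is None:
        markers = list(controls)
    k = len(markers)
    m = np.eye(k)
    for i, marker in enumerate(markers):
        if marker not in controls:
            raise ValueError(f"no control provided for marker {marker!r}")
        tbl = _control_intensities(controls[marker], markers)
        if len(tbl) < min_events:
            raise ValueError(
                f"control {marker!r}: {len(tbl)} events < required {min_events}"
            )
        x = tbl[f"intensity_{marker}"].to_numpy(float)
        sxx = float(x @ x)
        if sxx == 0 or np.ptp(x) == 0:
            raise ValueError(f"control {marker!r}: constant primary intensity")
        for j, other in enumerate(markers):
            if j == i:
                continue
            y = tbl[f"intensity_{other}"].to_numpy(float)
            m[i, j] = max(float(x @ y) / sxx, 0.0)
    return SpilloverMatrix(m, tuple(markers))


def apply_compensation(
    data: EventSet | pd.DataFrame, spill: SpilloverMatrix
) -> pd.DataFrame:
    """Compensate per-event intensities: right-multiply by the inverse.

    Accepts an EventSet (features are computed first) or a feature table;
    returns a table in which ``intensity_<marker>`` columns are replaced
    by compensated values.  ``raw_max_pixel_*`` columns are untouched.
    """
    if isinstance(data, EventSet):
        from .morphometry import compute_features

        data = compute_features(data)
    table = data.copy()
    cols = [f"intensity_{m}" for m in spill.markers]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    observed = table[cols].to_numpy(float)
    table[cols] = observed @ spill.inverse
    return table
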