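"""Linear-discriminant singlet/doublet classifier.

Large megakaryocytes overlap cell aggregates in a conventional BF-Area ×
Aspect-Ratio singlet gate, so singlets are instead separated from
doublets by a two-class linear discriminant over mask morphometrics and
intensities of the brightfield and CD41 channels.  The classifier is
constructed so the decision boundary sits exactly at score 0 (the
midpoint of the standardized class means) with singlets scoring
positive, and the score is divided by the pooled within-class standard
deviation of training scores so the "keep score ≥ 0" gate is scale-free.

Fisher LDA with a ridge-regularized pooled covariance:
``w ∝ (S_pooled + λI)⁻¹ (μ_singlet − μ_doublet)``, λ = 1e-3·tr(S)/p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .event_model import EventSet
from .morphometry import LDA_FEATURES

__all__ = [
    "SingletClassifier",
    "fit_singlet_classifier",
    "fit_singlet_classifier_from_features",
]

_RIDGE_FACTOR = 1e-3


@dataclass
class SingletClassifier:
    """Affine discriminant over standardized features; ≥ 0 ⇒ singlet."""

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    offset: float

    def score(self, features: Mapping[str, float] | pd.Series) -> float:
        """Discriminant score of one event; missing feature is an error."""
        x = np.empty(len(self.feature_names))
        for i, name in enumerate(self.feature_names):
            if name not in features:
                raise KeyError(f"feature {name!r} missing from event features")
            x[i] = float(features[name])
        if not np.isfinite(x).all():
            raise ValueError("non-finite feature value; cannot score event")
        z = (x - self.means) / self.sds
        return float(z @ self.weights + self.offset)

    def score_table(self, table: pd.DataFrame) -> pd.Series:
        """Vectorized scores; rows with non-finite features get NaN."""
        x = table[self.feature_names].to_numpy(float)
        z = (x - self.means) / self.sds
        s = z @ self.weights + self.offset
        s[~np.isfinite(x).all(axis=1)] = np.nan
        return pd.Series(s, index=table.index, name="singlet_score")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": self.feature_names,
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "weights": self.weights.tolist(),
                    "offset": self.offset,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SingletClassifier":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=list(d["feature_names"]),
            means=np.array(d["means"], float),
            sds=np.array(d["sds"], float),
            weights=np.array(d["weights"], float),
            offset=float(d["offset"]),
        )


def fit_singlet_classifier_from_features(
    singlets: pd.DataFrame,
    doublets: pd.DataFrame,
    feature_names: Sequence[str] | None = None,
) -> SingletClassifier:
    """Fit the discriminant from per-class feature tables."""
    if feature_names is None:
        feature_names = [f for f in LDA_FEATURES if f in singlets.columns]
        if not feature_names:  # ad-hoc tables: use all shared numeric columns
            feature_names = [
                c
                for c in singlets.columns
                if c in doublets.columns
                and np.issubdtype(singlets[c].dtype, np.number)
            ]
    feature_names = list(feature_names)
    xs = singlets[feature_names].to_numpy(float)
    xd = doublets[feature_names].to_numpy(float)
    xs = xs[np.isfinite(xs).all(axis=1)]
    xd = xd[np.isfinite(xd).all(axis=1)]
    for name, x in (("singlet", xs), ("doublet", xd)):
        if x.shape[0] < 2:
            raise ValueError(f"{name} truth population needs ≥ 2 usable events")
        if np.unique(x, axis=0).shape[0] < 2:
            raise ValueError(f"{name} truth population is degenerate (no variation)")

    pooled_all = np.vstack([xs, xd])
    means = pooled_all.mean(axis=0)
    sds = pooled_all.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = [feature_names[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"features with zero variance: {bad}")
    zs, zd = (xs - means) / sds, (xd - means) / sds

    ns, nd = len(zs), len(zd)
    cov_s = np.cov(zs, rowvar=False, ddof=1)
    cov_d = np.cov(zd, rowvar=False, ddof=1)
    pooled = ((ns - 1) * cov_s + (nd - 1) * cov_d) / (ns + nd - 2)
    pooled = np.atleast_2d(pooled)
    p = len(feature_names)
    lam = _RIDGE_FACTOR * np.trace(pooled) / p
    pooled_r = pooled + lam * np.eye(p)
    try:
        w = np.linalg.solve(pooled_r, zs.mean(axis=0) - zd.mean(axis=0))
    except np.linalg.LinAlgError as err:
        raise ValueError("pooled covariance singular after regularization") from err
    if not np.isfinite(w).all():
        raise ValueError("non-finite discriminant weights")

    midpoint = (zs.mean(axis=0) + zd.mean(axis=0)) / 2.0
    offset = -float(w @ midpoint)
    # orientation: singlets positive (guaranteed for PD matrices, enforced anyway)
    if float(zs.mean(axis=0) @ w + offset) < 0:
        w, offset = -w, -offset

    # scale-free score: unit pooled within-class SD of raw scores
    raw_s, raw_d = zs @ w + offset, zd @ w + offset
    var_pool = (
        (ns - 1) * np.var(raw_s, ddof=1) + (nd - 1) * np.var(raw_d, ddof=1)
    ) / (ns + nd - 2)
    sd_pool = float(np.sqrt(var_pool))
    if sd_pool > 0:
        w, offset = w / sd_pool, offset / sd_pool

    return SingletClassifier(
        feature_names=feature_names,
        means=means,
        sds=sds,
        weights=w,
        offset=offset,
    )


def fit_singlet_classifier(
    truth_singlets: EventSet | pd.DataFrame,
    truth_doublets: EventSet | pd.DataFrame,
    feature_names: Sequence[str] | None = None,
) -> SingletClassifier:
    """Fit from manually tagged truth populations (events or features)."""
    from .morphometry import compute_features

    if isinstance(truth_singlets, EventSet):
        truth_singlets = compute_features(truth_singlets)
    if isinstance(truth_doublets, EventSet):
        truth_doublets = compute_features(truth_doublets)
    return fit_singlet_classifier_from_features(
        truth_singlets, truth_doublets, feature_names
    )
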