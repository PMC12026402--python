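"""Hierarchical gating cascade with per-gate attrition reporting.

The cascade identifies cells of the megakaryocytic lineage in the
conventional order: stable flow → non-saturated → live → nucleated →
lymphocyte exclusion → CD41⁺ dump⁻ → singlet (discriminant score ≥ 0) →
in focus → CNN-confirmed CD41 membrane.  Each gate is an explicit,
reproducible rule; thresholds the original workflow placed by eye are
parameterized in :class:`GateConfig` with documented automatic rules.

Automatic intensity thresholds use Otsu's method on log1p intensities,
guarded by a minimum log-separation between the two Otsu classes: when a
column is effectively unimodal (no second population to cut away) the
gate keeps everything rather than slicing noise in half.  Auto
thresholds are resolved once, on the population surviving the saturation
gate, and then applied as fixed values.

Every gate's pass criterion is evaluated for *every* event; the cascade
itself is the running intersection, so independent gates commute and the
per-gate report fractions re-multiply exactly to the terminal fraction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import filters

from .event_model import EventSet

__all__ = [
    "GateConfig",
    "GatingReport",
    "STAGES",
    "gate_stable_flow",
    "gate_unsaturated",
    "gate_live_nucleated",
    "gate_exclude_lymphocytes",
    "gate_cd41_dump",
    "gate_focus",
    "run_cascade",
]

log = logging.getLogger(__name__)

STAGES = (
    "stable_flow",
    "unsaturated",
    "live",
    "nucleated",
    "lymphocyte",
    "cd41_dump",
    "singlet",
    "focus",
    "cnn",
)

AUTO = "auto"


@dataclass(frozen=True)
class GateConfig:
    """All cascade thresholds; defaults follow conventional settings."""

    saturation_max_raw_pixel: int = 4030  # keep strictly below
    focus_min_gradient_rms: float = 55.0  # keep strictly above
    singlet_min_score: float = 0.0  # keep score ≥ 0
    viability_max: float | str = AUTO
    dna_min: float | str = AUTO
    cd41_min: float | str = AUTO
    dump_max: float | str = AUTO
    cd45_min: float | str = AUTO
    ssc_max: float | str = AUTO
    lymph_auto_mode: str = "otsu"  # or "percentile" (75th/25th)
    stable_flow: str | tuple[float, float] = AUTO
    time_bin_s: float = 5.0
    stable_flow_nsd: float = 3.0
    saturation_channels: tuple[str, ...] | None = None  # None = all markers
    min_log_separation: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "saturation_max_raw_pixel",
            "focus_min_gradient_rms",
            "singlet_min_score",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


# ---------------------------------------------------------------------------
# Auto-threshold machinery
# ---------------------------------------------------------------------------


def _otsu_threshold(values: np.ndarray, min_log_separation: float) -> float | None:
    """Guarded Otsu cut on log1p values; None when effectively unimodal.

    Integrated intensities scale with cell area, so a single population
    already spans >1 decade; a split only counts as bimodal when the two
    Otsu class means differ by ``min_log_separation`` log units.  The
    returned threshold is the geometric midpoint of the class means —
    mid-gap placement rather than the mode edge Otsu itself favours for
    very unbalanced modes.
    """
    v = np.log1p(np.asarray(values, float))
    v = v[np.isfinite(v)]
    if v.size < 2:
        return None
    if np.ptp(v) == 0:
        raise ValueError(
            "degenerate single-valued intensity column: auto threshold "
            "impossible, supply an explicit threshold"
        )
    t = filters.threshold_otsu(v)
    lo, hi = v[v <= t], v[v > t]
    if lo.size == 0 or hi.size == 0:
        return None
    if hi.mean() - lo.mean() < min_log_separation:
        return None
    return float(np.expm1((lo.mean() + hi.mean()) / 2.0))


def _resolve(
    setting: float | str,
    values: np.ndarray,
    cfg: GateConfig,
    unimodal_default: float,
) -> float:
    """Fixed setting passes through; AUTO resolves via guarded Otsu."""
    if setting != AUTO:
        return float(setting)
    t = _otsu_threshold(values, cfg.min_log_separation)
    return unimodal_default if t is None else t


# ---------------------------------------------------------------------------
# Individual gates: each returns the surviving object_ids
# ---------------------------------------------------------------------------


def _ids(features: pd.DataFrame, keep: np.ndarray) -> pd.Index:
    return features.index[np.asarray(keep, bool)]


def stable_flow_window(
    times: np.ndarray, cfg: GateConfig
) -> tuple[float, float]:
    """Largest contiguous time span with per-bin counts inside robust bounds.

    Bin counts within median ± nsd robust SDs are "stable"; robust SD is
    1.4826·MAD floored at sqrt(median) (the Poisson noise floor, so a flat
    stream is never fragmented by counting noise).
    """
    t0, t1 = float(times.min()), float(times.max())
    t0 = np.floor(t0 / cfg.time_bin_s) * cfg.time_bin_s  # origin-aligned bins
    edges = np.arange(t0, t1 + cfg.time_bin_s, cfg.time_bin_s)
    if len(edges) < 3:
        warnings.warn("fewer than 2 time bins: keeping all events")
        return (-np.inf, np.inf)
    counts, _ = np.histogram(times, bins=edges)
    med = float(np.median(counts))
    mad = float(np.median(np.abs(counts - med)))
    rsd = max(1.4826 * mad, np.sqrt(max(med, 1.0)))
    ok = np.abs(counts - med) <= cfg.stable_flow_nsd * rsd
    # largest run of consecutive stable bins
    best_len, best_start, run_start = 0, 0, None
    for i, good in enumerate(list(ok) + [False]):
        if good and run_start is None:
            run_start = i
        elif not good and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len == 0:
        warnings.warn("no stable time bins found: keeping all events")
        return (-np.inf, np.inf)
    return float(edges[best_start]), float(edges[best_start + best_len])


def gate_stable_flow(features: pd.DataFrame, cfg: GateConfig) -> pd.Index:
    """Select events acquired in steady flow (time-density criterion)."""
    times = features["time_s"].to_numpy(float)
    if cfg.stable_flow == AUTO:
        lo, hi = stable_flow_window(times, cfg)
    else:
        lo, hi = cfg.stable_flow
    return _ids(features, (times >= lo) & (times <= hi))


def gate_unsaturated(
    features: pd.DataFrame, cfg: GateConfig, markers: tuple[str, ...] | None = None
) -> pd.Index:
    """Keep events below the saturation ceiling in every used channel."""
    if markers is None:
        markers = cfg.saturation_channels
    if markers is None:
        markers = tuple(
            c.removeprefix("raw_max_pixel_")
            for c in features.columns
            if c.startswith("raw_max_pixel_")
        )
    keep = np.ones(len(features), bool)
    for m in markers:
        keep &= (
            features[f"raw_max_pixel_{m}"].to_numpy(float)
            < cfg.saturation_max_raw_pixel
        )
    return _ids(features, keep)


def _live_keep(features: pd.DataFrame, cfg: GateConfig) -> np.ndarray:
    v = features["intensity_viability"].to_numpy(float)
    t = _resolve(cfg.viability_max, v, cfg, unimodal_default=np.inf)
    return v <= t


def _nucleated_keep(features: pd.DataFrame, cfg: GateConfig) -> np.ndarray:
    d = features["intensity_dna"].to_numpy(float)
    t = _resolve(cfg.dna_min, d, cfg, unimodal_default=-np.inf)
    return d > t


def gate_live_nucleated(features: pd.DataFrame, cfg: GateConfig) -> pd.Index:
    """Viability-dye negative/low AND DNA-dye positive."""
    return _ids(features, _live_keep(features, cfg) & _nucleated_keep(features, cfg))


def _lymphocyte_exclude(features: pd.DataFrame, cfg: GateConfig) -> np.ndarray:
    cd45 = features["intensity_cd45"].to_numpy(float)
    ssc = features["intensity_ssc"].to_numpy(float)
    if cfg.lymph_auto_mode == "percentile":
        t_cd45 = (
            float(np.nanpercentile(cd45, 75)) if cfg.cd45_min == AUTO else float(cfg.cd45_min)
        )
        t_ssc = (
            float(np.nanpercentile(ssc, 25)) if cfg.ssc_max == AUTO else float(cfg.ssc_max)
        )
    else:
        t_cd45 = _resolve(cfg.cd45_min, cd45, cfg, unimodal_default=np.inf)
        t_ssc = _resolve(cfg.ssc_max, ssc, cfg, unimodal_default=-np.inf)
    return (cd45 > t_cd45) & (ssc < t_ssc)


def gate_exclude_lymphocytes(features: pd.DataFrame, cfg: GateConfig) -> pd.Index:
    """Remove the CD45-high / SSC-low region."""
    return _ids(features, ~_lymphocyte_exclude(features, cfg))


def gate_cd41_dump(features: pd.DataFrame, cfg: GateConfig) -> pd.Index:
    """CD41-positive AND negative for every pooled dump-channel marker."""
    cd41 = features["intensity_cd41"].to_numpy(float)
    dump = features["intensity_dump"].to_numpy(float)
    t_cd41 = _resolve(cfg.cd41_min, cd41, cfg, unimodal_default=-np.inf)
    t_dump = _resolve(cfg.dump_max, dump, cfg, unimodal_default=np.inf)
    return _ids(features, (cd41 > t_cd41) & (dump <= t_dump))


def gate_focus(features: pd.DataFrame, cfg: GateConfig) -> pd.Index:
    """Keep in-focus events: brightfield gradient RMS above the floor."""
    rms = features["gradient_rms_bf"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        keep = rms > cfg.focus_min_gradient_rms
    return _ids(features, np.nan_to_num(keep, nan=0).astype(bool))


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------


@dataclass
class GatingReport:
    """Ordered attrition report plus per-event pass flags."""

    stages: list[dict]
    pass_table: pd.DataFrame
    terminal_ids: list[int]
    diameter_histogram: dict | None = None
    thresholds: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def terminal_fraction(self) -> float:
        total = self.stages[0]["n_in"] if self.stages else 0
        return len(self.terminal_ids) / total if total else 0.0

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "terminal_ids": [int(i) for i in self.terminal_ids],
            "terminal_fraction": self.terminal_fraction,
            "diameter_histogram": self.diameter_histogram,
            "thresholds": self.thresholds,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


_ORACLE_RULES = {
    "stable_flow": lambda t: t["is_stable"],
    "unsaturated": lambda t: ~t["is_saturated"],
    "live": lambda t: t["is_viable"],
    "nucleated": lambda t: t["is_nucleated"],
    "lymphocyte": lambda t: t["label"] != "lymphocyte",
    "cd41_dump": lambda t: t["cd41_positive"] & t["dump_negative"],
    "singlet": lambda t: t["is_singlet"],
    "focus": lambda t: t["is_in_focus"],
    "cnn": lambda t: t["cd41_membrane"],
}


def _resolved_thresholds(features: pd.DataFrame, cfg: GateConfig) -> GateConfig:
    """Freeze AUTO settings against the given reference population."""

    def res(setting, column, default):
        if setting != AUTO:
            return float(setting)
        t = _otsu_threshold(features[column].to_numpy(float), cfg.min_log_separation)
        return default if t is None else t

    out = {
        "viability_max": res(cfg.viability_max, "intensity_viability", np.inf),
        "dna_min": res(cfg.dna_min, "intensity_dna", -np.inf),
        "cd41_min": res(cfg.cd41_min, "intensity_cd41", -np.inf),
        "dump_max": res(cfg.dump_max, "intensity_dump", np.inf),
    }
    if cfg.lymph_auto_mode == "percentile":
        cd45 = features["intensity_cd45"].to_numpy(float)
        ssc = features["intensity_ssc"].to_numpy(float)
        out["cd45_min"] = (
            float(np.nanpercentile(cd45, 75)) if cfg.cd45_min == AUTO else cfg.cd45_min
        )
        out["ssc_max"] = (
            float(np.nanpercentile(ssc, 25)) if cfg.ssc_max == AUTO else cfg.ssc_max
        )
    else:
        out["cd45_min"] = res(cfg.cd45_min, "intensity_cd45", np.inf)
        out["ssc_max"] = res(cfg.ssc_max, "intensity_ssc", -np.inf)
    return replace(cfg, **out)


def run_cascade(
    events: EventSet | None,
    features: pd.DataFrame | None = None,
    cfg: GateConfig = GateConfig(),
    singlet_classifier=None,
    cnn_model=None,
    truth: pd.DataFrame | None = None,
    oracle: bool = False,
    stages: tuple[str, ...] | None = None,
) -> GatingReport:
    """Apply the gating cascade and report per-gate attrition.

    In oracle mode every gate decision comes from the ground-truth table
    (used to validate the cascade plumbing and as the separability budget
    of the synthetic generator).  In feature mode, gates act on the
    feature table; the singlet stage requires a fitted discriminant, and
    the CNN stage runs only when a model is supplied.

    ``stages`` restricts which gates run (order is always the canonical
    one); an empty tuple makes the cascade the identity.
    """
    if stages is None:
        stages = STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)

    if oracle and truth is None:
        raise ValueError("oracle mode requires a ground-truth table")
    if features is None:
        if events is None:
            raise ValueError("need events or a feature table")
        from .morphometry import compute_features

        features = compute_features(events)

    index = features.index
    if len(index) == 0:
        empty = pd.DataFrame(index=index)
        return GatingReport(
            stages=[
                {"name": s, "n_in": 0, "n_out": 0, "fraction": 0.0} for s in stages
            ],
            pass_table=empty,
            terminal_ids=[],
        )

    thresholds_used: dict[str, float] = {}
    if oracle:
        truth = truth.loc[index]
        passes = {s: _ORACLE_RULES[s](truth).to_numpy(bool) for s in stages}
    else:
        if "singlet" in stages and singlet_classifier is None:
            raise ValueError("singlet stage enabled but no classifier supplied")
        if "cnn" in stages and cnn_model is None:
            stages = tuple(s for s in stages if s != "cnn")
            log.info("no CNN model supplied: cnn stage skipped")

        # freeze auto thresholds on the post-saturation population
        ref_ids = gate_stable_flow(features, cfg)
        ref = features.loc[ref_ids]
        ref = ref.loc[gate_unsaturated(ref, cfg)]
        rcfg = _resolved_thresholds(ref if len(ref) else features, cfg)
        thresholds_used = {
            k: getattr(rcfg, k)
            for k in (
                "viability_max",
                "dna_min",
                "cd41_min",
                "dump_max",
                "cd45_min",
                "ssc_max",
            )
        }

        passes = {}
        for s in stages:
            if s == "stable_flow":
                ids = gate_stable_flow(features, rcfg)
            elif s == "unsaturated":
                ids = gate_unsaturated(features, rcfg)
            elif s == "live":
                ids = _ids(features, _live_keep(features, rcfg))
            elif s == "nucleated":
                ids = _ids(features, _nucleated_keep(features, rcfg))
            elif s == "lymphocyte":
                ids = gate_exclude_lymphocytes(features, rcfg)
            elif s == "cd41_dump":
                ids = gate_cd41_dump(features, rcfg)
            elif s == "singlet":
                scores = singlet_classifier.score_table(features)
                ids = features.index[
                    (scores >= rcfg.singlet_min_score).fillna(False).to_numpy()
                ]
            elif s == "focus":
                ids = gate_focus(features, rcfg)
            elif s == "cnn":
                from .cnn import POSITIVE, crop_event, predict

                crops = np.stack(
                    [crop_event(ev, events.panel) for ev in events]
                )
                pred = predict(cnn_model, crops)
                ok_ids = set(
                    np.asarray(events.object_ids)[
                        (pred["label"] == POSITIVE).to_numpy()
                    ].tolist()
                )
                ids = features.index[[i in ok_ids for i in features.index]]
            passes[s] = features.index.isin(ids)

    pass_table = pd.DataFrame(passes, index=index)
    stage_rows = []
    alive = np.ones(len(index), bool)
    for s in stages:
        n_in = int(alive.sum())
        alive = alive & passes[s]
        n_out = int(alive.sum())
        stage_rows.append(
            {
                "name": s,
                "n_in": n_in,
                "n_out": n_out,
                "fraction": (n_out / n_in) if n_in else 0.0,
            }
        )
    terminal_ids = [int(i) for i in index[alive]]

    hist = None
    if "diameter_bf" in features.columns and terminal_ids:
        diams = features.loc[terminal_ids, "diameter_bf"].dropna().to_numpy()
        counts, edges = np.histogram(diams, bins=np.arange(0, 62.5, 2.5))
        hist = {"bin_edges_um": edges.tolist(), "counts": counts.tolist()}

    return GatingReport(
        stages=stage_rows,
        pass_table=pass_table,
        terminal_ids=terminal_ids,
        diameter_histogram=hist,
        thresholds=thresholds_used,
        provenance={"oracle": oracle, "stages": list(stages)},
    )
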