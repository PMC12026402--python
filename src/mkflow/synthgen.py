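"""Parametric renderer of ground-truth-labeled synthetic IFC galleries.

No public image data accompany megakaryocyte (MK) imaging-flow-cytometry
studies, so this module renders labeled galleries that emulate every
event phenotype the gating cascade and the CNN must handle:

* ``mk`` — large cells (log-normal diameters, median 22.5 µm, truncated
  to the 10.5–51.5 µm range observed for human marrow MKs) with a true
  CD41⁺ membrane: many discrete spots on the cell perimeter.
* ``micro_mk`` — small MKs, 7–15 µm, same membrane signal.
* ``platelet_adherent`` — CD41⁻ cells carrying 1–4 bright ~2 µm CD41⁺
  platelet spots off the perimeter; the false-positive phenotype the CNN
  must reject.
* ``lymphocyte`` — CD45-high / SSC-low, dump-channel positive.
* ``dead`` — viability-dye positive.
* ``anucleate`` — no DNA signal.
* ``doublet`` — two touching cells, each with an MK membrane signal.

The brightfield texture is a high-contrast period-4 phase-randomized
checker: its central-difference gradient RMS sits near 70 in focus and
collapses under defocus blur, placing the in-focus/defocused boundary
around the conventional sharpness threshold of 55.  Noise follows a
standard camera model — Poisson shot noise plus Gaussian read noise —
with clipping to the bit depth, so saturated events are genuine.

Generation is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .event_model import DEFAULT_PANEL, EventImage, EventSet, PanelConfig

__all__ = [
    "SyntheticConfig",
    "CLASSES",
    "generate_event_set",
    "render_event",
    "apply_defocus",
    "make_cascade_fixture",
    "generate_compensation_controls",
]

CLASSES = (
    "mk",
    "micro_mk",
    "platelet_adherent",
    "lymphocyte",
    "dead",
    "anucleate",
    "doublet",
)

_DEFAULT_MIXTURE = {
    "mk": 0.35,
    "micro_mk": 0.05,
    "platelet_adherent": 0.15,
    "lymphocyte": 0.20,
    "dead": 0.08,
    "anucleate": 0.07,
    "doublet": 0.10,
}

# Per-class mean pixel amplitudes (12-bit counts) inside the cell disc.
# The field reports no physical intensity units; these scales are free
# parameters chosen so that integrated (area-summed) intensities of the
# populations stay resolved on log axes even though MK areas span ~25×:
# markers that define a gate differ by ≥ 30× in per-pixel amplitude.
_CLASS_AMPLITUDES: dict[str, dict[str, float]] = {
    #                     cd45   ssc   dump viability
    "mk":                {"cd45": 30, "ssc": 400, "dump": 1, "viability": 4},
    "micro_mk":          {"cd45": 30, "ssc": 400, "dump": 1, "viability": 4},
    "doublet":           {"cd45": 30, "ssc": 400, "dump": 1, "viability": 4},
    "platelet_adherent": {"cd45": 150, "ssc": 450, "dump": 1, "viability": 4},
    "lymphocyte":        {"cd45": 2000, "ssc": 30, "dump": 600, "viability": 4},
    "dead":              {"cd45": 100, "ssc": 300, "dump": 1, "viability": 1500},
    "anucleate":         {"cd45": 5, "ssc": 60, "dump": 1, "viability": 4},
}

_DNA_AMPLITUDE = 900.0
_DUMP_POSITIVE_AMPLITUDE = 600.0
_BF_LO, _BF_HI = 80.0, 3700.0
_SATURATION_LEVEL = 4030


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for synthetic gallery generation."""

    n_events: int = 500
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIXTURE)
    )
    # MK diameters: log-normal, median 22.5 µm, truncated to [10.5, 51.5]
    mk_diameter_median_um: float = 22.5
    mk_diameter_log_sd: float = 0.32
    mk_diameter_range_um: tuple[float, float] = (10.5, 51.5)
    micro_mk_diameter_range_um: tuple[float, float] = (7.0, 15.0)
    # doublet components kept moderate so the pair fits the field of view
    doublet_component_range_um: tuple[float, float] = (10.0, 22.0)
    lymphocyte_diameter_range_um: tuple[float, float] = (8.0, 11.0)
    other_diameter_range_um: tuple[float, float] = (9.0, 16.0)
    # CD41 signal geometry
    membrane_spot_count: tuple[int, int] = (8, 24)
    membrane_spot_amp: float = 500.0
    platelet_spots: tuple[int, int] = (1, 4)
    platelet_spot_amp: float = 1500.0
    spot_sigma_px: float = 1.5  # ≈ 2 µm spot diameter at 0.5 µm/px
    # optics / camera
    defocus_fraction: float = 0.08
    blur_sigma: float = 3.0
    saturated_fraction: float = 0.05
    noise_poisson_scale: float = 1.0
    read_noise_sd: float = 3.0
    background: float = 30.0
    # acquisition timeline
    duration_s: float = 300.0
    flow_instability: float = 0.05
    unstable_window_s: tuple[float, float] = (100.0, 110.0)
    seed: int = 0
    canvas_px: int = 120

    def __post_init__(self) -> None:
        total = float(sum(self.class_mixture.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture must sum to 1, got {total}")
        unknown = set(self.class_mixture) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in mixture: {sorted(unknown)}")
        for name in ("defocus_fraction", "saturated_fraction", "flow_instability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.mk_diameter_range_um
        if not (0 < lo < hi):
            raise ValueError("diameter bounds must be positive and ordered")
        object.__setattr__(self, "class_mixture", dict(self.class_mixture))


# ---------------------------------------------------------------------------
# Primitive painters
# ---------------------------------------------------------------------------


def _disc(canvas: int, cy: float, cx: float, radius_px: float) -> np.ndarray:
    yy, xx = np.mgrid[0:canvas, 0:canvas]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2


def _bf_texture(canvas: int, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized period-4 XOR checker, high contrast.

    A period-4 square wave has |central difference| = amplitude/2 at every
    pixel; XOR-ing two orthogonal waves makes both gradient components
    full-amplitude everywhere, so in-focus masks score a gradient RMS of
    roughly sqrt(2)/2 × amplitude on the [0, 100] normalized scale (~60),
    while modest defocus blur erases the period-4 component entirely.
    """
    py, px = rng.integers(0, 4, size=2)
    idx = np.arange(canvas)
    sq_y = (((idx + py) // 2) % 2).astype(bool)
    sq_x = (((idx + px) // 2) % 2).astype(bool)
    checker = np.logical_xor.outer(sq_y, sq_x)
    hi = _BF_HI * rng.uniform(0.97, 1.0)
    return np.where(checker, hi, _BF_LO)


def _add_spot(
    raster: np.ndarray, cy: float, cx: float, amp: float, sigma: float
) -> None:
    n = raster.shape[0]
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(cy) - r), min(n, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(n, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    raster[y0:y1, x0:x1] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
    )


def _membrane_spots(
    raster: np.ndarray,
    cy: float,
    cx: float,
    radius_px: float,
    k: int,
    amp: float,
    sigma: float,
    rng: np.random.Generator,
) -> None:
    """k spots on the cell-perimeter annulus (true membrane CD41 signal)."""
    angles = rng.uniform(0, 2 * np.pi, size=k)
    radii = radius_px * rng.uniform(0.9, 1.02, size=k)
    for a, r in zip(angles, radii):
        _add_spot(
            raster,
            cy + r * np.sin(a),
            cx + r * np.cos(a),
            amp * rng.uniform(0.7, 1.3),
            sigma,
        )


def _draw_diameter(label: str, cfg: SyntheticConfig, rng: np.random.Generator) -> float:
    if label == "mk":
        lo, hi = cfg.mk_diameter_range_um
        while True:
            d = float(
                np.exp(
                    rng.normal(np.log(cfg.mk_diameter_median_um), cfg.mk_diameter_log_sd)
                )
            )
            if lo <= d <= hi:
                return d
    if label == "doublet":
        lo, hi = cfg.doublet_component_range_um
        d = float(np.exp(rng.normal(np.log(15.0), 0.25)))
        return min(max(d, lo), hi)
    if label == "micro_mk":
        return float(rng.uniform(*cfg.micro_mk_diameter_range_um))
    if label == "lymphocyte":
        return float(rng.uniform(*cfg.lymphocyte_diameter_range_um))
    return float(rng.uniform(*cfg.other_diameter_range_um))


# ---------------------------------------------------------------------------
# Event renderer
# ---------------------------------------------------------------------------


def render_event(
    class_name: str,
    rng: np.random.Generator,
    config: SyntheticConfig | None = None,
    panel: PanelConfig = DEFAULT_PANEL,
    object_id: int = 0,
    time: float = 0.0,
    diameter_um: float | None = None,
    defocus_sigma: float = 0.0,
    saturate: bool = False,
    dump_positive: bool = False,
    decorate_cd41_membrane: bool = False,
    n_platelet_spots: int | None = None,
) -> EventImage:
    """Render one event of the given phenotype class.

    Optional keyword overrides decorate the base phenotype (e.g. a dead
    cell carrying a CD41 membrane signal, or a forced dump-positive cell)
    so constructed fixtures can make an event fail exactly one gate.
    """
    if class_name not in CLASSES:
        raise ValueError(f"unknown class {class_name!r}; expected one of {CLASSES}")
    cfg = config or SyntheticConfig()
    n = cfg.canvas_px
    px = panel.pixel_size_um
    max_pixel = panel.max_pixel

    signal = {m: np.zeros((n, n)) for m in panel.markers}
    amps = _CLASS_AMPLITUDES[class_name]
    jitter = float(np.exp(rng.normal(0.0, 0.25)))

    if diameter_um is None:
        diameter_um = _draw_diameter(class_name, cfg, rng)
    true_diameter = diameter_um

    centers: list[tuple[float, float, float]] = []  # (cy, cx, radius_px)
    if class_name == "doublet":
        r1 = diameter_um / 2 / px
        d2 = _draw_diameter("doublet", cfg, rng)
        r2 = d2 / 2 / px
        angle = rng.uniform(0, 2 * np.pi)
        half = (r1 + r2) / 2
        c0y, c0x = n / 2 + rng.uniform(-2, 2), n / 2 + rng.uniform(-2, 2)
        centers.append((c0y - half * np.sin(angle), c0x - half * np.cos(angle), r1))
        centers.append((c0y + half * np.sin(angle), c0x + half * np.cos(angle), r2))
    else:
        radius_px = diameter_um / 2 / px
        centers.append(
            (n / 2 + rng.uniform(-3, 3), n / 2 + rng.uniform(-3, 3), radius_px)
        )

    cell_mask = np.zeros((n, n), bool)
    for cy, cx, r in centers:
        cell_mask |= _disc(n, cy, cx, r)

    # brightfield: high-contrast texture inside the cell
    signal["bf"][cell_mask] = _bf_texture(n, rng)[cell_mask]

    # nucleus (DNA dye) unless anucleate
    if class_name != "anucleate":
        for cy, cx, r in centers:
            nucleus = _disc(n, cy, cx, max(0.55 * r, 2.5))
            signal["dna"][nucleus] = _DNA_AMPLITUDE * jitter

    # uniform immunophenotype / scatter / viability discs
    for marker in ("cd45", "ssc", "dump", "viability"):
        amp = amps[marker]
        if marker == "dump" and dump_positive:
            amp = _DUMP_POSITIVE_AMPLITUDE
        if amp > 0:
            signal[marker][cell_mask] += amp * jitter

    # CD41 signal
    membrane = class_name in ("mk", "micro_mk", "doublet") or decorate_cd41_membrane
    if membrane:
        for cy, cx, r in centers:
            k = int(rng.integers(cfg.membrane_spot_count[0], cfg.membrane_spot_count[1] + 1))
            _membrane_spots(
                signal["cd41"], cy, cx, r, k, cfg.membrane_spot_amp, cfg.spot_sigma_px, rng
            )
    elif class_name == "platelet_adherent":
        k = (
            int(rng.integers(cfg.platelet_spots[0], cfg.platelet_spots[1] + 1))
            if n_platelet_spots is None
            else int(n_platelet_spots)
        )
        cy, cx, r = centers[0]
        for _ in range(k):
            a = rng.uniform(0, 2 * np.pi)
            rr = r * np.sqrt(rng.uniform(0.0, 0.55))
            _add_spot(
                signal["cd41"],
                cy + rr * np.sin(a),
                cx + rr * np.cos(a),
                cfg.platelet_spot_amp * rng.uniform(0.8, 1.2),
                cfg.spot_sigma_px,
            )

    if defocus_sigma > 0:
        for m in signal:
            signal[m] = ndimage.gaussian_filter(signal[m], defocus_sigma)

    rasters: dict[str, np.ndarray] = {}
    for marker, ch in panel.channel_map.items():
        clean = signal[marker] + cfg.background
        lam = np.clip(clean * cfg.noise_poisson_scale, 0, None)
        noisy = rng.poisson(lam) / cfg.noise_poisson_scale
        noisy = noisy + rng.normal(0.0, cfg.read_noise_sd, size=clean.shape)
        if saturate and marker == "bf":
            cy, cx, _ = centers[0]
            iy, ix = int(np.clip(cy, 2, n - 3)), int(np.clip(cx, 2, n - 3))
            noisy[iy - 1 : iy + 2, ix - 1 : ix + 2] = max_pixel
        rasters[ch] = np.clip(np.rint(noisy), 0, max_pixel).astype(np.uint16)

    ev = EventImage(object_id=object_id, time=time, rasters=rasters)
    ev.true_diameter_um = true_diameter  # type: ignore[attr-defined]
    return ev


def apply_defocus(event: EventImage, sigma: float) -> EventImage:
    """Gaussian-blur every raster of a finished event; sigma=0 is identity."""
    if sigma < 0:
        raise ValueError("blur sigma must be non-negative")
    if sigma == 0:
        return EventImage(
            object_id=event.object_id,
            time=event.time,
            rasters={ch: r.copy() for ch, r in event.rasters.items()},
        )
    out: dict[str, np.ndarray] = {}
    for ch, r in event.rasters.items():
        blurred = ndimage.gaussian_filter(r.astype(float), sigma)
        out[ch] = np.rint(np.clip(blurred, 0, np.iinfo(r.dtype).max)).astype(r.dtype)
    return EventImage(object_id=event.object_id, time=event.time, rasters=out)


# ---------------------------------------------------------------------------
# Gallery generation
# ---------------------------------------------------------------------------


def _is_saturated(ev: EventImage, panel: PanelConfig) -> bool:
    return any(
        int(ev.channel(ch).max()) >= _SATURATION_LEVEL
        for ch in panel.channel_map.values()
    )


def _stable_time(cfg: SyntheticConfig, rng: np.random.Generator) -> float:
    """Uniform time outside the unstable-burst window."""
    w0, w1 = cfg.unstable_window_s
    gap = w1 - w0
    u = rng.uniform(0.0, cfg.duration_s - gap)
    return float(u if u < w0 else u + gap)


def generate_event_set(
    config: SyntheticConfig, panel: PanelConfig = DEFAULT_PANEL
) -> tuple[EventSet, pd.DataFrame]:
    """Render a labeled gallery under the configured study conditions.

    Returns the EventSet and a ground-truth table (one row per event:
    class label, per-gate truth flags and the true diameter).  The
    ``is_saturated`` flag is recomputed from the final rasters so it is
    consistent with the rendered pixels by construction; nucleation and
    viability flags follow the class definition.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    classes = sorted(cfg.class_mixture)
    probs = np.array([cfg.class_mixture[c] for c in classes])
    labels = rng.choice(classes, size=cfg.n_events, p=probs)
    defocused = rng.random(cfg.n_events) < cfg.defocus_fraction
    saturated = rng.random(cfg.n_events) < cfg.saturated_fraction
    unstable = rng.random(cfg.n_events) < cfg.flow_instability

    events: list[EventImage] = []
    truth_rows = []
    for i in range(cfg.n_events):
        label = str(labels[i])
        t = (
            float(rng.uniform(*cfg.unstable_window_s))
            if unstable[i]
            else _stable_time(cfg, rng)
        )
        ev = render_event(
            label,
            rng,
            config=cfg,
            panel=panel,
            object_id=i,
            time=t,
            defocus_sigma=cfg.blur_sigma if defocused[i] else 0.0,
            saturate=bool(saturated[i]),
        )
        events.append(ev)
        truth_rows.append(
            {
                "object_id": i,
                "label": label,
                "is_singlet": label != "doublet",
                "is_in_focus": not bool(defocused[i]),
                "is_saturated": _is_saturated(ev, panel),
                "is_viable": label != "dead",
                "is_nucleated": label != "anucleate",
                "is_stable": not bool(unstable[i]),
                "cd41_positive": label in ("mk", "micro_mk", "doublet", "platelet_adherent"),
                "dump_negative": label != "lymphocyte",
                "cd41_membrane": label in ("mk", "micro_mk", "doublet"),
                "true_diameter_um": getattr(ev, "true_diameter_um"),
            }
        )

    truth = pd.DataFrame(truth_rows).set_index("object_id")
    event_set = EventSet(panel=panel, events=events, labels=[str(x) for x in labels])
    return event_set, truth


# ---------------------------------------------------------------------------
# Constructed gating fixture
# ---------------------------------------------------------------------------


def make_cascade_fixture(
    seed: int = 1, panel: PanelConfig = DEFAULT_PANEL
) -> tuple[EventSet, pd.DataFrame]:
    """100-event fixture in which each group fails exactly one gate.

    Composition: 10 unstable-flow, 10 saturated, 10 dead, 10 anucleate,
    15 lymphocytes, 10 dump-positive, 10 doublets, 10 defocused,
    10 platelet-adherent and 5 clean MKs — so an oracle-driven cascade
    yields survivor counts 90, 80, 70, 60, 45, 35, 25, 15, 5.
    """
    cfg = SyntheticConfig(
        n_events=100, defocus_fraction=0.0, saturated_fraction=0.0, flow_instability=0.0
    )
    rng = np.random.default_rng(seed)

    groups: list[tuple[int, str, dict]] = []
    groups += [(1, "mk", {"unstable": True})] * 10
    groups += [(1, "mk", {"saturate": True})] * 10
    groups += [(1, "dead", {"decorate_cd41_membrane": True})] * 10
    groups += [(1, "anucleate", {"decorate_cd41_membrane": True})] * 10
    groups += [(1, "lymphocyte", {})] * 15
    groups += [(1, "mk", {"dump_positive": True})] * 10
    groups += [(1, "doublet", {})] * 10
    groups += [(1, "mk", {"defocus_sigma": cfg.blur_sigma})] * 10
    groups += [(1, "platelet_adherent", {})] * 10
    groups += [(1, "mk", {})] * 5

    events: list[EventImage] = []
    truth_rows = []
    for i, (_, label, opts) in enumerate(groups):
        opts = dict(opts)
        unstable = opts.pop("unstable", False)
        t = (
            float(rng.uniform(*cfg.unstable_window_s))
            if unstable
            else _stable_time(cfg, rng)
        )
        ev = render_event(
            label, rng, config=cfg, panel=panel, object_id=i, time=t, **opts
        )
        events.append(ev)
        decorated = bool(opts.get("decorate_cd41_membrane", False))
        truth_rows.append(
            {
                "object_id": i,
                "label": label,
                "is_singlet": label != "doublet",
                "is_in_focus": opts.get("defocus_sigma", 0.0) == 0.0,
                "is_saturated": _is_saturated(ev, panel),
                "is_viable": label != "dead",
                "is_nucleated": label != "anucleate",
                "is_stable": not unstable,
                "cd41_positive": decorated
                or label in ("mk", "micro_mk", "doublet", "platelet_adherent"),
                "dump_negative": (not opts.get("dump_positive", False))
                and label != "lymphocyte",
                "cd41_membrane": label in ("mk", "micro_mk", "doublet"),
                "true_diameter_um": getattr(ev, "true_diameter_um"),
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("object_id")
    labels = [g[1] for g in groups]
    return EventSet(panel=panel, events=events, labels=labels), truth


# ---------------------------------------------------------------------------
# Single-stain compensation controls
# ---------------------------------------------------------------------------


def generate_compensation_controls(
    markers: list[str],
    spillover: np.ndarray,
    n_events: int = 500,
    seed: int = 0,
    noise: str = "none",
    mean_intensity: float = 5e4,
) -> dict[str, pd.DataFrame]:
    """Synthetic single-stain controls as per-event intensity tables.

    ``spillover[i, j]`` is the fraction of fluorophore-i signal detected
    in channel j (diagonal 1).  Each control stains exactly one
    fluorophore; true per-event brightness is log-normal.  With
    ``noise="poisson"`` observed intensities are Poisson draws around the
    spillover-mixed expectation.
    """
    spillover = np.asarray(spillover, float)
    k = len(markers)
    if spillover.shape != (k, k):
        raise ValueError("spillover must be square over the control markers")
    rng = np.random.default_rng(seed)
    controls: dict[str, pd.DataFrame] = {}
    for i, marker in enumerate(markers):
        true = mean_intensity * np.exp(rng.normal(0.0, 0.35, size=n_events))
        observed = np.outer(true, spillover[i])
        if noise == "poisson":
            observed = rng.poisson(observed).astype(float)
        elif noise != "none":
            raise ValueError("noise must be 'none' or 'poisson'")
        controls[marker] = pd.DataFrame(
            observed, columns=[f"intensity_{m}" for m in markers]
        )
        controls[marker].index.name = "object_id"
    return controls
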