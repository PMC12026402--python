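"""Shared synthetic fixtures.

Everything is generated programmatically; the expensive galleries are
session-scoped so rendering and feature extraction happen once.
"""

from __future__ import annotations

import numpy as np
import pytest

from mkflow.event_model import DEFAULT_PANEL, EventSet
from mkflow.morphometry import compute_features
from mkflow.synthgen import SyntheticConfig, generate_event_set, make_cascade_fixture, render_event


@pytest.fixture(scope="session")
def cascade_fixture():
    """100-event constructed cascade fixture: (events, truth, features)."""
    events, truth = make_cascade_fixture(seed=1)
    return events, truth, compute_features(events)


@pytest.fixture(scope="session")
def default200():
    """200 events from the default class mixture, seed 1."""
    events, truth = generate_event_set(SyntheticConfig(n_events=200, seed=1))
    return events, truth, compute_features(events)


@pytest.fixture(scope="session")
def lymph30_features():
    """500 events, 30% lymphocytes / 70% MKs, seed 1: (truth, features)."""
    cfg = SyntheticConfig(
        n_events=500,
        seed=1,
        class_mixture={"lymphocyte": 0.3, "mk": 0.7},
        defocus_fraction=0.0,
        saturated_fraction=0.0,
        flow_instability=0.0,
    )
    events, truth = generate_event_set(cfg)
    return truth, compute_features(events)


@pytest.fixture(scope="session")
def mk_only():
    """60 clean MK singlets (degenerate mixture): (events, truth, features)."""
    cfg = SyntheticConfig(
        n_events=60,
        seed=2,
        class_mixture={"mk": 1.0},
        defocus_fraction=0.0,
        saturated_fraction=0.0,
        flow_instability=0.0,
    )
    events, truth = generate_event_set(cfg)
    return events, truth, compute_features(events)


@pytest.fixture(scope="session")
def lda_truth_sets():
    """Manually-tagged-style truth populations: 28 singlets, 52 doublets."""
    cfg = SyntheticConfig()
    rng = np.random.default_rng(1)
    singlets = EventSet(
        panel=DEFAULT_PANEL,
        events=[render_event("mk", rng, cfg, object_id=i) for i in range(28)],
    )
    doublets = EventSet(
        panel=DEFAULT_PANEL,
        events=[render_event("doublet", rng, cfg, object_id=i) for i in range(52)],
    )
    return compute_features(singlets), compute_features(doublets)


@pytest.fixture(scope="session")
def doublet100_features():
    """100 freshly rendered doublets (seed 1 stream, held out of training)."""
    cfg = SyntheticConfig()
    rng = np.random.default_rng(101)
    events = EventSet(
        panel=DEFAULT_PANEL,
        events=[render_event("doublet", rng, cfg, object_id=i) for i in range(100)],
    )
    return compute_features(events)


@pytest.fixture()
def tiny_event_set():
    """10 small, fast events for I/O tests."""
    cfg = SyntheticConfig(canvas_px=48)
    rng = np.random.default_rng(7)
    events = [
        render_event("micro_mk", rng, cfg, object_id=i, time=float(i))
        for i in range(10)
    ]
    return EventSet(panel=DEFAULT_PANEL, events=events, labels=["micro_mk"] * 10)
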