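"""Shared fixtures: the default synthetic study conditions.

Heavy generator outputs are session-scoped; tests treat them as read-only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adrnmes import (
    SimulationConfig,
    TrajectoryConfig,
    default_genome,
    simulate_chip_landscape,
    simulate_expression_panel,
    simulate_timecourse,
)
from adrnmes.containers import ExpressionMatrix
from adrnmes import enhancers

PANEL_SEED = 2026
CHIP_SEED = 7
TIMECOURSE_SEED = 11


def make_expression(values: np.ndarray, sample_meta: dict | None = None) -> ExpressionMatrix:
    """Small helper to build an ExpressionMatrix from a raw array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    idx = pd.Index([f"g{i:03d}" for i in range(n_genes)], name="probeset")
    cols = [f"s{j:02d}" for j in range(n_samples)]
    vdf = pd.DataFrame(values, index=idx, columns=cols)
    det = pd.DataFrame("P", index=idx, columns=cols)
    meta = pd.DataFrame(
        sample_meta or {"lineage": ["unknown"] * n_samples},
        index=pd.Index(cols, name="sample"),
    )
    return ExpressionMatrix(vdf, det, meta)


@pytest.fixture(scope="session")
def default_panel():
    return simulate_expression_panel(SimulationConfig(seed=PANEL_SEED))


@pytest.fixture(scope="session")
def default_timecourse():
    cfg = SimulationConfig(seed=TIMECOURSE_SEED)
    return cfg, TrajectoryConfig(), *simulate_timecourse(cfg, TrajectoryConfig())


@pytest.fixture(scope="session")
def default_landscape():
    cfg = SimulationConfig(seed=CHIP_SEED)
    genome = default_genome()
    track_a, track_b, genome_seq, truth = simulate_chip_landscape(cfg, genome)
    return genome_seq, track_a, track_b, truth


@pytest.fixture(scope="session")
def landscape_calls(default_landscape):
    """Normalized tracks, stitched regions and SE calls for both states."""
    genome_seq, track_a, track_b, truth = default_landscape
    out = {}
    for state, track in (("A", track_a), ("B", track_b)):
        norm = enhancers.normalize_track(track)
        thr = enhancers.auto_threshold(norm)
        peaks = enhancers.call_peaks(norm, thr, 200)
        regions = enhancers.stitch_peaks(peaks)
        out[state] = {
            "norm": norm,
            "regions": regions,
            "call": enhancers.call_superenhancers(regions, norm),
        }
    return out
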