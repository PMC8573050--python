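"""Shared fixtures: expensive simulated sessions are built once per run."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import calcilux as cx


@dataclass
class Pipeline:
    """One simulated session pushed through the full analysis pipeline."""

    config: cx.SessionConfig
    schedule: cx.StimulationSchedule
    stack: cx.MovieStack
    cellmap: "cx.CellMap"
    rois: cx.ROISet
    traces: cx.TraceMatrix
    events: "object"  # pandas DataFrame


def run_pipeline(config: cx.SessionConfig,
                 schedule: cx.StimulationSchedule) -> Pipeline:
    stack, cellmap = cx.simulate_session(config, schedule)
    rois = cx.assign_rois(stack, schedule)
    traces = cx.extract_traces(stack, rois, schedule)
    events = cx.detect_events(traces, schedule)
    return Pipeline(config=config, schedule=schedule, stack=stack,
                    cellmap=cellmap, rois=rois, traces=traces, events=events)


@pytest.fixture(scope="session")
def invivo_hour() -> Pipeline:
    """One-hour in-vivo session (10 stimuli), full pipeline, seed 1."""
    cfg = cx.invivo_preset(seed=1, duration_h=1.0)
    sched = cx.StimulationSchedule.hourly_blocks(1, 10)
    return run_pipeline(cfg, sched)


@pytest.fixture(scope="session")
def invivo_day() -> Pipeline:
    """Fourteen-hour in-vivo session (10 stimuli/hour), full pipeline, seed 0."""
    cfg = cx.invivo_preset(seed=0)
    sched = cx.StimulationSchedule.hourly_blocks(14, 10)
    return run_pipeline(cfg, sched)


@pytest.fixture(scope="session")
def baseline_session() -> Pipeline:
    """Unstimulated baseline session, full pipeline, seed 3."""
    cfg = cx.baseline_preset(seed=3)
    return run_pipeline(cfg, cx.empty_schedule())


@pytest.fixture(scope="session")
def hek_trace():
    """Noiseless single-cell trace with 10 stimuli, seed 0."""
    cfg = cx.hek_preset(seed=0)
    sched = cx.StimulationSchedule.periodic(10, 12.0, start_s=2.0)
    return cx.simulate_hek_trace(cfg, sched) + (sched,)


def match_rois_to_neurons(rois: cx.ROISet, cellmap) -> dict[int, int]:
    """Map each ROI id to the nearest ground-truth neuron index."""
    pos = cellmap.positions_px
    out = {}
    for rid, (cy, cxx) in zip(rois.ids, rois.centroids_px):
        out[int(rid)] = int(np.argmin(np.hypot(pos[:, 0] - cy,
                                               pos[:, 1] - cxx)))
    return out
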