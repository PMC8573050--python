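"""Optical-electrical correlation on a simulated slice-style session.

Runs the imaging pipeline on a one-hour stimulated session, records the same
cells with a simulated multi-electrode array, pairs spikes with optical
peaks, and reports the temporal and spatial R^2.

Run:  python examples/mea_correlation.py
"""

import calcilux as cx
from calcilux.coupling import (pair_events, spatial_correlation,
                               temporal_correlation)


def main() -> None:
    cfg = cx.invivo_preset(seed=0, duration_h=1.0)
    sched = cx.StimulationSchedule.hourly_blocks(1, 10)
    stack, cellmap = cx.simulate_session(cfg, sched)
    rois = cx.assign_rois(stack, sched)
    traces = cx.extract_traces(stack, rois, sched)
    events = cx.detect_events(traces, sched)

    # temporal: one electrode per detected neuron, tight pickup radius
    mea = cx.simulate_mea(cellmap, rois.centroids_um(), noise_ratio=0.1,
                          radius_um=15.0, seed=0)
    pairs = pair_events(events, mea, rois, radius_um=15.0)
    temporal = temporal_correlation(pairs)
    print(f"temporal R^2 = {temporal.r2:.3f}  "
          f"({temporal.n} spike/peak pairs, slope {temporal.slope:.3f} uV/%)")

    # spatial: regular electrode grid, active-area vs spike-count fit
    grid = cx.mea_grid(4, 4, pitch_um=56.0, origin_um=(28.0, 28.0))
    mea_grid_rec = cx.simulate_mea(cellmap, grid, noise_ratio=0.12, seed=0)
    spatial = spatial_correlation(rois.label_image > 0, cfg.pixel_scale_um,
                                  mea_grid_rec)
    print(f"spatial R^2  = {spatial.r2:.3f}  "
          f"({spatial.n} electrodes)")


if __name__ == "__main__":
    main()
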