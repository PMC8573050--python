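"""Long-duration in-vivo monitoring: per-hour response fidelity.

Simulates a 14-hour cranial-window session (sparse rendering, 10 stimuli per
hour), runs ROI assignment, trace extraction and event classification, and
prints the pooled primary-response fidelity per hour.

Run:  python examples/invivo_fidelity.py      (about half a minute)
"""

import calcilux as cx


def main() -> None:
    cfg = cx.invivo_preset(seed=0)
    sched = cx.StimulationSchedule.hourly_blocks(14, 10)
    stack, _ = cx.simulate_session(cfg, sched)
    rois = cx.assign_rois(stack, sched)
    traces = cx.extract_traces(stack, rois, sched)
    events = cx.detect_events(traces, sched)

    windows = [(float(h), float(h + 1)) for h in range(14)]
    fid = cx.fidelity(events, rois.ids, sched, windows)
    pooled = (fid.groupby("window_start_h")
              .apply(lambda g: g["n_responses"].sum() / g["n_stimuli"].sum(),
                     include_groups=False))
    print(f"{rois.n_rois} ROIs, {len(events)} events")
    for h, f in pooled.items():
        bar = "#" * int(round(40 * f))
        print(f"hour {int(h):2d}  fidelity {f:5.2f}  {bar}")
    print(f"minimum hourly fidelity: {pooled.min():.2f}")


if __name__ == "__main__":
    main()
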