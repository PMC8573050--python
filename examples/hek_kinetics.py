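"""Single-cell transient kinetics: fold change and decay half-life.

Simulates the HEK-style single-cell preset (direct pulse stimulation, fast
imaging), extracts the dI/I0 trace, and fits the exponential decay of each
transient.

Run:  python examples/hek_kinetics.py
"""

import numpy as np

import calcilux as cx


def main() -> None:
    cfg = cx.hek_preset(seed=0)
    sched = cx.StimulationSchedule.periodic(10, 12.0, start_s=2.0)
    trace, cellmap = cx.simulate_hek_trace(cfg, sched)

    fold = 1.0 + float(np.nanmax(trace.dff[0]))
    fits = [f for f in cx.decay_fits_per_stimulus(trace, 1) if f.ok]
    t_half = np.mean([f.t_half_ms for f in fits])

    print(f"peak/baseline fold change : {fold:.3f}  (configured "
          f"{cfg.fold_change})")
    print(f"decay half-life           : {t_half:.1f} ms over "
          f"{len(fits)} transients  (configured {cfg.t_half_decay_ms:.0f} ms)")


if __name__ == "__main__":
    main()
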