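"""Opsin photocurrent kinetics: simulate a noisy single-pulse trace and
recover the on/off time constants.

Run:  python examples/photocurrent_fit.py
"""

import numpy as np

import calcilux as cx


def main() -> None:
    pulse = cx.StimulationSchedule(onsets_s=np.array([0.05]),
                                   pulse_width_ms=100)
    ons, offs = [], []
    for seed in range(20):
        trace = cx.simulate_photocurrent(pulse, noise_frac=0.02, seed=seed)
        fit = cx.fit_photocurrent(trace, pulse)
        if fit.ok:
            ons.append(fit.tau_on_ms)
            offs.append(fit.tau_off_ms)
    print(f"tau_on  = {np.mean(ons):5.1f} +/- {np.std(ons):.1f} ms "
          "(generator: 32 ms)")
    print(f"tau_off = {np.mean(offs):5.1f} +/- {np.std(offs):.1f} ms "
          "(generator: 68 ms)")


if __name__ == "__main__":
    main()
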