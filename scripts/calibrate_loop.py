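#!/usr/bin/env python
"""Calibration report for the loop model's canonical parameterization.

The reference parameters are calibrated against two physiological criteria:
a single motor-nerve volley should elicit a Renshaw-cell burst of 2-5 spikes,
and the compound somatic IPSP in the recorded motoneuron should fall in the
100-500 µV range, for every EPSP conductance rise time in {1, 4, 8} ms. This
script prints the achieved values for the current defaults (or for overrides
passed on the command line) so the calibration can be re-checked after any
parameter change.

Usage:
    python scripts/calibrate_loop.py [--epsp-gpeak 2.0] [--glycine-gpeak 1.2]
"""

from __future__ import annotations

import argparse
from dataclasses import replace

from renshaw.loop_model import GlycineParams, ModelConfig, volley_response


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--epsp-gpeak", type=float, default=None,
                        help="unitary axonal EPSP conductance peak at 1 ms rise (nS)")
    parser.add_argument("--glycine-gpeak", type=float, default=None,
                        help="unitary glycinergic conductance peak per spike (nS)")
    args = parser.parse_args()

    base = ModelConfig(duration_s=2.0, discard_s=0.5, mn_noise_sd_uv=0.0)
    if args.epsp_gpeak is not None:
        base = replace(base, epsp_unitary_gpeak_ns=args.epsp_gpeak)
    if args.glycine_gpeak is not None:
        base = replace(
            base, glycine_params=GlycineParams(unitary_peak_ns=args.glycine_gpeak)
        )

    print(f"unitary EPSP g_peak @1ms rise: {base.epsp_unitary_gpeak_ns:g} nS "
          f"(charge-normalized across rise times)")
    print(f"unitary glycine g_peak: {base.glycine_params.unitary_peak_ns:g} nS")
    print()
    ok = True
    for rise in (1.0, 4.0, 8.0):
        r = volley_response(replace(base, epsp_rise_ms=rise))
        spikes = r["mean_spikes_per_cell"]
        ipsp = r["ipsp_amplitude_uv"]
        flag_s = "OK" if 2.0 <= spikes <= 5.0 else "OUT OF RANGE (want 2-5)"
        flag_i = "OK" if 100.0 <= ipsp <= 500.0 else "OUT OF RANGE (want 100-500)"
        ok &= flag_s == "OK" and flag_i == "OK"
        print(f"rise {rise:g} ms: {spikes:.2f} Renshaw spikes/cell/volley [{flag_s}], "
              f"compound IPSP {ipsp:.0f} µV [{flag_i}], "
              f"onset {r['ipsp_onset_ms']:.2f} ms")
    print()
    print("calibration criteria " + ("met" if ok else "NOT met"))


if __name__ == "__main__":
    main()
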