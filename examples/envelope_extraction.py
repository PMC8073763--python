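"""Upper/lower envelope recovery from an amplitude-modulated β-band tone.

A 20 Hz carrier modulated by a known 1 Hz envelope is run through the
half-wave extrema detector and spline interpolation; the recovered
envelopes are compared against the true modulator.
"""

import numpy as np

from envsync import build_envelopes

fs = 256
t = np.arange(60 * fs) / fs
modulator = 1 + 0.5 * np.cos(2 * np.pi * 1.0 * t)
signal = modulator * np.cos(2 * np.pi * 20.0 * t)

env = build_envelopes(signal, min_separation=20)
core = slice(2 * fs, -2 * fs)  # splines are unconstrained near the record edges

up_err = np.abs(env.upper[core] - modulator[core]).max()
lo_err = np.abs(env.lower[core] + modulator[core]).max()
print(f"retained maxima: {len(env.knots.max_idx)}, minima: {len(env.knots.min_idx)}")
print(f"max |upper - true modulator|  = {up_err:.4f}")
print(f"max |lower + true modulator|  = {lo_err:.4f}")
print()
print("Both envelopes track the 1 Hz modulator to within a few percent of")
print("its amplitude; the knot counts reflect the 20-sample separation rule")
print("thinning the 20 Hz peak train.")
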