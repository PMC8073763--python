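"""Phase-locking value on constructed relative-phase windows.

The PLV maps a window of relative phase angles to the modulus of their
mean unit vector: 1 means every angle is the same (perfect locking),
0 means the angles spread uniformly around the circle.
"""

import numpy as np

from envsync import compute_plv

locked = np.full(2560, 0.7)               # one 10-s window at 256 Hz, constant offset
uniform = 2 * np.pi * np.arange(8) / 8    # 8 unit vectors at the roots of unity
half = np.where(np.arange(2560) % 2 == 0, 0.0, np.pi)  # two opposing directions

print(f"constant relative phase  -> PLV = {compute_plv(locked):.12f}")
print(f"uniformly spread phases  -> PLV = {compute_plv(uniform):.12f}")
print(f"two opposing directions  -> PLV = {compute_plv(half):.12f}")
print()
print("1 = the two phase series move in perfect lockstep; 0 = no consistent")
print("phase relationship; opposing halves cancel to 0 as well.")
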