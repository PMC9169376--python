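"""Turn one 500 ms window into its DWT feature vector.

A single-level discrete wavelet transform splits the window into
approximation (low-pass, cA) and detail (high-pass, cD) coefficients; the
concatenation cA || cD is the feature vector the classifier consumes.
"""

import numpy as np

import lithowarn as lw

rec = lw.simulate_state_signal("stone", 1.0, seed=3)
window = lw.segment_recording(rec)[0]

for name in lw.SUPPORTED_WAVELETS:
    c = lw.dwt_single_level(window.values, name, padding="symmetric")
    energy = (np.sum(c.approx**2) + np.sum(c.detail**2)) / np.sum(window.values**2)
    print(f"{name:8} taps={lw.load_wavelet(name).filter_length:3d}  "
          f"len(cA)=len(cD)={len(c.approx):3d}  feature dim={2*len(c.approx):4d}  "
          f"coef/signal energy={energy:6.3f}")

# Without padding (periodized transform) the orthogonal families conserve
# energy exactly and halve the window length:
c = lw.dwt_single_level(window.values, "haar", padding="none")
print(f"\nhaar, no padding: {len(window)} samples -> {len(c.approx)}+{len(c.detail)} "
      "coefficients (half length, energy preserved)")
back = lw.idwt_single_level(c, "haar")
print(f"reconstruction error: {np.max(np.abs(back - window.values)):.2e}")
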