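"""The speckle contrast ↔ correlation time ↔ flow model.

Evaluates the single-exposure contrast model K²(τ_c/T) at a few flow speeds,
inverts a contrast value back to τ_c, and shows that relative flow (1/τ_c)
halves when the correlation time doubles.
"""

import numpy as np

from speckleflow import k_squared, invert_contrast

T = 5e-3  # camera exposure, seconds

print("tau_c/T      K^2       K")
for x in (0.05, 0.1, 0.5, 1.0, 2.0, 10.0, 100.0):
    ksq = k_squared(x * T, T=T)
    print(f"{x:7.2f}  {ksq:8.5f}  {np.sqrt(ksq):7.4f}")

K = np.sqrt(k_squared(1.0, T=1.0))
tau = invert_contrast(K, T=T)
print(f"\ninverting K = {K:.6f} at T = {T*1e3:.0f} ms -> tau_c = {tau*1e3:.4f} ms")
print("(tau_c = T, as expected: contrast fixes the ratio tau_c/T)")

f1, f2 = 1.0 / invert_contrast(K, T=T), 1.0 / invert_contrast(np.sqrt(k_squared(2.0, 1.0)), T=T)
print(f"relative flow at tau_c=T vs tau_c=2T: {f1:.1f} vs {f2:.1f} (ratio {f1/f2:.2f})")
print("flow is read as 1/tau_c: doubling the correlation time halves the flow.")
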