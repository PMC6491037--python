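"""From raw node timeseries to leakage-corrected 1 Hz amplitude envelopes.

Simulates one subject with a known envelope correlation (r = 0.6
between nodes 2 and 7) and zero-lag leakage mixing, then shows how
symmetric orthogonalization removes the leakage-inflated correlation
while preserving the genuine envelope coupling.
"""

import numpy as np

from envconn import (
    CohortDesign,
    amplitude_correlation_matrix,
    simulate_subject,
    subject_band_envelope,
)
from envconn.bands import ALPHA
from envconn.synthetic import default_base_corr

n = 10
base = default_base_corr(n)
base[2, 7] = base[7, 2] = 0.6  # planted long-range envelope coupling

design = CohortDesign(
    n_case=1, n_control=1, n_nodes=n, duration=120.0, sampling_rate=200.0,
    bands=[ALPHA], base_envelope_corr={"Alpha": base},
    leakage_strength=0.3, seed=5,
)

z_raw, z_corrected = [], []
for s in range(10):
    rec = simulate_subject(design, "control", s)
    raw = subject_band_envelope(rec, ALPHA, orthogonalize=False)
    corr = subject_band_envelope(rec, ALPHA, orthogonalize=True)
    z_raw.append(amplitude_correlation_matrix(raw, variance_normalize=False).z[2, 7])
    z_corrected.append(
        amplitude_correlation_matrix(corr, variance_normalize=False).z[2, 7]
    )

target = np.arctanh(0.6)
print(f"envelope sets: {corr.n_nodes} nodes x {corr.n_samples} samples at 1 Hz")
print(f"planted Fisher z on edge (2,7):            {target:.3f}")
print(f"recovered without leakage correction:      {np.mean(z_raw):.3f}")
print(f"recovered after symmetric orthogonalization: {np.mean(z_corrected):.3f}")
# Without correction, zero-lag mixing inflates the apparent coupling;
# orthogonalization removes the shared signal and restores the target.
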