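"""Principal fluctuation modes of cluster populations.

Plants a population series driven by two orthogonal modes — monomer/dimer
exchange and (monomer+dimer) vs (trimer+tetramer) redistribution — and
shows that PCA of the 1/N_frames covariance recovers both directions, their
amplitude ordering, and their physical classification.
"""
import numpy as np

import ionclust as ic
from ionclust.pca import mode_report

m1 = np.array([1, -1, 0, 0]) / np.sqrt(2)     # dissociation <-> ion pairing
m2 = np.array([1, 1, -1, -1]) / 2.0           # small <-> large clusters

series, true_cov = ic.plant_series(ic.SeriesSpec(
    n_frames=10_000, modes=(tuple(m1), tuple(m2)),
    amplitudes=(0.05, 0.025), noise=0.004, seed=9))

result = ic.pca(series, s_max=4)
report = mode_report(result, k=2)

print("eigenvalues:", "  ".join(f"{v:.2e}" for v in result.eigenvalues))
print("variance fractions:",
      "  ".join(f"{100 * f:.1f}%" for f in result.variance_fractions))
print(f"first two modes carry {100 * report.cumulative_variance:.1f}% "
      "of the variance")
for k, (comp, label) in enumerate(zip(report.components,
                                      report.classifications), start=1):
    angle = np.degrees(np.arccos(min(1.0, abs(comp @ (m1 if k == 1 else m2)))))
    print(f"mode {k}: [" + " ".join(f"{c:+.3f}" for c in comp) + f"]  {label}"
          f"  (angle to planted mode: {angle:.2f} deg)")
# Angles well under 5 degrees mean the empirical covariance reproduces the
# planted fluctuation structure; the labels name the sign patterns.
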