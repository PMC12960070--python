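"""Compare cluster-size populations between two systems.

Generates two 44-ion population time series whose mean free-monomer
fractions differ by a planted gap of 0.03 (1.32 ions), summarises each with
block maximum-error bars, and reports the componentwise difference —
the same statistic used to compare diastereomeric salt systems.
"""
import ionclust as ic

GAP = 0.03  # planted monomer-fraction gap; 44 * 0.03 = 1.32 ions
mode = (1, -1, 0, 0)  # monomer/dimer exchange fluctuation

series_a, _ = ic.plant_series(ic.SeriesSpec(
    n_frames=2000, base=(0.50 + GAP / 2, 0.30 - GAP / 2, 0.12, 0.08),
    modes=(mode,), amplitudes=(0.05,), seed=1))
series_b, _ = ic.plant_series(ic.SeriesSpec(
    n_frames=2000, base=(0.50 - GAP / 2, 0.30 + GAP / 2, 0.12, 0.08),
    modes=(mode,), amplitudes=(0.05,), seed=2))

summary_a = ic.summarize(series_a, n_blocks=5, n_ions=44)
summary_b = ic.summarize(series_b, n_blocks=5, n_ions=44)

print("mean ions per size class (A):",
      "  ".join(f"{c:.2f}±{e:.2f}" for c, e in
                zip(summary_a.counts, summary_a.counts_max_error)))
print("mean ions per size class (B):",
      "  ".join(f"{c:.2f}±{e:.2f}" for c, e in
                zip(summary_b.counts, summary_b.counts_max_error)))

diff = ic.population_difference(summary_a, summary_b)
for i, (d, u, sig) in enumerate(zip(diff.delta_counts, diff.uncertainty_counts,
                                    diff.significant), start=1):
    mark = "significant" if sig else "within uncertainty"
    print(f"size {i}: A-B = {d:+.2f} ± {u:.2f} ions ({mark})")
print(f"planted monomer-count gap was {44 * GAP:.2f} ions")
# A significant size-1 difference near 1.32 means the estimator recovers the
# planted excess of free ions; errors are conservative block maximum errors.
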