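# ionclust

Detection and statistics of transient ionic clusters in molecular-dynamics
trajectories of electrolyte and salt solutions — the pre-nucleation regime
where dissolved ions reversibly form dimers, trimers and small aggregates
long before any crystal nucleates. The package was built for comparing
diastereomeric salt solutions (e.g. a chiral ammonium cation with the two
enantiomers of camphorsulfonate, systems of 22 cations + 22 anions in
solvent), where small, statistically significant differences in clustering
propensity accompany differences in solubility, but the machinery applies
to any ionic solution trajectory with orthorhombic periodic boundaries.

## Method

For each frame, every ion is assigned to exactly one cluster by an
ellipsoidal-shell scan:

1. **Reference ellipsoid.** For a reference ion, diagonalise the geometric
   covariance matrix of its atomic coordinates; the eigenvalues λᵢ give the
   semiaxes aᵢ = 2√λᵢ of its best-fitting ellipsoid.
2. **Shell expansion.** Concentric shells with semiaxes a(n) = aᵢ + nδ
   (δ = 0.4 nm, about one solvent molecule) are scanned outwards. An ion
   with an atom in the current shell joins the cluster iff its nearest-atom
   distance to any already-accepted member is ≤ 0.3 nm. The scan stops when
   a shell holds only solvent, or holds ion atoms with no new contact.
3. **Partition.** The procedure repeats with the next unassigned ion until
   every ion belongs to one cluster; the result is insensitive to the
   reference order.

From the partition of each frame, with cᵢ clusters of size i among N ions
and nᵢ = cᵢ/N, the state vector **v**(n₁, 2n₂, 3n₃, …) collects the ion
fractions per cluster-size class, normalised as Σᵢ i·nᵢ = 1 (sizes beyond
the reporting cap are kept in an explicit overflow term). Time averages
carry conservative *maximum errors* — the largest deviation of a
contiguous-block mean from the global mean — and system comparisons report
per-class differences with summed uncertainties. The dynamics of the
populations are characterised by PCA of the covariance

  C_ij = (1/N_frames) Σ_k (i·n_i,k − ⟨i·n_i⟩)(j·n_j,k − ⟨j·n_j⟩),

whose leading eigenvectors are the principal interconversion modes
(typically monomer↔dimer exchange, then small↔large redistribution).

A synthetic-fixture generator plants clusters of known composition (contact
chains at ≤ 0.25 nm separated by ≥ 1.2 nm, solvent outside a 0.35 nm skin),
population series with known covariance, and toy interconversion
trajectories, so every stage is testable against exact ground truth; an
independent contact-graph oracle (single-linkage with solvent obstruction)
cross-checks the detector.

## Worked example

`examples/detect_clusters.py` plants 44 ions in known clusters plus solvent
and runs the detector and the oracle:

```text
frame: 857 atoms, 44 ions, box 10.8 nm
  planted: 28x size-1  3x size-2  2x size-3  1x size-4
 detected: 28x size-1  3x size-2  2x size-3  1x size-4
   oracle: 28x size-1  3x size-2  2x size-3  1x size-4
detected partition identical to planted truth: True
```

All three size histograms agree and the member sets are identical: the
shell scan resolves every planted cluster exactly. The other examples show
population comparison (`population_analysis.py` recovers a planted
1.32-ion free-monomer gap as 1.39 ± 0.17, flagged significant), PCA mode
recovery (`pca_modes.py`, planted modes recovered within 0.2°), and the
file-based pipeline (`end_to_end_pipeline.py`, a dimer/monomer toggle whose
leading eigenvector is (1,−1)/√2 — pure monomer–dimer anticorrelation).

The same stages are scriptable from the shell:

```bash
ionclust synth traj --spec toy.yaml --out toy
ionclust scan --traj toy.gro --roles toy.roles.csv --out parts.json
ionclust populations --partitions parts.json --out pops.json
ionclust pca --populations pops.json --out pca.json
ionclust run --config run.yaml        # whole pipeline + manifest
```

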