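# Methods

## Scope and model

ionclust analyses equilibrium pre-nucleation clustering in MD trajectories
of ionic solutions: which transient clusters exist frame by frame, how the
cluster-size populations are distributed and how they fluctuate. It does
not run MD, perceive connectivity, or model nucleation kinetics; frames,
box vectors and an atom→molecule/role map are inputs. Only orthorhombic
boxes are supported — the method needs nothing beyond minimum-image
distances and shell-membership tests, and restricting to orthorhombic
cells keeps the minimum image exact and cheap; triclinic input is rejected
with a clear error. All internal lengths are nm (GRO native; PDB Å are
converted on read). Every molecule is made whole once per frame before any
geometry, since an ellipsoid fitted to a molecule split across a periodic
face is meaningless.

## Cluster definition

The guiding physical idea is that two ions belong to the same cluster when
their closest approach is not mediated by solvent. Operationally, for a
reference ion:

1. Its geometric covariance matrix (unweighted, centred second moments
   divided by the atom count N, not N−1, so a single atom gives exactly
   zero) is diagonalised; semiaxes are aᵢ = 2√λᵢ along the eigenvectors.
   All atoms, hydrogens included, enter the fit; a heavy-atom variant can
   be had by filtering the coordinates passed in. Vanishing semiaxes
   (single-atom, linear or planar ions) are floored at 0.1 nm
   (`semiaxis_floor`) so the base ellipsoid always has positive volume.
2. Concentric shells a(n) = aᵢ + nδ are scanned outwards, δ = 0.4 nm by
   default (roughly one solvent molecule). Shell membership is inclusive
   (Σ(xᵢ/sᵢ)² ≤ 1 after minimum-image wrapping and rotation into the
   principal frame) and a boundary atom belongs to the inner of two
   adjacent shells, so shells partition space. An ion with any atom in the
   current shell is nominated whole (candidacy is atom-level, acceptance
   molecule-level); it is accepted iff its minimum interatomic distance to
   the atoms of *any already-accepted member* — the accumulated cluster,
   the more permissive and connectivity-consistent reading of "contact
   with the inner shells" — is ≤ 0.3 nm (`contact_threshold`). Acceptance
   within a shell iterates to a fixed point so contact chains inside one
   shell are chased.
3. The scan terminates when a shell beyond the base ellipsoid contains no
   ion atoms other than the members' (a solvent-only shell and an empty
   shell are treated alike: neither can connect further ions), when ion
   atoms are present but no candidate is accepted, or at n_max
   (default ⌈min(box)/2/δ⌉, beyond which shells are not meaningful under
   minimum image). Shell 0 is the reference's own region and never triggers
   termination. A shell containing only member atoms keeps the scan going:
   an accepted elongated cluster can span several shells before its
   environment is reached.

Reference ions are processed in ascending molecule-id order by default
(deterministic); a seeded random order is available, and the size
distribution's insensitivity to the order is asserted in the tests rather
than assumed. Already-assigned ions are never reconsidered, so the frame
partition is disjoint and complete by construction, and an integrity check
enforces Σ sizes = N_ions.

An independent brute-force oracle backs the tests: a graph on ions with an
edge when the nearest-atom distance is ≤ 0.3 nm and no solvent atom lies
within a blocking radius (default 0.15 nm) of the closest-approach
segment; connected components are clusters (SciPy's `connected_components`
does the graph part). The oracle shares no code with the shell scan.

## Populations and uncertainties

With cᵢ clusters of size i among N ions, nᵢ = cᵢ/N, the state vector holds
the components i·nᵢ, so n₁ + 2n₂ + 3n₃ + … = 1 holds identically. The
alternative normalisation (fraction of clusters) cannot satisfy this
condition and was rejected. Clusters larger than the reporting cap
S_max (default 4 — larger species are negligibly populated in the target
systems) accumulate in an explicit overflow component so the normalisation
check stays exact to 1e-12; a charge-resolved tally (cations/anions per
cluster) is retained even though size classes merge charge compositions,
so the merging approximation can be inspected.

Uncertainties are **maximum errors**: the series is cut into n_blocks
contiguous blocks (default 5; the remainder folds into the last block) and
each component's uncertainty is the largest deviation of a block mean from
the global mean. No canonical formula exists for this estimator, so block
count and length are explicit parameters; by construction it dominates the
standard error of the mean on uncorrelated data (≥ 95% of seeded
replicates in the tests) and degrades gracefully to a sampling-quality
flag on correlated data. Differences between systems subtract means and
*add* the two maximum errors — conservative, consistent with the
estimator's semantics — and a component is flagged significant when
|difference| exceeds that combined uncertainty. The ion-count view
(N·i·⟨nᵢ⟩) requires both systems to contain the same number of ions.

## PCA of population fluctuations

The covariance of the truncated state vectors uses the divisor N_frames
(not N_frames − 1) — immaterial at trajectory frame counts, but the test
oracles match it exactly. Truncation to S_max happens *before* centring
and the vectors are not renormalised: renormalising would redistribute the
neglected large-cluster fraction into the retained components and distort
the fluctuations. Consequences asserted in the tests: on overflow-free
series the deviations sum to zero, C·𝟙 = 0, and one eigenvalue is exactly
zero with eigenvector ∝ 𝟙; Σ eigenvalues = trace(C); the statistic is
invariant under frame permutation. Eigenvector signs are fixed by making
each vector's largest-magnitude component positive, so reports are
reproducible across linear-algebra backends. Mode reports classify sign
patterns (components below 0.2 of the mode's largest magnitude are treated
as negligible) into the two canonical mechanisms — monomer–dimer
anticorrelation, and monomer–dimer vs trimer–tetramer redistribution —
with an explicit sign-group description as fallback.

## Synthetic fixtures: what they emulate and what they do not

`plant_frame` emulates the composition of the target systems (22 cations +
22 anions by default) with ions as rigid 5-atom blobs, clusters as contact
chains (nearest-atom spacing 0.22 nm ≤ the 0.25 nm `intra_contact`),
cluster separations ≥ 1.2 nm (`inter_gap`), and single-atom solvent kept
outside a 0.35 nm skin, with one solvent atom guaranteed on every cluster
pair's closest-approach segment. Cluster seeds go on a seeded, jittered
periodic grid: this satisfies the separation constraint by construction,
stays minimum-image-safe, and makes infeasible boxes detectable exactly
(a too-small box raises a generation error naming the constraint) instead
of failing probabilistically. Solvent density defaults to 0.5 atoms/nm³ —
deliberately sparse: enough to exercise solvent-only termination and
segment obstruction, cheap enough for hundreds of fixtures. Every frame
re-validates its own constraints by direct distance computation before
being returned, and generation is bit-reproducible per seed.

These fixtures are geometric, not physical: no electrostatics, no realistic
solvation shells, no force field, and cluster/gap distances chosen to make
the planted partition the unique answer. Passing tests therefore
demonstrate that the implementation computes the defined statistics
correctly, not that the cluster definition is chemically optimal for a
given real system — on real trajectories, borderline contacts near the
0.3 nm threshold will make the partition sensitive to that parameter, which
is why it is exposed.

`plant_series` builds population vectors as a normalised base composition
plus planted fluctuation modes orthogonal to 𝟙 (preserving normalisation)
and isotropic noise projected into the zero-sum subspace; the analytic
covariance (Σ aₘ²mₘmₘᵀ + σ²P) is returned for recovery tests. Frames with
negative components are resampled (bounded, then an error); at the default
amplitudes this essentially never triggers, so the bias is negligible.
`toy_trajectory` runs a Markov chain over size partitions (single-ion
detach/join at a hop rate, sizes capped at 4) and re-plants the geometry
each frame with a frozen box and solvent budget, so the composition is
constant across the trajectory; consecutive frames share partition
topology, not atom positions — sufficient for every downstream statistic,
which consumes partitions only, but not a model of diffusive dynamics
(cluster lifetimes or autocorrelations cannot be studied with it).

## Numerical choices and problem sizes

Tolerances: shell membership and eigen-decompositions are asserted at
1e-10–1e-12; GRO round-trips at the format's 1e-3 nm precision; planted
geometry constraints at 1e-9. Degenerate inputs: single-atom molecules fit
floor-sized ellipsoids; constant series give zero covariance and zero
variance fractions (no division by a zero trace); empty frames, unknown
molecule ids, non-orthorhombic boxes and unmapped atoms raise typed errors.
The test suite and the acceptance script use 100 planted 44-ion frames for
detector/oracle equivalence, 20 fixtures × 50 orderings for order
insensitivity, 10,000-frame series for mode recovery, 200 replicates for
the uncertainty-coverage property and 2,000-frame series per system for
the planted population-gap recovery — sizes at which the stochastic checks
are stable across seeds while the whole suite runs in well under a minute.

## Known limitations

Orthorhombic boxes only; text formats only (GRO/PDB/extended-XYZ — binary
XTC/TRR are out of scope, though MDAnalysis can convert); the
accumulated-members reading of the contact condition is an interpretive
choice (the alternative — contact with the previous shell's ions only —
can split elongated clusters whose links skip a shell); maximum errors are
a conservative heuristic, not a confidence interval; and the charge-merged
size classes discard composition information beyond the retained tally.
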