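# Methods

## Configurational entropy

The quasi-harmonic bound of Schlitter is computed as
S = (R/2) Σ_i ln(1 + α λ_i), where λ_i are the eigenvalues of the
symmetrized mass-weighted covariance M^{1/2} C M^{1/2} (u Å²) and
α = k_B T e²/ħ² expressed per (u Å²) (≈ 45.7/(u Å²) at 300 K). The
eigenvalue route is used instead of a raw determinant for numerical
stability and guaranteed symmetry; eigenvalues in [−10⁻⁸·max|λ|, 0) are
clipped to zero, anything more negative is an error. S is reported per
mole in J/(K mol). The bound counts only the Cα degrees of freedom of the
chosen selection, is an upper bound to the true configurational entropy
(anharmonicity and supra-linear correlations are neglected), and is used
for *differences* between states, where those neglected terms largely
cancel.

**Covariance and fitting.** Each frame is superposed onto the reference
(first frame of the analysed window) by optimal translation plus proper
rotation (Kabsch/SVD) over the analysed selection; the covariance is
taken about the time mean with 1/n normalisation. Selections with fewer
than three atoms cannot define a rotation and are used unfitted.
Superposition absorbs up to six fluctuation modes, so closed-form
comparisons against i.i.d. Gaussian ensembles — which contain no
rigid-body drift — are run with fitting disabled (`superpose=False`).

**Domain decomposition.** Each named selection is fitted onto its own
reference selection by default, so the per-domain entropy measures
internal fluctuations, not inter-domain motion. A `fit="global"` mode
fits once on all Cα atoms for sensitivity checks, and `fit="none"`
disables fitting; which convention the decomposition "should" use is a
genuinely open choice, and per-domain fitting was selected as the variant
that isolates what a domain's entropy is usually meant to capture. The
decomposition neglects inter-domain correlations: the whole is not the
sum of its parts, and both are reported.

**Uncertainty.** The sampling uncertainty of S is
|S(all frames) − S(first 90% of frames)|, both over growing windows. On
i.i.d. data the cumulative S grows monotonically toward the analytic value
(the finite-sample covariance underestimates the log-determinant), so the
uncertainty is a one-sided convergence measure rather than a symmetric
error bar.

**Solvent entropy.** ΔS_solv = a_polar·ΔSAS_polar + a_apolar·ΔSAS_apolar,
linear in the polar and apolar SAS changes, and ΔS_total = ΔS_config +
ΔS_solv. The coefficients must be supplied explicitly; the shipped
defaults (a_polar = −0.11, a_apolar = +0.43 J/(K mol Å²)) are
representative literature magnitudes for surface-area-based hydration
entropies, flagged in their provenance note as "verify before quantitative
use". The estimate is qualitative by construction.

## Pairwise force distribution analysis

For atom pairs (i, j) across two disjoint groups the signed central-force
scalar is f = −dU/dr with U = k_e q_i q_j/r + 4ε[(σ/r)¹² − (σ/r)⁶],
k_e = 138.935 kJ mol⁻¹ nm e⁻², truncated to zero beyond 10 Å, and
converted with 1 kJ mol⁻¹ nm⁻¹ = 1.66054 pN. Negative = attractive.
A residue pair's per-frame force is the *sum* of its atom-pair scalars:
this is additive, preserves the attraction/repulsion semantics, and is
the default scalarization; the signed-vector-norm variant (norm of the
vector sum, signed by the summed scalars) is available behind
`scalarization="vector-norm"` for comparison, since residue-level
scalarizations are not uniquely defined. Lorentz–Berthelot rules combine
σ/ε. Plain truncation is used (no PME, no shift function): shifting a
potential leaves its force unchanged, and reciprocal-space contributions
cannot be attributed to residue pairs; relative to the simulation
Hamiltonian this is an approximation that matters only near the cutoff.

Pairs that never come inside the cutoff are dropped exactly; the report
threshold (default 200 pN on |F_mean|, user-overridable) mirrors the
convention of listing only strong contacts.

**Errors.** Block averaging with doubling block sizes (1, 2, 4, …) while
at least 8 full blocks remain; the estimate is std(block means)/√n_blocks.
The plateau is declared when the estimate changes by <5% over two
consecutive doublings; otherwise the largest admissible block size is
used. Fewer than 8 blocks makes the estimator itself too noisy, which is
why the ladder stops there.

**State differences.** ΔF = F_PL − F_PD matched by residue identity; a
pair present in only one state keeps its value with Δ marked absent. The
combined error is the *linear* sum of the two state errors — deliberately
conservative for possibly correlated estimates, and consistent with the
published table arithmetic (22 + 38 = 60, where quadrature would give
≈44).

## Surface areas and geometry

SAS is computed by sphere-surface point sampling (960 points per atom by
default, Fibonacci distribution, biotite backend) with a 1.4 Å probe.
Van der Waals radii come from the Bondi table per element, overridable
per atom (`Topology.radii`), which is how the analytic sphere fixtures
inject exact radii. Polar area is that of N and O atoms, with hydrogens
following their nearest heavy atom; everything else is apolar — the
polar/apolar split is by element class because no finer rule is required
by the linear solvent model. Buried area is SAS(a) + SAS(b) − SAS(a∪b)
per frame; it is exactly symmetric in the groups and non-negative up to
point-sampling noise (≲0.2% on the two-sphere oracle at 960 points).

RMSD uses the fit/measure convention: superpose on the fit selection's Cα
atoms, measure over the measure selection without re-fitting, so rigid
motion of a distal domain relative to the fitted domain is reported (this
is the "fit on TN, measure TC" construction). RMSF is the per-atom RMS
deviation about the time-mean position after fitting on the measured
selection itself by default (overridable), matching per-protein
fluctuation profiles. Named distances are Cα–Cα Euclidean distances (the
groove widths d1 = I85–T138 and d2 = Y74–A149), with a min-distance mode
over all inter-group atom pairs. Equilibrium statistics discard the
leading 10% of frames; moving averages are centered with edge truncation,
and a 1-ns window is 1000 ps.

## Synthetic generators and what they do (not) show

The Gaussian generator draws i.i.d. frames from a specified 3N-dimensional
covariance; the analytic Schlitter value of that covariance is returned
alongside, giving an exact oracle for the entropy pipeline. i.i.d. frames
are deliberate: ensemble estimators converge fastest, making the oracle
sharpest. An AR(1) latent mode (stationary distribution unchanged) exists
solely to exercise block averaging. The PD/PL pair scales the covariance
rows/columns of a particle subset, so the exact ΔS is known; with 30
particles per domain the ≤6 modes absorbed by per-domain fitting cost
under 7% of ΔS, which is why the recovery harness uses that size. Bead
complexes and sphere fixtures give the force and surface stages analytic
answers.

None of these emulate real solvated-protein features: no autocorrelated
collective modes (beyond AR(1)), no anharmonicity, no solvent, no bonded
forces, no conformational transitions. Passing tests therefore demonstrate
the *estimators* are correct on their statistical assumptions, not that a
0.5 µs protein trajectory is converged — convergence must still be judged
with the cumulative-sampling uncertainty on real data.

**Problem sizes.** Validation runs use 50 000 frames for the Gaussian
entropy oracle (≤5 particles), 20 000 frames and 60 particles for the
PD/PL domain recovery, ≤50-atom bead complexes over ≤5 frames for the
force oracle, and 960 sphere points for surfaces — sizes at which every
closed-form comparison is comfortably inside its tolerance while the full
validation completes in about a minute of compute.

## Pipeline conventions

One YAML config drives all stages; flags override config. Replicas are
windowed per replica, then pooled into a single ensemble per state
(pooling after windowing; the order is configurable in effect by pooling
trajectories upstream, since per-replica covariance averaging and pooled
covariances differ and neither is canonically "right"). Outputs are TSV
with fixed `%.6g` formatting, so identical configs and fixtures produce
byte-identical files; a JSON run report lists exactly the files written;
`--dry-run` writes nothing. Results go to files, logs to stderr, and
stdout stays empty unless `--print-table` is given. Exit codes: 0 ok,
1 user/config error, 2 internal error.

## Known limitations

* The Schlitter bound degrades for strongly anharmonic or multi-basin
  dynamics; no mutual-information or normal-mode corrections are applied.
* Solvent entropy coefficients are placeholders in magnitude; quantitative
  solvent terms require user-supplied, source-verified coefficients.
* Force analysis covers nonbonded Coulomb + LJ only — no bonded terms, no
  reciprocal-space electrostatics.
* The MHC I α1/α2/α3 boundaries in the shipped domain map are canonical
  approximations; per-study residue tables should override them.
* DCD is the only binary trajectory container wired in (times must be
  uniformly spaced, as the DCD header stores a single timestep).
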