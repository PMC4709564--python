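# pepedit

Trajectory analysis for the molecular mechanism of MHC class I peptide
editing by tapasin: quasi-harmonic configurational entropy with domain
decomposition, pairwise residue–residue force distribution analysis (FDA),
solvent-accessible and buried surface areas, and the geometric observables
(fit/measure RMSD, RMSF, groove-width distances) used to compare the
peptide-deficient (PD) and peptide-loaded (PL) states of the tapasin–MHC I
complex.

It is written for structural bioinformaticians and molecular-simulation
practitioners who want these comparative PD-vs-PL analyses as a tested,
reusable library and command-line pipeline — and who want every stage
verifiable against synthetic ensembles with known ground truth, because
multi-microsecond production trajectories are rarely shareable.

## What it computes

**Configurational entropy.** The Schlitter quasi-harmonic upper bound

    S = (R/2) ln det[ 1 + (k_B T e²/ħ²) M^{1/2} C M^{1/2} ]

where **C** is the covariance matrix of Cα positional fluctuations after
least-squares removal of overall translation and rotation, **M** the
diagonal mass matrix, *T* the temperature and *e* Euler's number; the
result is per mole, J/(K mol). The determinant is evaluated through the
eigenvalues of the symmetrized mass-weighted covariance. Domain
decomposition evaluates the same bound per named selection (α1, α2, α3,
β2m, Ag, TN, TC) to localize entropy changes; the sampling uncertainty is
the difference between the entropy over all frames and over the first 90%
of frames. A linear polar/apolar SAS relation supplies the solvent-entropy
estimate, and ΔS_total = ΔS_config + ΔS_solv.

**Pairwise forces (FDA).** For two atom groups (e.g. tapasin TN + peptide
vs MHC I α1+α2), the per-frame sum of signed central-force scalars
−dU/dr (Coulomb + Lennard-Jones 6–12, 10 Å cutoff) over the atom pairs of
each residue pair, time-averaged, with block-averaged errors. Negative
forces are attractive. State-difference tables report ΔF = F_PL − F_PD
with linearly summed errors.

**Geometry.** Shrake–Rupley-style SAS (1.4 Å probe) with a polar/apolar
split, buried interface area SAS(a)+SAS(b)−SAS(a∪b), RMSD with independent
fit and measure selections (e.g. fitting on TN while measuring TC), RMSF,
named Cα–Cα distances such as the groove widths d1/d2, threshold
fractions, equilibration windowing (discard the first 10%) and 1-ns moving
averages.

**Synthetic ground truth.** Multivariate-Gaussian ensembles with known
covariance (hence known entropy), paired PD/PL ensembles differing by a
controlled covariance change, charged Lennard-Jones bead complexes with
analytic pairwise forces, and sphere clusters with analytic surface areas.

## Worked example

Generate a small self-consistent PD/PL bead-complex fixture set and run
the full pipeline on it:

```sh
pepedit synth -o demo --seed 7 --n-frames 200
cd demo && pepedit all -c config.yaml
```

`out/forces_delta.tsv` (abridged) then contains:

```
group1  group2  F_PD_pN   F_PD_err_pN  F_PL_pN   F_PL_err_pN  dF_PD_to_PL_pN  dF_err_pN
BEA1    BEB1    -638.662  3.1935       -360.317  1.41528      278.345         4.60878
BEA3    BEB1    -222.889  1.06683      -143.496  0.551573     79.3934         1.6184
```

The dominant bead pair is strongly attractive (−639 pN) in the PD state;
in the PL state the second group sits 2 Å farther away, so the attraction
weakens and ΔF is positive (+278 pN, "less attractive"), exactly the kind
of signature that distinguishes a force that is released upon peptide
loading. The `distance_*_d1.tsv` series confirm the construction: the mean
bead-pair distance is 6.02 Å (PD) vs 8.01 Å (PL), a 2 Å separation of the
distance modes. `out/entropy_delta.tsv` reports per-domain ΔS = S_PL −
S_PD in J/(K mol) with convergence uncertainties.

The same stages are available as library calls (`residue_pair_forces`,
`entropy_by_domain`, `buried_surface`, `rmsd_series`, ...) on any
PDB + DCD + parameter-sidecar inputs; selections come from a YAML domain
map (a default map for the tapasin–MHC I B*44:02 system ships with the
package, with the MHC I domain boundaries marked approximate).

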