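# Methods

`cysred` reimplements, as a tested pipeline over synthetic ground truth, the
analysis chain used to study disulfide-bond reduction susceptibility in IgG1
monoclonal antibodies: differential-alkylation quantitation of free thiols,
pseudo-first-order reduction kinetics under mild DTT stress, structural
descriptors (solvent accessibility and S–S bond stiffness) from trajectory
frames, and the accessibility–rate correlation.

## The measurement model

A cysteine that carries a free thiol at the moment of NEM exposure is
alkylated with N-ethylmaleimide (+125.047679 Da, C6H7NO2); every cysteine
still disulfide-bonded at that point is later reduced under denaturing
conditions and carboxymethylated with sodium iodoacetate (+58.005479 Da,
C2H2O2). The two species of each tryptic peptide are separated by
67.042200 Da and quantified by extracted-ion-chromatogram peak areas over
two charge states × three isotopes. (Some descriptions of this chemistry
quote the NaIAA shift as "+67 Da"; that figure is the NEM–NaIAA
*difference*. The per-adduct values above are the chemically consistent
monoisotopic deltas and are what the package computes from its elemental
constants table.)

The measured NEM fraction of a single-cysteine peptide at exposure time τ is

    F(τ) = A_NEM / (A_NEM + A_CAM),

with areas summed over charge states, isotopes, and the two diastereomer
retention-time peaks that NEM alkylation produces (it creates a
stereocenter). Unlabelled peptide signal is monitored but excluded from the
denominator; a warning fires if it exceeds 1% of the total. Observations
failing mass accuracy (|error| > 5 ppm) or isotope-envelope similarity
(idotp < 0.9) are dropped per charge state, not per peptide-timepoint (the
alternative is configurable).

The two hinge cysteines (C229/C232, mature numbering) share one tryptic
peptide, giving four monitored species (NEM/NEM, NEM/CAM, CAM/NEM,
CAM/CAM). The default total-hinge fraction counts every NEM-containing
species at full weight:

    F_hinge = (A_NN + A_NC + A_CN) / (A_NN + A_NC + A_CN + A_CC).

This weights singly-labelled molecules upward relative to the per-site
expectation (2·A_NN + A_NC + A_CN)/(2·total), which is provided behind a
flag for sensitivity analysis. A consequence worth knowing when reading
rate tables: with independent sites, 1 − F_hinge = (1 − F₁)(1 − F₂), so the
rate fitted to the total-hinge series is the *sum* of the two site rates.

## Kinetics

Reduction under excess (1 mM) DTT is pseudo-first-order: dC/dt = −kC for
the oxidized population, hence

    1 − F(τ) = (1 − F0) · exp(−k τ),

with F0 the baseline free-thiol fraction. The default estimator is ordinary
least squares of ln(1 − F) on τ (k = −slope, F0 = 1 − exp(intercept)); the
τ = 0 point participates, so the baseline is estimated rather than assumed.
The closed-form per-timepoint estimator k = [ln(1−F0) − ln(1−F(τ))]/τ
averaged over τ > 0 is available as `per_timepoint_mean`; the two are
identical on noise-free data. Weighting of timepoints is not used (whether
the original fits weighted them is unknown; unweighted OLS is the
documented default).

Numerical choices:

* points with 1 − F < 0.01 (saturation floor, configurable) are excluded
  and reported — ln(1 − F) is unstable as F → 1, which hinge residues
  approach within an hour;
* a negative raw slope is clipped to k = 0 and flagged;
* optional bootstrap CIs resample log-residuals (1000 draws, seeded); CIs
  are an additive feature of this package, not part of the emulated study;
* class-level fold changes use geometric means of fitted rates; clipped
  k = 0 fits carry no log information and are excluded from the mean but
  counted in the result.

Identifiability: with the 7-point design (0–60 min), rates k ≥ 1e-3/min are
recovered with <10% median bias at realistic area noise; for k ≤ 1e-4/min
the 60-minute window moves F by ≤ 0.6%, and the estimate is dominated by
noise. The test suite asserts this widening rather than hiding it.

## Structural descriptors

**Shrake–Rupley SASA** is implemented from scratch: each atom's sphere of
radius r_vdW + probe (Bondi radii, probe 1.4 Å) carries n quasi-uniform
golden-spiral test points (default 960, no RNG — results are
bit-reproducible); a point is accessible if outside every neighbour's
expanded sphere, with neighbour candidates restricted to r_i + r_j + 2·probe.
Before point placement the structure is canonicalized to a principal-axes
pose (eigenbasis ordered by variance, signs fixed by third moments). The
canonicalization is covariant under proper rigid motions, which makes the
discretized SASA *exactly* translation- and rotation-invariant for generic
structures — a naive lab-frame implementation varies by O(1/n_points) (about
0.5% at 960 points) under rotation. Residue SASA sums all atoms of the
residue, hydrogens included when present; a frame-range option allows
excluding equilibration frames. Accuracy: ≤0.5% against analytic
sphere/dimer areas at 960 points; within 2% of an independent 100k-point
Monte-Carlo rejection oracle on random clusters (compared at 3840 points,
where discretization error is well inside the band, and allowing the
oracle's own 3σ binomial noise, which reaches ~2% on nearly-buried atoms).

**Bond geometry and stiffness.** Per frame, the Sγ–Sγ′ distance and the two
sulfur orientation angles Θ1, Θ2 are extracted; Θ is concretized as the
Cβ–Sγ–Sγ′ angle at each cysteine (the original definition lives in an
unavailable appendix — this convention is documented, not asserted to
match). The stiffness is κ_SS = kB·T/σ² at T = 300 K (kB·T = 0.596162
kcal/mol), with σ² the maximum-likelihood (n-denominator) variance of the
distance series — for normally distributed data this *is* the normal fit,
without a histogram-binning choice. A zero-variance series yields an
infinite-stiffness flag, not an exception.

**Cystine fixture dynamics.** No external MD engine is assumed. A four-site
cystine disulfide core (CB–SG–SG′–CB′, CB as united CH2) with Amber-type
bonded terms (S–S: K = 166 kcal·mol⁻¹·Å⁻², r0 = 2.038 Å; C–S: K = 227,
r0 = 1.810 Å; C–S–S angle: K = 68 kcal·mol⁻¹·rad⁻², θ0 = 103.7°; X–S–S–X
torsion 3.5/0.6 kcal/mol, n = 2/3) is integrated with the BAOAB Langevin
scheme (dt = 1 fs, friction 1 ps⁻¹, 300 K). Analytic forces are validated
against finite differences of the energy in the tests. The sampled S–S
distribution is normal with mean ≈ 2.04 Å (tracking r0; all-atom
simulations of full antibodies report ≈ 2.1 Å) and σ² ≈ kB·T/(2K), i.e.
κ_SS ≈ 330–390 kcal·mol⁻¹·Å⁻² including angle coupling. This is a fixture
generator — bonded terms only, no non-bonded forces, no solvent model
beyond the Langevin bath.

## Synthetic world

The generator states, rather than tunes, the experimental conditions:
timepoints τ ∈ {0, 1, 5, 10, 15, 30, 60} min at 1 mM DTT; species split by
the forward model above; two charge states (2+, 3+ at a 60/40 intensity
split) × three isotopes (Poisson envelope, λ = 0.0006 × monoisotopic mass —
cheap, mass-monotone, and irrelevant downstream where areas are summed);
NEM species split 60/40 over two diastereomer peaks; hinge sites simulated
independently (no within-molecule correlation model exists to emulate);
multiplicative lognormal area noise (default CV 0.05 — replicate counts
and CVs are unreported in the emulated study, so these are explicit,
config-surfaced placeholders), ppm jitter N(0, 1.5), idotp ~ U(0.92, 1).
All randomness flows through one seed; fixed-seed output is byte-identical.

Ground-truth rates are tied linearly to ground-truth accessibility,
k = 1.6e-4 · SASA, with class-level SASA (interchain 62, hinge 8, SEFL 0.6,
intrachain 0.06 Å², lognormal jitter σ = 0.25) chosen so the class rates
reproduce the stated ~1000-fold interchain/intrachain contrast (1e-2 vs
1e-5 /min); the hinge rate is overridden to 2e-2/min so hinge points sit
*above* the SASA–k line, reproducing the observation that including hinge
residues depresses the correlation. Baseline F0 = 0.01, below the reported
<5% free-thiol ceiling.

The example molecule is a synthetic IgG1 stand-in (real therapeutic
sequences are proprietary): deterministic sequences with cysteines at the
canonical mature-linear positions, the CH2 intrachain pair at placeholder
positions HC:C264/HC:C324 (user-overridable), lysines placed so every
cysteine lands on a well-sized tryptic peptide except HC:C223, whose
peptide is deliberately 4 residues — below the retention threshold of 5 —
so it reports "ND" like its conserved real counterpart. The canonical map
counts are 12 intrachain + 2 LC–HC interchain + 2 hinge (+2 SEFL).

What a green test does **not** establish: real chromatographic
interference, isotope-envelope distortion, charge-state-dependent QC
failure correlation, within-molecule hinge cooperativity, or real antibody
structure — the SASA stage is validated on analytic and Monte-Carlo
fixtures, not on a folded IgG1.

## Correlation

Pearson r and an OLS line on raw (SASA, k) values — the modelled relation
is linear; a log-log option exists behind a flag given the ~1000-fold
dynamic range. Hinge pairs are excluded by default and reported, and the
hinge-included r is always computed alongside for the sensitivity
comparison. Zero variance in either axis returns an undefined-correlation
result with a reason, not an exception. The per-molecule pairing of rate
tables with structures (kappa vs lambda light-chain isotypes) is an
explicit config mapping, never inferred.

## Interfaces

Chains are read from FASTA (ids `LC`, `HC`); the cysteine registry is JSON
(`{chain, position, bond_class, partner}` per cysteine, both directions
present and mutually consistent). Peak tables are CSV, fraction/rate tables
TSV, structures single- or multi-model PDB (plus a minimal XYZ reader);
all CLI artifacts carry a `#` provenance header (config hash, seed,
version) and contain no timestamps, so identical config + seed reproduces
byte-identical files. Mature linear numbering (1-based, signal-peptide-free)
is the only coordinate system; IMGT/Kabat/EU mappings are out of scope.

## Known limitations

* The hinge rate from the four-peak total fraction is k₁+k₂, not a
  per-site rate (see above); per-site hinge rates require the per-site
  fraction variant.
* The cystine model's equilibrium length follows its force-field r0
  (2.038 Å), about 0.06 Å below the 2.1 Å seen in all-atom antibody
  simulations.
* The SASA pose canonicalization can be unstable for structures with
  (near-)degenerate principal axes or vanishing third moments; values stay
  valid, only exact rotation invariance may degrade to the O(1/n_points)
  level there.
* `per_timepoint_mean` requires a τ = 0 observation; `log_linear` does not.
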