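# cysred

Disulfide-bond reduction susceptibility analysis for IgG1 antibodies.

Monoclonal IgG1 antibodies hold their four chains together with 16 canonical
disulfide bonds (12 intrachain, 2 light–heavy interchain, 2 heavy–heavy in
the hinge; engineered SEFL molecules add a CH2 pair). Which of these bonds
break first under reducing stress is a product-quality question: free
cysteines scramble, aggregate, and cost potency. This package implements the
full analysis chain that answers it with differential alkylation:

1. **Topology** — chains, cysteine registry, bond classification, in-silico
   tryptic digestion, monoisotopic mass/adduct arithmetic
   (NEM +125.047679 Da, carboxymethyl +58.005479 Da).
2. **Quantitation** — Skyline-style peak areas (2 charge states × 3
   isotopes, diastereomer double peaks summed; |ppm| ≤ 5 and idotp ≥ 0.9 QC)
   to per-cysteine NEM fractions F(τ), including the four-species hinge
   formula.
3. **Kinetics** — pseudo-first-order rates from
   1 − F(τ) = (1 − F0)·e^(−kτ): log-linear OLS of ln(1−F) on τ (default) or
   the closed-form per-timepoint estimator; class fold changes by geometric
   means.
4. **Structure** — from-scratch Shrake–Rupley SASA (deterministic
   golden-spiral points, principal-axes pose so results are exactly
   rigid-motion invariant), S–S bond geometry, and stiffness
   κ_SS = kB·T/σ² at 300 K; plus a minimal Langevin integrator for a
   cystine disulfide model used as the trajectory fixture.
5. **Correlation** — Pearson r and OLS line of k against per-cysteine mean
   SASA, hinge excluded by default (hinge bonds reduce faster than their
   accessibility predicts).

A synthetic-data generator supplies ground truth for every stage: peak
tables over the τ ∈ {0,1,5,10,15,30,60} min, 1 mM DTT time course with
known (k, F0) per cysteine; harmonic bond-length series with known
stiffness; toy structures with analytic SASA. See `docs/methods.md` for the
model details and stated defaults.

## Worked example

Run the numbered analysis scripts from the repository root (each writes its
tables under `results/`; stage 1 regenerates the ~250 KB peak table, which
is not checked in):

```sh
python analysis/01_simulate.py
python analysis/02_quantify.py
python analysis/03_fit_kinetics.py
python analysis/04_structure.py
python analysis/05_correlate.py
```

Stage 2 and 3 print the class-level picture:

```
mean NEM fraction at 60 min by bond class:
  hinge       0.913
  interchain  0.533
  SEFL        0.015
  intrachain  0.010
...
interchain/intrachain geometric-mean fold change: 1,791
hinge/intrachain geometric-mean fold change: 5,774
```

— hinge and interchain cysteines are orders of magnitude more susceptible
to 1 mM DTT than buried intrachain ones, and the recovered fold change sits
in the expected 100–10000 band for a 1000× simulated contrast. Stage 5
closes the loop structurally:

```
SASA vs k over 15 cysteines (hinge excluded):
  Pearson r = 1.0000  (including hinge: 0.3381)
  best linear fit k = 1.611e-04 * SASA + -2.80e-06
```

The fitted slope recovers the simulated coupling (1.6e-4 min⁻¹ Å⁻²), and
the hinge-included r collapses because hinge bonds reduce ~25× faster than
their modest accessibility predicts. Stage 4 reports the cystine-model S–S
bond: mean 2.039 Å, σ 0.039 Å, κ_SS ≈ 393 kcal·mol⁻¹·Å⁻².

The same chain is available as a CLI:

```sh
cysred --seed 1 --outdir out full      # simulate → … → correlate
cysred --config my.json quantify       # single stage, JSON config
```

All artifacts are plain text with a provenance header; identical config and
seed reproduce byte-identical files.

## Acceptance script

`scripts/acceptance.py` recomputes the package's externally anchored
structural quantity from scratch: it runs ~1 ns of implicit-solvent-style
Langevin dynamics of the disulfide-bonded cystine model at 300 K, extracts
per-frame Sγ–Sγ′ distances with `bond_geometry`, fits a normal
distribution, and reports the mean S–S bond length (Å):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(~3 min on one CPU.)
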