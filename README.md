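# affimut

Antibody affinity maturation by structure-based screening, with the
wet-lab follow-up analysis built in.  `affimut` is for computational
structural biologists and protein engineers who want to (1) run an
in-silico saturation mutagenesis of antibody CDR residues against a bound
antigen and rank candidate muteins by interaction energy, and (2) analyze
the SPR kinetics and binding thermodynamics of the candidates they then
measure.

## What it computes

**Screening.**  For every selected CDR position, all 19 substitutions are
modeled as randomized rotamer ensembles (side chains rebuilt from ideal
geometry, perturbed, annealed, and energy-minimized to an RMS gradient of
0.01 kcal mol⁻¹ Å⁻¹ with backbones fixed).  Each model is scored by the
antibody–antigen nonbonded energy

&nbsp;&nbsp;&nbsp;&nbsp;*E* = Σᵢⱼ [ *k*_C *q*ᵢ*q*ⱼ/(ε *r*ᵢⱼ) + εᵢⱼ((*r*ₘᵢₙ/*r*ᵢⱼ)¹² − 2(*r*ₘᵢₙ/*r*ᵢⱼ)⁶) ],&nbsp;&nbsp;ε = 80

summed over cross-partner atom pairs.  Models without antigen contact are
filtered out; the score of a mutation is the median shift of its ensemble
relative to a wild-type reference ensemble, ΔE = median(mut) − median(WT),
negative favoring binding.

**Characterization.**  From rate constants: *K*_D = *k*_off/*k*_on and
ΔG° = *RT* ln *K*_D.  From temperature series: van't Hoff
(ln *K*_D vs 1/*T* → ΔH°, ΔS°) and Eyring
(ln(*k*_on·*h*/(*k*_B*T*)) vs 1/*T* → ΔH‡, ΔS‡) regressions, ΔΔ-tables vs
a reference variant, and an enthalpy/entropy compensation summary.  Raw
sensorgrams are fitted globally with a 1:1 Langmuir model.

Synthetic generators (toy helix complexes with planted charge
complementarity, simulated kinetics and sensorgrams with known ground
truth) make every stage testable end to end; see `docs/methods.md`.

## Worked example

The package bundles the published 25 °C kinetic table of the anti-MCP-1
scFv 11K2 and its muteins.  Recompute *K*_D, fold-changes and improvement
calls:

```sh
affimut kd --table src/affimut/data/kinetics_11k2_25c.tsv
```

prints (abridged):

```
            kon    koff  KD_nM  fold_change  improved  kd_consistent  dG_kcal_mol
variant
WT      1.4e+05  0.0001  0.714            1     False          False        -12.5
L-N31R  1.3e+05 2.2e-05  0.169         4.22      True           True        -13.3
L-S53E  7.3e+04 1.4e-05  0.192         3.72      True           True        -13.3
L-T56D  2.2e+05 8.6e-05  0.391         1.83      True           True        -12.8
L-N31K  3.4e+05   0.098    288      0.00248     False           True        -8.92
```

Reading this: L-N31R binds ~4-fold tighter than wild type
(*K*_D 0.17 nM vs 0.71 nM recomputed from the rates), driven by its
10-fold slower *k*_off.  `kd_consistent=False` on the WT row flags that
the printed *K*_D (0.80 nM) disagrees with its own printed rate ratio by
more than 5 % — the tool reports such internal inconsistencies instead of
resolving them.  Five of the twelve muteins are improved, all of them in
the light chain.

Delta energetics and compensation from the published van't Hoff fits:

```sh
affimut deltas --thermo src/affimut/data/thermo_11k2.tsv
affimut compensation --thermo src/affimut/data/thermo_11k2.tsv
```

```
           dH  mTdS    dG   ddH  mTddS  ddG
WT       -7.3  -5.0 -12.3   0.0    0.0  0.0
L-N31R  -25.6  12.3 -13.3 -18.3   17.3 -1.0
...
slope(-TddS on ddH) = -0.955, intercept = -0.126, R2 = 0.999
  L-N31R: efficiency ddG/ddH = 0.055
```

L-N31R gains 18.3 kcal/mol of binding enthalpy but entropy compensates
almost all of it (slope ≈ −1): only ~5 % of the enthalpy advantage
survives as free energy (ΔΔG° = −1.0 kcal/mol).

A self-contained screening run on a generated toy complex:

```sh
affimut simulate toy-complex --out toy.pdb --seed 0
affimut screen --pdb toy.pdb --partition A:A,B:B --positions A:5 \
    --n-models 20 --n-wt 50 --seed 1 --out-dir screen_out
```

writes `report.tsv` with one row per substitution (n_valid, median, ΔE,
selected flag), `histograms.json` with the wild-type reference
distribution, and a provenance record (seed, config hash, version).

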