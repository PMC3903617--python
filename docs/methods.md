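# Methods

`affimut` implements a two-stage antibody affinity-maturation analysis: an
in-silico saturation mutagenesis screen of antibody CDR residues scored by
the antibody-antigen nonbonded interaction energy, and an SPR-side
kinetic/thermodynamic characterization of candidate muteins.  This note
records the models, the tunable parameters, and the design choices that
were genuinely open.

## Interaction-energy surrogate

Binding affinity is approximated by the cross-partner nonbonded energy

    E = sum_{i in antibody, j in antigen} [ k_C q_i q_j / (eps_r r_ij)
          + eps_ij ((rmin_ij / r_ij)^12 - 2 (rmin_ij / r_ij)^6) ]

with `k_C = 332.0637 kcal A / (mol e^2)`, a uniform relative dielectric
`eps_r = 80` mimicking water, Lorentz-like combination
`rmin_ij = rmin_i/2 + rmin_j/2` doubled per-atom halves, and
`eps_ij = sqrt(eps_i eps_j)`.  Intra-partner pairs never contribute.  There
is no distance-dependent dielectric and no solvation term.  The default is
the exact full double sum (complexes here are small); an optional hard
cutoff with no switching function is available and its discontinuity is
documented behavior.

### Parameter table

The bundled united-atom table (`data/forcefield_united_v1.tsv`) covers every
heavy atom of the 20 standard residues.  Hydrogens are omitted; their
partial charges are folded into the bonded heavy atoms, so per-residue
charges sum exactly to the formal charge (0, or +-1 for Asp/Glu/Lys/Arg).
Histidine is treated as neutral; termini carry no extra charge.  rmin/2 and
SASA radii follow standard element values (C 1.908/1.70, N 1.824/1.55,
O 1.661/1.52, S 2.000/1.80 A).

The Lennard-Jones well depths are **half** of typical explicit-atom values
(C 0.055, N 0.085, O 0.105, S 0.125 kcal/mol).  Rationale: net dispersion
between protein surfaces in water is strongly screened by the competing
protein-water dispersion, and this score is explicitly designed so that
charge complementarity dominates interface energetics — the signal the
screen exists to detect.  With full well depths, accumulated dispersion
from bulky aromatic side chains overwhelms the electrostatic term at
`eps_r = 80` and the screen degenerates into a bulk detector.  The table is
versioned and user-replaceable (`--params`); absolute energies from this
surrogate are not comparable to any particular force-field implementation,
and no absolute published energy is used as a target anywhere.

## Mutant construction and relaxation

Side chains are built from ideal internal coordinates (bond lengths,
angles, ring closures per residue type) with chi angles drawn from a
coarse backbone-independent rotamer library (<= 4 rotamers per type,
priors summing to 1; whitespace-delimited, user-replaceable).  Backbone
atoms (N, CA, C, O) and the CB anchor never move, anywhere in the pipeline.
Proline targets and disulfide-bonded cysteines are rejected by default:
their geometry is not representable with a fixed backbone.

Each randomized model — wild-type reference and mutant alike — is
generated by the same protocol:

1. for a mutant, substitute the residue (geometry from the template);
2. resample **every** movable side chain's rotamer from the library prior
   and jitter its chi angles with Gaussian noise (sigma 15 deg default);
   a pinned rotamer policy on the mutated site is honored;
3. optionally, cooled greedy descent in the mutated residue's chi space
   (`anneal_cycles`, default 0 — see below);
4. Cartesian minimization of the movable side-chain atoms.

The strict symmetry of steps 2-4 between the wild-type reference and the
mutant ensembles is what makes the delta-E statistic unbiased: re-running
the wild-type identity through the mutant pipeline shifts the median by
less than the bootstrap error of either ensemble.  Two earlier asymmetric
variants — annealing only the mutated side chain, and resampling the
rotamer only at the mutated site — each produced a measurable control
offset (~0.03 kcal/mol), which is why annealing is off by default and the
resampling covers all movable side chains.

The minimization objective is the cross-partner nonbonded energy plus the
nonbonded energy among movable atoms of different residues plus harmonic
restraints holding bond lengths and 1-3 distances at their ideal values
(k = 50 and 15 kcal/mol/A^2).  Nonbonded terms within one residue are
excluded; the restraints keep its geometry near-rigid.  The optimizer is
limited-memory quasi-Newton (L-BFGS-B) with a diagonal preconditioner from
the restraint stiffnesses and a stopping callback on the RMS Cartesian
gradient over movable atoms, threshold 0.01 kcal/mol/A.  "Mean square
gradient below 0.01" is read as this RMS criterion.  The energy trace is
non-increasing by construction of the line search, and the two-atom
Lennard-Jones dimer recovers its analytic minimum to better than 1e-3 A
at a tightened threshold.

### Movable set

By default the screen relaxes a *fixed, symmetric* movable set: every
rotatable side chain (both partners) with a heavy atom within 8 A of the
other partner, identical for the wild-type reference and every mutant
ensemble (the mutated position is always added).  An earlier asymmetric
variant — mutated side chain plus its 6 A neighborhood for mutants, but
interface contacts only for the reference — biased every delta-E downward
by roughly the extra relaxation depth and pushed the wild-type-identity
control to -2 kcal/mol instead of 0; the symmetric set restores the control
to ~0, which is the property the screen's statistics rely on.  The local
policy remains available (`ScreeningConfig.movable_policy = "local"`).

## Screening statistics

For each position, all 19 substitutions are enumerated (deterministic
order).  Models whose relaxed structure has no cross-partner heavy-atom
pair within the contact cutoff (4.5 A default; the notion of "lacking
non-covalent interactions" is not standardized, so the cutoff is exposed
as config) are filtered out and counted.  The score of a mutation is the
median of its surviving model energies minus the wild-type reference
median; the mean is computed and reported alongside.  Selection:
delta-E <= -1.0 kcal/mol and at least half the models surviving — both
thresholds are stand-ins for a visual histogram-shift judgment and sit in
config.  Ranking sorts ascending by delta-E with deterministic
tie-breaking by (chain, position, target).

Per-mutation random streams derive from `SeedSequence([master_seed,
crc32(mutation_id)])`, so reports are byte-identical regardless of
execution order or parallelism.

## Kinetics and thermodynamics

All constants live in one module: R = 1.9872e-3 kcal/mol/K,
k_B/h = 2.0837e10 /s/K, T_ref = 298.15 K.

* `K_D = k_off / k_on` (1 M standard state); `dG0 = R T ln K_D`, negative
  for sub-molar binders.  A supplied K_D that disagrees with the rate
  ratio by more than 5 % relative is flagged inconsistent and never
  silently corrected.
* van't Hoff: OLS of `ln K_D` on `1/T`; slope `dH0/R`, intercept `-dS0/R`
  (binding convention, so `dG0 = dH0 - T dS0 = R T ln K_D`).
* Eyring: OLS of `ln(k_on h / (k_B T))` on `1/T`; slope `-dHa/R`,
  intercept `dSa/R`.
* Both fits are unweighted by default (no weighting scheme is standard for
  this data); a per-point-variance weighted option was considered and left
  out of scope.
* Langmuir 1:1 global sensorgram fit: shared (k_on, k_off, R_max) across
  concentrations, association `R_eq (1 - exp(-(k_on C + k_off) t))` with
  `R_eq = R_max C / (C + K_D)`, dissociation single-exponential in k_off;
  least squares in log-parameter space (positivity); standard errors by
  the delta method from the Gauss-Newton covariance.  Bulk
  refractive-index jumps, baseline drift, and mass-transport limitation
  are not modeled — the synthetic generator matches this, which is what
  the round-trip tests do and do not demonstrate about instrument data.
* Delta tables subtract the reference variant; `ddG = ddH + (-T ddS)`
  holds exactly by construction.  Fold-change is `K_D_ref / K_D_mut`,
  improved means fold-change > 1.  The compensation summary regresses
  `-T ddS` on `ddH` over muteins and reports per-variant efficiency
  `ddG/ddH`.

## Synthetic data

* **Toy complexes**: two ideal alpha-helices (phi -57, psi -47, standard
  backbone internal coordinates) facing each other, side chains built from
  the rotamer library.  A planted pair is aimed by rotating each chain
  about its helix axis and tuning the inter-chain offset until the two
  CB anchors sit at a target distance.  These scaffolds are chemically
  plausible but lack loops, backbone flexibility, waters and real epitope
  composition — passing screens on them shows the pipeline's statistics
  work, not that any real antibody would rank the same way.
* **Planted benchmark**: serine site on the antibody helix facing a
  glutamate on the antigen at 9.5 A CB-CB — close enough for long charged
  side chains (Arg reach ~6.3 A, Lys ~5.5 A) to form contacts, far enough
  that short side chains stay distant.  The oracle enumerates every library
  rotamer of every substitution in the *static* environment (no
  minimization, exactly reproducible) and records the best rotamer's
  energy shift; agreement with the minimized pipeline is asserted at
  sign/rank level only.
* **Kinetics**: `k_on(T) = (k_B T/h) exp(-(dHa - T dSa)/(RT))`,
  `K_D(T) = exp((dH0 - T dS0)/(RT))`, `k_off = K_D k_on`, with
  mean-corrected multiplicative lognormal noise applied independently to
  both rates.  The default temperature grid is 7 points over 283-313 K
  (the underlying experiments' grids are not published; this is a
  plausible SPR range).  Default simulated variants use the published
  fitted parameters, under which the generated 25 C kinetics land within
  a factor ~2 of the published rate constants.
* **Sensorgrams**: the same Langmuir model run generatively, default 5 min
  association / 20 min dissociation (typical contact times), additive
  Gaussian RU noise.

## Problem sizes

The self-contained test bed uses 7-8 residue helices (~85 heavy atoms),
20-50 models per ensemble in tests and 100/1000 as the production
defaults, 20 master seeds for the stability study, 200 noise replicates
for fit-bias estimates, and 100 random complexes for the energy oracle.
These sizes were chosen so the statistics of interest (medians, sign
stability, bias) are resolved well inside their acceptance bands.

## Known limitations

* Fixed backbone everywhere; no loop remodeling, no explicit solvent, no
  polarization.  Absolute energies are surrogate-scale only.
* The rotamer library is coarse (2-4 rotamers/type); fine chi
  distributions and backbone-dependence are out of scope.
* The SASA operation (Shrake-Rupley, 960 points, probe 1.4 A) is an
  approximation used for interface description, never compared numerically
  against crystallographic interface areas.
* His protonation, termini and non-standard residues are fixed choices of
  the parameter table; mmCIF input is supported through the same reader
  but only PDB output is written.
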