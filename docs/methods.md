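# Methods

`petnano` models the desk-computable side of a degraded-PET-nanoparticle
study: polymer construction, a calibrated statistical emulator of
shock-compression degradation chemistry, functional-group and surface
censuses, a rigid-body implicit-solvent binding-site search over a protein
surface, and umbrella-sampling/WHAM free-energy extraction. Reactive and
explicit-solvent molecular dynamics are out of scope; wherever a stage of
the original workflow requires them, the package generates synthetic data
with known ground truth so that every downstream algorithm can be
validated quantitatively.

## Structure records

A `MolecularSystem` couples atom records (element, position in nm, charge
in elementary units, provenance origin, optional residue) with an
undirected bond graph over persistent integer ids. Ids are never
reindexed by edits: the altered-neighbourhood counter (ALT) and the
water-oxygen tally (N_Ow) both depend on identity being stable across the
degradation history. Provenance (`origin`) distinguishes polymer,
water-derived, protein and other atoms; N_Ow is simply the number of
`origin="water"` oxygens bonded into the main particle.

Internal units are nm / elementary charge / kJ/mol; PDB files (Angstrom)
are converted at the I/O boundary. Distance-based bond perception uses
Cordero-style covalent radii with a 1.2 tolerance factor, and LAMMPS-style
ReaxFF bond tables are read with a 0.3 bond-order threshold (both
configurable; 1.2 and 0.3 are the common post-processing conventions).

## Polymer builder

Chains are grown from an idealized ethylene-terephthalate repeat-unit
template (`-O-CH2-CH2-O-CO-C6H4-CO-`, 1 nm period, idealized bond
lengths) with two end-group conventions:

* `bis_glycol` (default): hydroxyethyl caps on both ends, giving exactly
  2n ester groups per n-unit chain (so 200/400/800 esters for 1/2/4
  chains of 100 units) and formula C(10n+2)H(8n+6)O(4n+2);
* `acid_glycol`: one carboxylic and one glycol end, 2n-1 esters.

A 100-unit chain weighs 19 279.1 g/mol (`bis_glycol`) or 19 235.0 g/mol
(`acid_glycol`); the nominal literature mass of 19 246 g/mol for this
chain length lies between the two conventions (the end caps of the
original construct are not stated), so both agree with it to better than
0.2% and no exact match is claimed.

Nanoparticle assembly replaces MD folding with a deterministic geometric
collapse: monomer-sized atom groups are placed, with seeded random
orientations, on a boustrophedon walk through a sphere-clipped cubic grid
(0.72 nm cells, radius grown until all monomers fit), and an iterative
push-apart then enforces a 0.15 nm minimum interatomic separation. The
cell spacing is chosen so that the resulting gyration radii (about 2.1 nm
for 2 chains, 2.6 nm for 4) sit near amorphous-PET density; the collapsed
geometry is somewhat looser than an MD-folded particle (reference values
are 1.82/2.31 nm), which inflates SASA accordingly. Geometry feeds only
the geometric observables (R_g, SASA, the rigid-body scan); all chemistry
lives in the bond graph, which assembly never touches. Bond lengths are
not preserved by the collapse — a deliberate trade, since no force-field
quality is claimed for the folded coordinates.

## Functional-group census

Group perception is connectivity-based (no bond orders) with the fixed
precedence EST > COOH > CHO > CO > OH:

* ester: carbonyl C with one terminal O and one bridging O whose other
  neighbour is carbon;
* carboxyl: same but the bridging O carries hydrogen;
* aldehyde: C with one terminal O, at least one H and exactly one carbon
  neighbour; ketone carbonyl: one terminal O, two carbon neighbours, no H;
* hydroxyl: degree-2 O bonded to one C and one H, excluding carboxyl O-H
  (the printed hydroxyl and carboxyl columns are separate, so carboxyl
  hydroxyls are not double-counted);
* R3-R6: independent rings of size 3-6 containing at least one oxygen.

Rings follow the smallest-set-of-smallest-rings convention: candidate
cycles up to size 6 are enumerated per biconnected component
(`networkx.simple_cycles` with a length bound) and added shortest-first
while linearly independent over GF(2) on edge space. Enumerating only
short cycles keeps ring perception linear-time even when long-range
cross-links create enormous cycles; among equal-length candidates,
all-carbon cycles are preferred, so benzene remains the canonical ring of
a fused system and is never counted (R-counters require an oxygen
member). SSSR ambiguity in pathologically fused systems is resolved by
this deterministic tie-break.

The census runs on the *main particle*: every connected component whose
molar mass reaches half that of the heaviest component. Pristine
multi-chain particles are held together by dispersion, not covalent
bonds, so their equal-mass chains all count; detached 2-18-carbon
fragments fall far below the threshold and are reported separately.

Surface metrics: gyration radius is the mass-weighted RMS distance from
the mass-weighted centroid; SASA is Shrake-Rupley quadrature (960
golden-spiral points per atom, Bondi radii, 0.14 nm probe, reported in
A^2); hydrogen bonds use the common geometric criterion (donor-acceptor
O-O distance <= 0.35 nm, H-donor-acceptor angle <= 30 degrees);
hydrophilicity indices divide the particle-water pair energy and H-bond
count by SASA.

## Degradation emulator

Shock-compression chemistry is emulated *statistically*: a
`DegradationSchedule` fixes the final census of the main particle, and a
seeded graph-edit engine realises it exactly. This is a deliberate design
point — the downstream acceptance surface is the census, not reaction
kinetics, so the generator plants outcomes rather than simulating
chemistry. The packaged schedules (S10...S30 for the 2-chain particle,
L10...L30 for the 4-chain one) encode the printed degradation outcomes at
10-30 GPa; the pressure label only indexes this table, and no Hugoniostat
physics (e.g. effective temperatures) is modelled.

An integer planner decomposes each schedule into edit budgets. Ester
scissions take one of five cap chemistries — hydrolysis (COOH with a
water oxygen + alcohol OH), H-capping (CHO + OH), decarbonylation (CO
released + OH), O-alkyl acid cleavage (COOH from polymer oxygens only)
and decarboxylation (CO2 released) — chosen so the group counts *and* the
water-oxygen tally close simultaneously:

    N_Ow = hydrolyses + OH attachments + 2 COOH attachments
         + CHO attachments + CO attachments + epoxides
         + water-mode rings + ether bridges.

Remaining group targets are met by attachments (hydroxyls at C-H sites
with site-class weights aliphatic/dearomatized/aromatic defaulting to
0.6/0.3/0.1; carboxyls and aldehydes via benzene-ring opening; in-ring
ketones), ring targets by closures that either recruit an existing
backbone ester oxygen (census-neutral for N_Ow; sites reserved before
attachments can consume them) or insert a water oxygen (epoxides always
do), and cross-links are census-neutral C-C bonds added as a spanning set
over the cut segments so the particle fuses into one molecule. Detached
fragments are mono-(2-hydroxyethyl)-terephthalate-like aromatic
hydroxy-acids (10 carbons, within the reported 2-18 carbon range), plus
the CO/CO2 the cap chemistries release. Because the printed group counts
are *formed* groups, the pristine chain-end hydroxyls are consumed first
(dehydroxylation); each detached fragment accounts for 3 units of the
ester drop (two boundary cuts plus one carried ester).

Every edit draws its site uniformly from the currently eligible ones with
the schedule's seeded generator, so output is bit-reproducible, and after
editing the census is re-run and compared against the planted counts
(hard failure on any mismatch). A mass ledger tracks inserted water
atoms, deleted hydrogens and detached fragments and must balance to
numerical precision. ALT — the number of atoms whose bonded-neighbour
element multiset changed — is emergent, not planted: packaged runs give
values of the same order as the reference outcomes and monotone in
pressure, but no agreement is claimed.

Infeasible schedules (group targets incompatible with the oxygen tally,
or too few eligible sites) raise before editing, with the deficit named.

## Binding-site search

The search runs on rigid bodies with an implicit solvent: Debye-screened
Coulomb (relative permittivity 78.5, Debye length 0.784 nm for a 0.15 M
1:1 electrolyte at 300 K, both derived from the standard closed form and
overridable) plus a generic per-element 12-6 Lennard-Jones table with
Lorentz-Berthelot mixing, scaled by 0.1 during the search to smooth the
energy surface. Pair distances are clamped at 0.01 nm; no cutoff by
default.

The propagator is seeded Metropolis rigid-body Monte Carlo rather than MD
integration: only the sampled configuration set matters downstream, and
MC needs no forces and is exactly reproducible. Collective variables are
the spherical angles (polar theta, azimuth phi) of the nanoparticle
centre of mass in the protein frame; a well-tempered bias (Gaussian
hills, base height 0.8 kJ/mol, deposited every 1000 accepted steps, bias
factor 20, width 0.1 rad in both angles — the width is not prescribed
anywhere and 0.1 rad resolves the toy bodies' angular features) drives
the particle across the whole surface, with a reflecting wall on the
centre-of-mass distance (7 nm default; tests on toy bodies scale the wall
to the body size). Hills are periodic in phi and unwrapped in theta; bias
behaviour within ~one hill width of the poles is therefore approximate (a
documented limitation).

Every visited pose is recorded and afterwards rescored with the unscaled
vacuum model (LJ scale 1, relative permittivity 1, no screening) —
mirroring a vacuum re-evaluation of the trajectory — and the
lowest-energy pose is selected. On toy charge-patched complexes the
selected minimum matches or beats a 10^4-point (theta, phi, distance)
brute-force grid for every tested seed, because the scan also relaxes the
orientation the grid freezes.

## Umbrella sampling and WHAM

The synthetic umbrella generator draws i.i.d. samples from the exact
biased density exp(-beta[F(x) + k/2 (x-x_i)^2]) by inverse-CDF sampling
on a fine grid, with a trapezoidal CDF (a raw cumulative sum shifts every
draw by half a grid step, which a 1000 kJ mol^-1 nm^-2 spring misreads as
a ~0.5 kJ/mol/nm tilt of the recovered profile). Defaults mirror the
production protocol: 20 windows, 0.2 nm spacing, k = 1000 kJ/mol/nm^2,
5000 samples per window, 310 K. The generating profile is a single
Gaussian well of configurable depth rising to a flat plateau.

WHAM solves the standard self-consistent equations on 0.02 nm bins,
converged when no window constant moves by more than 1e-6 kJ/mol. Two
numerical details matter at this spring stiffness: the Boltzmann factor
of the bias is averaged over each bin by midpoint quadrature (the bias
varies by more than 1 kJ/mol across a bin, and bin-centre evaluation
biases the profile by ~1-2 kJ/mol), and bins with fewer than 25 total
counts are dropped (a near-empty edge bin produces a wildly noisy free
energy that would corrupt the minimum-shift). The adsorption free energy
is minus the mean of the trailing 20% of the profile above the minimum;
the plateau is accepted when its fitted slope is below 1 kJ/mol/nm *or*
its total rise is under 10% of the profile height (the slope of a
genuinely flat tail fluctuates at the +-1 kJ/mol/nm level at these sample
sizes, while monotone profiles still fail loudly). Bootstrap errors
resample each window with replacement (200 iterations by default),
warm-starting each replica from the full-data window constants, and
report per-bin and Delta-G standard deviations; the plateau region is
located once on the full-data profile.

Recovered well depths of 10-260 kJ/mol agree with the generating truth to
max(0.5 k_BT, 2%); pointwise, the bulk (95%) of the profile tracks the
truth to 0.5 k_BT, while the max deviation over ~200 bins reaches ~1.3
kJ/mol from the window-to-window random walk inherent to 20x5000
samples — an extreme-value statistic, not a typical error.

What passing these tests shows — and does not: the generator samples the
biased densities *exactly*, so recovery validates binning, the WHAM
solver and the Delta-G reader, but says nothing about MD-specific error
sources (autocorrelation, incomplete orthogonal relaxation, pulling
hysteresis). The reference adsorption free energies themselves
(-145/-55/-272/-260 kJ/mol for the four particle systems) require
explicit-solvent MD and are not reproduced here; the tested depths
bracket that regime instead.

## Structure metrics

Close contacts are protein/particle heavy-atom pairs within a cutoff
(default 0.4 nm — the original analysis never states its cutoff, so
contact *counts* are not comparable, only their domain decomposition),
each attributed to the albumin domain of its protein residue using the
canonical ranges I = 1-195, II = 196-383, III = 384-585 (half-open at the
boundaries). RMSD uses closed-form Kabsch superposition (SVD with a
reflection guard); RMSF is the per-residue fluctuation about a reference
after per-frame superposition (optionally disabled). Pair-energy traces
re-evaluate the vacuum model over equilibrium poses and report mean +-
standard deviation per component; solvated energies are out of scope.

## Synthetic data vs real data

The toy complexes are rigid charge-patched carbon bodies with three
labelled "domains"; they exercise geometry, sampling and bookkeeping, not
protein physics. The degradation emulator reproduces group populations
but not reaction pathways, spatial clustering of functional groups, or
charge redistribution. Consequently, green tests here certify the
*algorithms* (census, search, WHAM, metrics) against exact ground truth;
they do not certify force-field realism or any MD observable.

## Problem sizes

Default test and acceptance workloads: 100-unit chains (2210 atoms), 2-
and 4-chain particles (4420/8840 atoms), 30 000-step scans on ~70-atom
toy complexes, 20-window x 5000-sample umbrella datasets with 200
bootstrap iterations. Builds take under a second per chain, a full
degradation run 1-5 s, a scan ~6 s and a full bootstrap WHAM ~40 s.
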