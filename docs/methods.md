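# Methods

## Scope and model

`hydracryst` analyses the hydration structure and hydrogen-bond geometry of
proteins in the crystalline state. The pipeline covers five stages:

1. **Crystal system construction** — expand an asymmetric unit into the unit
   cell with space-group operators, insert water to a target hydration level
   h (grams of water per gram of protein), and add counterions to zero net
   formal charge.
2. **Hydrogen-bond detection** — a purely geometric criterion (below),
   per-water bond counts decomposed by partner class, and ring perception in
   the water–water bond network.
3. **Hydration statistics** — surface-distance profiles per residue class,
   two-dimensional (r, θ) geometry maps with peak finding, hydration-level
   trend tables and protein–protein contact maps.
4. **Crystal-database comparison** — the same O-H···O geometry statistics
   computed from hydrogen-containing crystal structures filtered by
   experimental method and resolution.
5. **Synthetic data** — generators that produce every input the pipeline
   needs, including an equilibrated bulk-water reference sample.

## Hydrogen-bond criterion

A donor–hydrogen/acceptor arrangement is counted as a hydrogen bond when

* the donor heavy atom to acceptor distance is **strictly less than 3.5 Å**
  (for water pairs this is the interoxygen distance), and
* the D–H···A angle lies in **[120°, 180°]**, i.e. the deviation from
  linearity θ = 180° − ∠(D–H···A) satisfies θ ≤ 60° (the 120° boundary is
  inclusive).

Geometry is reported as (r, θ) with r the hydrogen-to-acceptor-oxygen
distance; a perfectly linear bond has θ = 0 and, for water at its preferred
O···O separation of ~2.8 Å, r ≈ 1.85 Å. Donors are O–H and N–H groups of
water and protein; acceptors are water oxygens, protein oxygens, and protein
nitrogens carrying no hydrogen. Bonds with nitrogen at either end are
flagged (`n_mediated`) so that O-H···O-only statistics can be extracted.
Hydrogens are attached to their heavy atom template-first (water H → O;
protein hydrogens via the PDB remoteness code in the atom name, e.g.
HB2 → CB, HG1 → OG1), with a nearest-heavy-atom fallback gated at 1.2 Å for
nonstandard names. Template-first assignment matters for disordered inputs:
with 0.1 Å Gaussian positional noise a pure distance rule starts dropping
covalent O–H pairs and silently loses bonds.

## Geometry maps and the scoring gate

The (r, θ) maps histogram **all** hydrogens of **all** donors whose heavy
atom lies within the 3.5 Å proximity gate of an acceptor, with no angular
condition. Binning is 0.1 Å × 5° over r ∈ [1.2, 4.0) Å, θ ∈ [0, 90)°;
geometries outside the ranges are tallied in a spill register so that raw
counts are conserved. This scoring rule was a genuinely open design choice,
and two candidates were measured on the bulk-water sample:

* *Hydrogen-based gate* (score every H···O pair up to 4.0 Å, any angle):
  the pair count grows with the cube of the gate, so the diffuse non-bonded
  population at r ≈ 3.6–4.0 Å, θ ≈ 60–85° accumulates bin heights equal to
  the bonded peak (within ±2%), and the global histogram maximum becomes a
  noise-level coin flip between the two regions across seeds.
* *Proximity gate* (score both hydrogens of every donor against acceptors
  within 3.5 Å of the donor heavy atom, any angle): the bonded peak at
  (1.85 Å, 17.5°) dominates stably, while mis-oriented hydrogens of
  proximal pairs still populate the non-bonded band at r > 3.0 Å,
  60° < θ < 90° — both features of liquid water the maps are meant to show.

The proximity gate is the default (`scoring_gate = 3.5`). Map peaks are the
centre of the maximal bin, ties broken toward smaller r then smaller θ. No
Jacobian (r² sin θ) weighting is applied: raw counts place the θ peak at
15–20°, which is the expected location for near-tetrahedral water once the
solid-angle factor is left in; dividing it out would move the maximum to
θ → 0 and is deliberately not done.

### Expected peak location

On the equilibrated bulk-water reference the maximal bin sits at
r = 1.85 ± 0.05 Å (bin [1.8, 1.9)) and θ = 17.5 ± 2.5° (bin [15, 20)),
stable across seeds. The r value matches the first intermolecular O···H
peak of three-site water models and of neutron-diffraction water
(≈1.8–1.9 Å). Literature statements that place this peak at 2.0 Å are
consistent with our measurement only at coarser binning; with 0.1 Å bins
the maximum is robustly in the 1.8–1.9 Å bin, and the package reports what
it computes.

## Surface-distance profiles

For every water oxygen the distance to the protein surface is the minimum
minimum-image distance over protein atoms, **hydrogens included**. Class
profiles (main chain / hydrophilic side chains / hydrophobic side chains /
whole surface) use the minimum over atoms of that class only, so each water
contributes once per class histogram; the whole-surface histogram is not an
envelope of the class histograms. Counts are averaged over frames and
divided by the number of protein chains ("per protein"). Defaults: 0.1 Å
bins to 6 Å; hydration-shell queries (e.g. rings near a surface class) use
4 Å. Trend tables read each class profile at the bins containing the
hydrogen-bond distance (1.8 Å) and the van der Waals contact distance
(2.5 Å).

The hydrophilic/hydrophobic split of residues is configurable; the default
hydrophobic set is {ALA, VAL, LEU, ILE, PRO, PHE, MET, TRP, GLY} (a standard
Kyte–Doolittle-style binary partition), all other standard amino acids
hydrophilic. Backbone atoms N, CA, C, O, OXT and their hydrogens are main
chain regardless of residue.

## Crystal builder

Space groups P1 and P4₁ are supported; the P4₁ operator set
{(x,y,z), (−x,−y,z+½), (−y,x,z+¼), (y,−x,z+¾)} is hard-coded in the
international-tables setting. Operators act on fractional coordinates;
each molecule (protein chains whole, solvent per residue) is wrapped into
the cell by its centroid so molecules are never split. Water insertion is
rejection sampling: uniform oxygen position, uniform random orientation,
rejected while any existing heavy atom or placed oxygen is within the clash
cutoff (default 2.4 Å — just below the water–water O···O hydrogen-bond
distance, so first-shell placement stays possible) under minimum image;
a per-molecule attempt cap (default 10 000) turns pathological packing into
a capacity error that reports how many molecules were placed. The target
water count for hydration level h is round(h·M_protein/18.015). Formal
charges use residue-level rules (ASP/GLU −1, LYS/ARG +1, HIS 0 by default
and configurable, termini +1/−1 per chain); positive systems get Cl⁻,
negative systems Na⁺, at non-clashing random positions. Neutralisation is
idempotent.

## Bulk-water Monte Carlo sampler

The bulk reference is rigid three-site water (O–H 0.9572 Å, H–O–H 104.52°,
charges −0.834/+0.417 e, Lennard-Jones on oxygen σ = 3.1507 Å,
ε = 0.1521 kcal/mol) sampled by single-molecule Metropolis Monte Carlo:
random translation (uniform, ±0.18 Å initial) plus random rigid rotation
about the oxygen (±18° initial), auto-tuned toward ~45% acceptance during
equilibration. Energy is Lennard-Jones (O–O) plus Coulomb over all nine
site pairs with a **molecule-based spherical cutoff** of 10 Å on the
minimum-image O–O distance; the partner molecule is shifted whole into the
donor's periodic image, so dipoles are never split (a molecule-based cutoff
avoids the artificial charge ordering a site-based cutoff induces). No
Ewald summation is used: the sampler exists to produce local hydrogen-bond
geometry, which is insensitive to the long-range treatment.

Defaults: 440 molecules at 1.0 g/cm³ (cubic box edge 23.6 Å, comfortably
above twice the cutoff), 300 K, 400 equilibration sweeps, 200 production
sweeps sampled every 4 (50 frames). At these settings the energy settles
near −9.4 kcal/mol per molecule, the O–O radial distribution peaks at
2.75–2.80 Å with g ≈ 2.6, and one run takes about a minute on one CPU.
Equilibration is verified by a plateau test: the mean energy of the last
two quarters of the equilibration window must agree within 1% (at 64–125
molecules the quarter-mean noise itself is 1–2%, so small-system tests use
a 2% tolerance).

## Synthetic fixtures

* **Ice-rule lattice** — oxygens on a diamond (cubic-ice-like) lattice with
  nearest O–O exactly 2.76 Å in a periodic box. Proton placement orients
  every O–O link by an Eulerian circuit of the 4-regular bond graph: each
  vertex then has out-degree exactly 2, which *is* the ice rule (two
  covalent hydrogens per oxygen, one hydrogen per link). Each molecule
  donates two and accepts two bonds, so the mean bond count is exactly 4 —
  the bulk-water limit. Seeds shuffle the traversal, giving different valid
  proton configurations; optional Gaussian jitter of the oxygen sites
  (hydrogens follow the jittered axes) models thermal/lattice disorder
  without breaking covalent geometry.
* **Ring fixtures** — regular planar water polygons (default edge 2.8 Å),
  each molecule donating one hydrogen along an edge so the bond cycle
  closes; the second hydrogen points out of plane.
* **Toy surface** — a lattice of minimal serine-like (exposed O–H) and
  leucine-like (exposed CD1) sites with buried backbone atoms, and waters
  placed at exactly 1.8 Å above hydroxyl hydrogens (accepting orientation)
  or 2.5 Å above hydrophobic carbons; 8 Å lateral spacing guarantees the
  prescribed atom is the nearest surface atom.
* **Entry sets** — synthetic PDB files plus a CSV manifest
  (entry id, method, resolution) feeding the crystal-database module.

## What the synthetic data does and does not show

The generators emulate the *geometric* features the analyses measure:
tetrahedral bonding at the bulk limit, planar ring motifs, prescribed
surface distances, and liquid-water near-order at 300 K. They do not
emulate protein flexibility, NPT cell relaxation versus hydration level,
long-range electrostatics, or real crystallographic disorder; passing tests
therefore validate the analysis machinery and the bulk-water geometry, not
the full crystal-MD observables, which require production molecular
dynamics outside this package's scope.

## Numerical choices

* Distance gate strictly `<`, angular gate inclusive `≤`, matching the
  stated criterion boundaries; a pair at exactly O···O = 3.5 Å is not
  bonded, a bond at exactly 120° is.
* Neighbour searches use periodic k-d trees and are bit-identical to
  all-pairs evaluation (tested on 20 random 64-water boxes).
* Histogram edges are half-open `[lo, hi)`; values landing exactly on an
  edge belong to the upper bin, with the usual floating-point caveat for
  distances constructed to sit on an edge.
* Altloc selection keeps the highest occupancy, ties broken by altloc
  letter; PDB serials above 99 999 wrap modulo 100 000.
* Orthorhombic (rectangular) periodic cells only, coordinates in Å
  throughout.
* Monte Carlo moves, water insertion and ion placement consume a single
  seeded NumPy generator each; every generator is bitwise reproducible
  under a fixed seed.

## Known limitations

* Only P1 and P4₁ space groups; no generic operator parsing, no mmCIF
  output, no non-orthorhombic cells.
* No energetic or orbital hydrogen-bond definitions, no bond lifetimes.
* Waters without modelled hydrogens are excluded from database geometry
  maps rather than given inferred hydrogens; entries whose space group is
  not supported fall back to direct contacts with a logged warning.
* The sampler is a structural reference, not a dynamical model: no
  diffusion, dielectric response or NPT sampling.
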