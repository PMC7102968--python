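# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `aptastruct`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structure model and I/O

Structures are parsed with gemmi (mmCIF and PDB dialects) into a small
chain → residue → atom hierarchy that preserves **author numbering**
throughout, because every residue in the analyses is cited by author number
(Arg28, nucleotide G33). Alternate locations are collapsed to the
highest-occupancy copy, ties broken by the lexicographically smallest altloc
tag — deterministic and in line with common practice. Hydrogens are retained
when present but all geometric operations default to heavy atoms, since the
crystal structures of interest (2.7–2.9 Å resolution) carry none. Waters and
non-polymer ligands are excluded from interface and geometry operations by
default (includable by flag); residue kinds come from a fixed table bundled
in `chemistry.py` (20 amino acids, A/C/G/U, DA/DC/DG/DT, everything else
`other`).

Round-trip fidelity (parse → serialize → parse preserving inventory and
coordinates to 1e-3 Å) is asserted in tests; PDB fixed-width output is the
precision bottleneck.

## Superposition protocol

`kabsch_superpose` is the standard SVD solution for the least-squares proper
rotation; degenerate (collinear/coincident) point sets are rejected by an
SVD rank check (second singular value < 1e-8 of the first). It is verified
in tests against two independent routes: scipy's quaternion-based
`Rotation.align_vectors` and a brute-force rotation search (2000–4000
uniformly sampled rotations polished by Nelder–Mead), with agreement to
1e-3 Å on noisy instances.

The comparison protocol anchors the fit on the effector-binding-domain
segment list (48–66, 73–103, 108–129, 131–137, 139–151, 166–173, 179–180,
183–202; both protomers pooled) and evaluates the DNA/RNA-reading domain
under that transform with **no refit**. The reading-head domain is defined
as residues 2–47 per protomer — everything N-terminal of the first anchor
segment, covering helices α1–α3 — and is configurable. A residue pair
enters a fit only when its Cα is modeled in both structures; pair counts
are always reported. For dimers, the chain correspondence (parallel or
swapped) that minimizes the anchor r.m.s.d. is chosen automatically, since
crystallographic chain labels are arbitrary. Marker-residue displacements
(defaults: residues 55, 12, 42) occur once per protomer and are averaged
over the two copies.

## Interface analysis

* **Contact census (3.7 Å).** A protein residue counts as a contact residue
  if any heavy atom lies within the cutoff of any nucleic heavy atom
  (inclusive boundary); a cKDTree supplies the neighbor lists and an exact
  all-pairs oracle replicates the census in tests.
* **Surface areas.** Shrake–Rupley numerical SASA with a 1.4 Å probe and
  960 sphere points by default. Points come from a golden-spiral
  construction, so results are bit-reproducible; doubling the point count
  moves areas by < 1 %. Radii are the Bondi (1964) set, versioned in
  `chemistry.py`. The buried area of a protein domain is
  SASA(free protein, domain atoms) − SASA(complex, domain atoms); domain
  definitions must not overlap. The implementation is cross-checked in
  tests against biotite's SASA (same radii, different point sets, 2 %
  agreement) and against the closed-form sphere and two-sphere-cap areas
  (0.5 % at 3840 points). Because the reference areas for the real
  complexes were produced by an unnamed program, comparisons against them
  carry a ±10 % band.
* **Hydrogen bonds.** Heavy-atom criteria for hydrogen-free models:
  donor–acceptor distance ≤ 3.5 Å and antecedent–donor–acceptor angle
  ≥ 90° whenever the donor's antecedent atom is modeled. Donor/acceptor
  classes come from fixed per-residue tables (backbone N/O plus standard
  side-chain and base/sugar/phosphate atoms). These gates are deliberately
  permissive; every reported bond carries its raw distance and angle so
  users can re-gate without recomputation. Bonds are groupable per residue
  pair to surface bidentate interactions.
* **Ring interactions.** π–π stacking: any ring–ring pair (Phe/Tyr/Trp/His
  rings, purine five- and six-membered rings, pyrimidine ring) with
  centroid distance ≤ 4.5 Å and interplanar angle ≤ 30°. Cation–π: Arg
  guanidinium or Lys ammonium centroid within 6.0 Å of a ring centroid and
  within 45° of the ring normal. Literature-typical values; configurable;
  geometry always reported.

## Nucleic-acid geometry

Torsions use the standard quadruples — α: O3′(i−1)–P–O5′–C5′, β through ζ
along the backbone, χ: O4′–C1′–N9–C4 (purines) / O4′–C1′–N1–C2
(pyrimidines) — and are undefined (never zero) when an atom, including one
from an unmodeled neighbor at author number ± 1, is missing. syn is
χ ∈ [−90°, +90°], the standard convention.

Base pairs are detected as nucleotide pairs with ≥ 2 inter-base hydrogen
bonds (heavy-atom criteria restricted to edge atoms) and base interplanar
angle ≤ 45°; each nucleotide joins at most one pair (candidates ranked by
bond count, then mean bond distance). Edge classification uses a fixed
atom→edge table per base; atoms on an edge boundary (e.g. guanine O6:
Watson–Crick and Hoogsteen) contribute fractional weight 1/k to each of
their k edges, and the pair's edge on each side is the weighted majority,
ties resolved toward Watson–Crick. This weighting is what lets, e.g., a
G:G sugar/sugar pair bonded through N2 and N3 classify correctly even
though N2 also belongs to the Watson–Crick edge. Orientation is cis when
the N(glyc)–C1′–C1′–N(glyc) pseudo-torsion lies within ±90°, trans
otherwise — a self-contained formula rather than a reference-frame
library. `canonical` requires Watson–Crick/Watson–Crick, cis, and A:U or
G:C; G:U is flagged as wobble.

Stacking runs are maximal sequences of author-consecutive nucleotides whose
bases pass the stacking gate; a nucleotide is flipped out when both
sequential neighbors are modeled yet it stacks with neither. Helix form is
called from successive base-pair frames (origin: C1′–C1′ midpoint; x:
C1′→C1′; normal: mean base-plane normal): A for mean rise 2.3–3.1 Å and
twist 30–34°, B for 3.1–3.6 Å and 34–38°, else irregular — windows taken
from canonical fiber values, since only categorical calls are needed.

## Dyad pseudo-symmetry

The dimer two-fold axis comes from the axis–angle decomposition of the
protomer-onto-protomer Kabsch rotation; chains whose relating rotation is
under 90° are rejected as "not an approximate dyad". The screw component
(translation along the axis) is reported, not silently absorbed — real
dimers are never exactly C2. A point on the axis solves (I − R)p = t⊥ by
least squares. The nucleic phosphorus atoms are then rotated exactly 180°
about the axis (Rodrigues at θ = π, an involution) and matched to the
nearest original phosphorus with mutual-nearest filtering; the
correspondence table and the r.m.s.d. over mutual pairs quantify how far
the nucleic fold is from respecting the protein dyad. Phosphorus atoms are
used because they are the conventional per-nucleotide fiducials; the
mapping rule is nearest-neighbor because no authoritative rule exists for
this construction.

## Binding thermodynamics

Units: K_d molar, ΔH kJ·mol⁻¹, ΔS J·mol⁻¹·K⁻¹. All concentrations are per
protein **dimer**, the binding unit (n = 1 means one dimer per nucleic
molecule); the CLI accepts per-monomer values with a ×0.5 flag. The
evaluation temperature defaults to **298 K** (not 298.15): 298·ΔS
reproduces every tabulated −TΔS cell at 0.1 kJ·mol⁻¹ precision, 298.15
does not. ΔG = ΔH − TΔS and ΔG = RT·ln K_d (R = 8.314 J·mol⁻¹·K⁻¹) are
both computed and their residual is *reported*: for the operator-DNA row
the two routes disagree by ≈ 0.9 kJ·mol⁻¹ purely from the printed
precision of K_d, and hiding that would be worse than surfacing it.
Fold changes are presented at two significant figures; the underlying
arithmetic value is always carried alongside (26.2/5.6 = 4.7, which the
literature variously rounds to 4.5 or 5).

The ITC model is the exact single-site mass balance: with total
macromolecule M and titrant L in the cell after the instantaneous-overflow
dilution of injection k (each component scaled by 1 − dV/V₀, titrant
incremented by c_syr·dV/V₀), the bound concentration is the root of the
1:1 quadratic with effective site concentration n·M, and the differential
heat is V₀·ΔH·([PL]ₖ − [PL]ₖ₋₁·(1 − dV/V₀)). The default protocol mirrors
the published experiment: 1 ml cell at 15 µM, 175 µM syringe, 35
injections of 5 µl with a discarded 2 µl first injection, 298 K. Fitting
runs trust-region least squares over (ln K_d, ΔH, n) with the first
injection excluded; ΔS is derived from the fitted K_d and ΔH. The
noiseless simulate→fit round trip recovers all three parameters to 0.1 %;
at 2 % peak-heat Gaussian noise the median fitted K_d over 100 seeded
replicates stays within 15 % of truth. The fraction-bound isotherm
f = [P]/(K_d + [P]) assumes protein excess over labeled nucleic acid and
requires the data to sample the transition.

## Synthetic generators

The generators emulate the *geometric situations* of the study, not its
molecules:

* **Helices.** Base-pair geometries are solved once per pair type: base i
  is fixed with its glycosidic bond at 55° to a 10.4 Å C1′–C1′ axis; base
  j's in-plane placement (rotation + translation, both flips) is optimized
  so the requested hydrogen bonds reach 2.9 Å without base-moiety clashes,
  starting from the exact two-circle intersections that satisfy the bond
  distances. The solved pair is re-normalized so the C1′–C1′ axis is
  exactly the frame x-axis, then frames are stacked with the prescribed
  rise and twist (A: 2.81 Å / 32.7°; B: 3.38 Å / 36.0°, canonical fiber
  values). Residue templates come from the Chemical Component Dictionary
  via biotite at run time, re-conformed to a standard anti glycosidic
  torsion (χ = −158°).
* **Toy C2 complex.** Two copies of a three-helix poly-alanine mini-domain
  (rigid ALA templates set on an ideal Cα spiral; carbonyl O placed by sp²
  peptide geometry) exactly related by a 180° rotation about z, plus a
  nucleic component placed symmetrically (a strand and its exact dyad
  image — consistent with a palindrome, whose reverse complement is
  itself), offset perpendicular to the dyad, or as a single bent strand
  kept strictly on one side of the axis (monomeric, aptamer-like).
  Placements were chosen once so the components touch (contacts at 3.7 Å,
  minimum separation ≥ 2.6 Å) without clashing; a < 1.5 Å protein–nucleic
  distance raises an error.
* **Noise.** Isotropic per-atom Gaussian displacement under
  `numpy.random.default_rng(seed)`; σ = 0 is bit-identical.

What the generators do **not** emulate: connected sugar–phosphate backbones
between residues (each nucleotide is rigidly placed, so inter-residue
backbone torsions of *built* helices are smooth but not canonical),
side-chain chemistry beyond alanine in the toy protein, sugar pucker,
crystallographic disorder, and solvent. Passing tests therefore demonstrate
the correctness of the *operators* (census, superposition, classification,
symmetry, fitting) on controlled geometry — not that real crystal
structures would yield any particular value. The checks against the
deposited complexes live in `tests/test_acceptance.py` and run whenever the
coordinate files are available locally or fetchable.

## Numerical choices and degenerate inputs

* Cutoff boundaries are inclusive (a 3.70 Å pair counts at a 3.7 Å cutoff).
* Kabsch rejects < 3 points and collinear sets; anchored comparisons reject
  < 3 anchor pairs and empty probes, and report both pair counts.
* Torsions at chain termini or across gaps are `None`, never 0; the
  glycosidic class of such nucleotides is `unclassified`.
* The base-pair candidate search prunes at 12 Å base-centroid distance and
  excludes same-chain neighbors closer than 2 in author numbering.
* SASA with unknown elements fails loudly, naming the element.
* All report randomness is seeded; `analyze_complex` output is
  byte-reproducible for a fixed config, and every threshold used is echoed
  into the report together with the package version.

## Problem sizes

Test and acceptance runs use 4–14-residue helices, a ~620-atom toy complex,
960–3840 SASA points, 20 superposition-oracle instances, 50 census-oracle
instances and 100 ITC noise replicates — sizes chosen to exercise every
code path with comfortably converged statistics.
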