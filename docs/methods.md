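# Methods

## Overview

`mepclust` compares peptide–MHC class I complexes by the shape of their
molecular electrostatic potential (MEP) over the peptide-binding cleft and
groups them by hierarchical clustering with multiscale-bootstrap support.
The pipeline is: sanitise PDB input → assign charges/radii → rigid
superposition onto a common reference → MEP on one shared lattice →
skin ∩ cylinder focus masks → pairwise Hodgkin indices → correlation-distance
complete-linkage clustering with AU/BP p-values → significance flagging.

## Input handling and charge model

Coordinate records are accepted in fixed-column PDB v3.3 or in a stripped
whitespace-delimited nine-field dialect (record type, serial, atom name,
residue name, chain, residue number, x, y, z); the sanitiser emits the
latter, because modelled pMHC files frequently carry occupancy/B-factor/
element columns in non-standard layouts. Alternate locations other than
' '/'A' are dropped; hydrogens are used if present but never added.

Charges and radii are assigned from a lookup table keyed by
(residue, atom name). The shipped default is a *formal* charge model:
carboxylates −1 (split over the two oxygens), LYS/ARG +1, HIS neutral,
zwitterionic termini (+1 on the first backbone N, −1 on OXT/O of the last
residue, applied only to chains that actually have those atoms); radii come
from a per-element table (C 1.7, N 1.55, O 1.52, S 1.8, H 1.2 Å). A full
force-field charge set can be merged in as a TSV. The coarse default is
deliberate: the comparison statistic is evaluated on a solvent shell at
least one probe radius away from the surface and up to 25 Å out, where the
field is dominated by the placement of net charges rather than by
sub-elementary partial-charge detail. The protonation states the table
encodes are fixed (pH-7-like); no titration prediction is attempted.

## Superposition

Each complex is fitted to a reference structure by the least-squares optimal
rigid transform (Kabsch), pairing atoms by shared
(chain, residue number, atom name) keys — Cα-only by default so side-chain
differences between peptides do not enter the fit. The fit is applied twice
in sequence and both RMSDs are reported; for an exact least-squares optimum
the second pass is a fixed point, and the invariant `rmsd_pass2 ≤
rmsd_pass1 + 1e-9` is enforced by test. Degenerate pairings (fewer than
three pairs, or collinear pairs, for which the rotation about the line is
unidentifiable) are errors.

The built-in reference is a canonical synthetic frame (cleft plane =
xy-plane, peptide axis = x, cleft centroid at the origin) generated
deterministically in code; any user PDB can serve as reference instead.
Generating the reference rather than shipping a static file keeps it
byte-reproducible and avoids a redundant data artefact.

## Electrostatics

The MEP is a screened-Coulomb (Debye–Hückel) sum in a uniform dielectric:

    φ(r) = (C/ε) Σᵢ qᵢ exp(−κ dᵢ)/dᵢ,   dᵢ = max(|r − rᵢ|, 0.5 Å)

with C = 332.0637 kcal·mol⁻¹·Å·e⁻², ε = 78.4, and κ the inverse Debye
length from ionic strength 0.05 mol/L at 298.15 K (κ = 0 recovers plain
Coulomb; at the defaults the Debye length is ≈ 13.6 Å). The 0.5 Å
singularity floor only clamps evaluation points essentially on top of an
atom; skin masking removes those points from every comparison anyway.

This is an explicit simplification relative to a finite-difference
linearised Poisson–Boltzmann solution: there is no low-dielectric molecular
interior and no dielectric boundary. The choice is defensible for this
statistic — the Hodgkin index is scale-invariant and is computed on a shell
outside the molecular surface where charge geometry dominates — and the
`PotentialGrid` contract lets a PB solver be slotted in without touching
the rest of the pipeline. It does mean absolute potential values should not
be interpreted quantitatively near the surface.

All complexes share one axis-aligned lattice sized to the focus cylinder
plus 5 Å padding. Default spacing is 1.0 Å (matching the probe scale);
coarser spacings trade resolution for speed and the tests/benchmark use
2.0 Å. Grids and masks can be exported as OpenDX scalar fields.

An analytic monopole+dipole prescreen (Hodgkin index of the truncated
multipole fields on a deterministic spherical shell) is computed and
reported, but is advisory only: final clustering always uses the grid-based
indices.

## Focus region

The skin of a complex is the set of lattice points strictly outside its
solvent-accessible surface (atom radius + probe radius σ, default 1 Å) but
within a thickness δ (default 25 Å) of it:
0 < minᵢ(|g − rᵢ| − (Rᵢ + σ)) ≤ δ. Boundary conventions are fixed (open at
the SAS, closed at the outer bound and on the cylinder surface) so point
counts are exactly reproducible.

The cylinder (default radius 40 Å, length 33 Å) is placed once, on the
reference: center = centroid of the peptide-chain atoms, axis = unit normal
of the least-squares plane through the peptide Cα atoms. The axis is the
*cleft-top normal*, not the groove direction — which is why the radius may
exceed the length: the flat faces of the cylinder parallel the cleft plane
and the radius spans the cleft in-plane. The peptide chain is auto-detected
as the shortest chain of 8–11 residues. Both center and axis can be pinned
in the configuration, and the placement actually used is always recorded in
the run report. Each pair of complexes is compared on the intersection of
both skins with the cylinder; an empty pairwise mask is an error naming the
pair.

## Similarity

For potentials φ_a, φ_b at the masked points,

    SI = 2 Σ φ_a φ_b / (Σ φ_a² + Σ φ_b²),   D = sqrt(2 − 2 SI).

SI ∈ [−1, 1] (clamped at tolerance 1e−9), D ∈ [0, 2]. Diagonal entries are
set to 1/0 by definition. Because masks are pair-specific, the SI matrix
need not be positive semi-definite; it is symmetric by construction.

## Clustering and cluster support

The clustering input is the column profile of the SI matrix (one column per
complex; configurable to D). Distances between profiles are 1 − Pearson
correlation, and the tree is built by complete linkage with a deterministic
tie rule (among equal-distance merges, the lexicographically smallest merged
leaf-label set wins).

Cluster support follows the multiscale bootstrap: for scale factors
r ∈ {0.5, 0.6, …, 1.4} the rows of the input matrix are resampled with
replacement to size round(r·n), the tree is rebuilt, and BP_r of a reference
node is the fraction of replicates containing its exact leaf set. The AU
p-value fits ψ(r) = Φ⁻¹(1 − BP_r) = v√r + c/√r by weighted least squares
(weights nboot·φ_pdf(ψ_r)²/(BP_r(1 − BP_r))) and sets AU = 1 − Φ(v − c);
BP at r = 1 is the ordinary bootstrap probability. Degenerate handling:
scales with BP_r ∈ {0, 1} are excluded from the fit; a node with BP_r = 1
(resp. 0) at every scale has AU = 1 (resp. 0); a non-degenerate node with
fewer than two usable scales gets AU = NaN with a warning. In a bootstrap
replicate, a column rendered constant by the resample is given correlation
0 with all others rather than failing the replicate.

Randomness is fully keyed: each (scale, replicate) pair draws from its own
stream derived from the master seed, so results are bit-reproducible and
increasing nboot leaves earlier replicates unchanged.

Nodes with AU strictly greater than the threshold (default 0.95), excluding
the root, are flagged. The reported partition assigns each leaf to the
*maximal* flagged cluster containing it — the same convention as picking
the largest supported clusters in pvclust's `pvpick` — with unflagged
leaves as singletons. (Stable sub-clusters inside a strong group routinely
reach high AU too; reporting maximal clusters is what makes the partition
meaningful.)

At least three complexes are required end to end: with two, the similarity
matrix and its correlation-distance profiles are degenerate and no
clustering question exists.

## Synthetic benchmark

The fixtures module emulates exactly the features the pipeline consumes:
a neutral scaffold slab of pseudo-atoms (identical across all fixtures, so
every similarity difference is attributable to the peptide), and a
nine-position pseudo-peptide at 3.8 Å Cα spacing in the cleft plane with a
small fixed y zig-zag (so the least-squares peptide plane is well defined).
Group structure is planted as mutually orthogonal ±1 sign patterns (Hadamard
rows, zero-padded to nine positions, scaled by the separation in e);
within-group members differ only by Gaussian coordinate jitter of the
peptide atoms. Pseudo-residues use registered fixture residue types in the
charge model, decoupling fixture truth from the biological table.

Benchmark study conditions: 3 groups × 3 complexes, separation 1 e, jitter
0.2 Å, nboot 1000, grid spacing 2.0 Å, cylinder 12 Å radius × 14 Å length
(sized to the toy cleft, whose peptide spans ≈ 30 Å in x and whose scaffold
sits 4 Å below the cleft plane). Under these conditions the planted
partition is recovered with adjusted Rand index 1.0 and every planted-group
node exceeds AU 0.95; this is asserted by the acceptance tests and
recomputed by `scripts/acceptance.py`.

What passing this benchmark does *not* show: the fixtures have no realistic
pMHC geometry, no side chains, no dielectric heterogeneity, and their group
separation is by construction cleaner than real epitope families. The
benchmark validates the machinery (masking, similarity, bootstrap,
flagging), not biological discrimination power on real complexes.

## Numerical choices

- SI clamp tolerance 1e−9; symmetric-matrix check tolerance 1e−9.
- Collinearity threshold for fits and peptide planes: second singular value
  ≤ 1e−8 × the largest.
- Cylinder radial boundary includes a 1e−9 Å² slack so points exactly on
  the surface are included regardless of rounding.
- Complete-linkage input is symmetrised ((D + Dᵀ)/2) before the exact-
  equality tie scan, because `numpy.corrcoef` is symmetric only to 1 ulp.
- TSV floats are written with `%.12g`, making identically-seeded runs
  byte-identical.
- Complexity: one grid evaluation is O(lattice points × atoms); the
  similarity stage is O(pairs × lattice points); the bootstrap is
  O(scales × nboot × n³) for n complexes.

## Known limitations

- Screened Coulomb instead of Poisson–Boltzmann (see above).
- Formal charges only by default; no protonation-state prediction.
- Atom pairing for superposition requires shared residue numbering with the
  reference; no sequence alignment is attempted.
- One global cylinder per run; no per-complex adaptive focus region.
- The analytic prescreen is reported but never feeds clustering.
- Alternative similarity indices (e.g. Carbó) and linkage methods are
  extension points, not implemented.
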