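# Methods

This note records the models implemented in `aakdyn`, the parameters that
matter, the numerical conventions, and what the synthetic test systems do
and do not demonstrate.

## Coarse-grained representation

A structure is reduced to an ordered list of network nodes: one node per
standard amino-acid residue, represented by its Cα and carrying all heavy
(non-hydrogen) atoms of the residue, plus — when requested — one node per
non-water hetero residue (a bound ligand), represented by its heavy-atom
centroid. Node order is chain order, then author residue number, then
insertion code, and is deterministic for a given input. Waters are always
removed; alternate locations are resolved to the highest-occupancy
conformer with ties going to the first occurrence in the file; hydrogens
are ignored throughout. Internal indices are 0-based; author numbering
survives only in node labels. Structures with unresolved residues are
analysed as deposited: the node set actually used is recorded in the run
manifest.

## Elastic network models

**GNM.** Contacts are decided on the representative (Cα) coordinates with
a closed interval, d ≤ R_c; pairs at exactly the cutoff are in contact.
The Kirchhoff matrix has off-diagonal −γ for contacts and a diagonal fixed
by zero row sums. The full spectrum is computed by dense symmetric
eigendecomposition; a mode counts as zero when λ ≤ 10⁻¹⁰ λ_max. A
connected network must yield exactly one zero mode (the uniform vector);
anything else raises an error listing the graph components rather than
silently misindexing modes. Mode numbering excludes zero modes everywhere:
"mode 1" is the slowest internal mode.

**ANM.** The off-diagonal 3×3 block of a contacting pair is
−γ ê_ij ê_ijᵀ with ê_ij the unit separation vector; diagonal super-blocks
enforce zero block-row sums. A non-degenerate three-dimensional structure
yields exactly six zero modes (three translations, three infinitesimal
rotations); any other null-space dimension triggers a warning, since
collinear or disconnected geometries silently shift mode indices
otherwise.

**Parameters.** γ and the thermal prefactor 3k_BT/γ are set to 1: all
fluctuation amplitudes are relative, and comparison with experiment is
done after uniformly rescaling predicted B-factors
(B = 8π²/3 × MSF) to match the experimental mean. Cutoffs default to
R_c = 10 Å (GNM) and 15 Å (ANM), the community-standard choices for
Cα-level networks; both are configurable, and quantities derived from slow
modes typically shift by a few percent across reasonable cutoffs.

**Hinges.** A hinge is reported where a signed slow-mode shape changes
sign between sequence neighbours of the same chain (the neighbour with the
smaller amplitude is reported; ties go to the lower index), supplemented
by local minima of the squared shape lying strictly below the 10% mobility
quantile. A constant-sign mode has no opposing motions and reports no
hinges.

**GNM↔ANM correspondence.** Because the two models differ in dimension and
potential, modes are paired by Pearson correlation between per-node
squared shapes (the ANM shape summed over x, y, z), not by index.

## Deformations and overlaps

The deformation vector between two conformations is formed on mapped nodes
only, after least-squares rigid superposition (proper rotation, det = +1)
of the second structure onto the first; at the optimum the residual is
orthogonal to the translational and rotational degrees of freedom, so
overlaps against internal modes are well defined. When the mapping is
partial, mode vectors are sliced to the mapped nodes and renormalised;
the sliced basis is then no longer orthonormal, so the cumulative overlap
is guaranteed to be monotone but only reaches exactly 1 for a full
mapping. CO is reported as the square root of the summed squared cosines.

Conformers along mode k follow R± = R⁰ ± s_k λ_k^{−1/2} **u**_k; the
default amplitude is chosen so each conformer lies 1 Å Cα-RMSD from the
reference. When an all-atom source is supplied, every atom of a residue is
displaced rigidly by that residue's Cα mode component; no energy
minimisation is applied. The synthetic "closed-form" generator
(`deform_toy`) instead takes its amplitude directly as the Cα RMSD of the
displacement: for very soft, nearly mechanism-like modes the λ^{−1/2}
convention would produce displacements of thousands of ångströms, far
outside the harmonic regime in which mode recovery is meaningful.

## Communication model

Affinities a_ij = N_ij/√(N_i N_j) count heavy-atom pairs within 4 Å (one
atom from each residue); sequence neighbours get no special treatment and
ligand nodes participate exactly like residues. Hitting times are
evaluated in closed form from the degrees and the pseudoinverse of the
weighted Laplacian,

    H(j|i) = Σ_k d_k ( [Γ̃⁺]_ki − [Γ̃⁺]_ji − [Γ̃⁺]_kj + [Γ̃⁺]_jj ),

and split into a self part (the [Γ̃⁺]_jj-bearing terms, dominated by the
target's own mean-square fluctuation) and a cross part (the
cross-correlation terms) whose between-state difference maps localise
communication changes. Two independent verification routes guard this
formula in the tests: a first-step-analysis linear solver and seeded
Monte-Carlo random walks.

The per-node mean hitting-time profile defaults to the *receiver*
convention — the average over source nodes of the time to reach the
profiled node, whose minima are the most efficient receivers — with the
broadcast convention (average over targets from the node) available
behind a flag; reports name the convention. Note the two conventions give
genuinely different profiles (on the three-site path graph: receiver
(7/3, 2/3, 7/3) versus broadcast (5/3, 2, 5/3)).

Optimal pathways are Dijkstra shortest paths on the directed graph with
step cost −log m_ij for the hop j→i; ties are broken by fewer hops, then
lexicographic node order, making reported paths deterministic. Group
statistics (e.g. N-domain ↔ C-domain communication) are the mean and
standard deviation of hitting times over all ordered pairs between two
disjoint groups, in both directions.

## Subsystem analysis

The effective Hessian of a subsystem S coupled to environment E is the
Schur complement H̃ = H_SS − H_SE H_EE⁺ H_ES, with H_EE pseudo-inverted at
the same relative zero threshold as the mode decomposition so that
rigid-body modes of an isolated environment do not blow up the
complement. Two exact properties anchor the implementation: with zero
coupling H̃ equals H_SS bitwise, and for positive-definite matrices
inv(H̃) equals the SS block of the full inverse.

One consequence deserves emphasis: rigid motions of S always remain zero
modes of H̃, because the environment can relax along them (a restriction
of a global rigid motion is a rigid motion of S). Slow modes of a
two-lobe structure move each lobe essentially rigidly, so the restriction
of such a mode to one lobe lies almost entirely in H̃'s null space and
correlates with *no* internal effective mode. The meaningful
correspondences — asserted in the tests — are that each slow internal
effective mode matches its best full-system counterpart restricted to the
subsystem, and, at weak coupling, the modes of the isolated subsystem.

Cross-structure mode comparison requires a prior rigid superposition of
one structure onto the other over the mapped Cα pairs (directions are
meaningless otherwise); structural alignments are consumed as two-column
index maps, not computed. The family-conservation summary is
⟨CO(m)⟩ × 100 for m = 10: for each of the reference's first ten modes the
cumulative overlap onto the partner's first ten (capped at 1), averaged.
The reference structure is the first argument by convention; the summary
is not exactly symmetric under swapping, but is so within a few points on
well-aligned pairs.

## Synthetic test systems

The generators produce Cα models with fabricated B-factors (a smooth
radial trend) and a deterministic tetrahedron of four pseudo heavy atoms
within 1.5 Å of each Cα, so that atom-contact code paths run without real
side chains. All randomness is seeded isotropic Gaussian noise; every
generator is bit-for-bit reproducible from (spec, seed).

The dumbbell — two compact lobes bridged by a five-node linker — is the
workhorse: its bridge is a designed hinge and its slowest modes are
inter-lobe. Two geometric details are deliberate. The linker follows a
gentle off-axis arc because an exactly straight linker leaves true
zero-energy mechanisms (rotating a lobe about the linker axis changes no
pair distance), which would corrupt the six-mode rigid null space. The
lobes are mildly anisotropic (scaled 1.25/0.8 in y/z) to split the
otherwise degenerate bend-in-y/bend-in-z slow-mode pairs, keeping mode
numbering stable. The two-chain dimer is a pair of C2-related helices used
for symmetric mode profiles and the 3N−6 mode-count check at N = 516
(2 × 258 residues).

What passing on these systems shows — and does not. The toys exercise the
full algebra (spectra, overlaps, hitting times, Schur complements) against
independently solvable cases, and they emulate the *structure* of real
input (multi-chain Cα models with heavy atoms and B-factors). They do not
reproduce the contact heterogeneity, packing density or side-chain
chemistry of real proteins, so quantitative results on real structures —
B-factor correlations, specific overlap values, pathway routes — must be
established on real coordinates; the toy results certify the machinery,
not the biology.

## Numerical choices and limitations

- Dense symmetric eigensolvers throughout; systems up to a few thousand
  residues are practical on one CPU (a 516-residue dimer decomposes in
  seconds). No sparse/Lanczos path is provided.
- Zero-mode threshold is relative (λ ≤ 10⁻¹⁰ λ_max) everywhere, including
  environment pseudo-inversion.
- Deformations with norm below 10⁻¹⁰ Å are rejected as "no conformational
  change": below superposition round-off the direction is noise.
- Contact detection uses exact closed-interval distances (KD-tree for
  atom pairs); ties at the cutoff are contacts.
- The Monte-Carlo walk oracle caps total steps at 10⁷ and reports mean ±
  standard error; it is a verification device, never the analysis path.
- Alternate-location handling keeps one conformer per atom name; mixed
  partial occupancies within a residue are not modelled.
- mmCIF input, symmetry-generated assemblies, structural alignment
  computation and post-displacement energy minimisation are out of scope.
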