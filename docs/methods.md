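# Methods

## The model

A molecule is a labelled point cloud in R^3 (coordinates in Å). A growing
scale parameter turns it into a filtration of simplicial complexes: either a
Vietoris–Rips filtration, where a set of p+1 atoms spans a p-simplex once all
pairwise distances fall below the scale (a simplex's filtration value is its
diameter, so an edge appears exactly at its length), or an Alpha filtration,
the subcomplex of the Delaunay triangulation filtered by simplex circumradius.

On each sublevel complex the **discrete Dirac matrix** D_p is the symmetric
block-tridiagonal matrix

    D_p = [[ 0,   B_1,  0, ... ],
           [ B_1ᵀ, 0,  B_2, ... ],
           [ 0,  B_2ᵀ,  0,  ... ],
           [ ...          B_{p+1}],
           [ ...  B_{p+1}ᵀ,  0  ]]

built from the signed boundary matrices B_k (column = alternating (-1)^i
face signs of a k-simplex; increasing vertex labels fix the orientation).
Its side is n_0 + ... + n_{p+1}. Squaring it gives a block-diagonal matrix of
Hodge Laplacians L_0, ..., L_p and the lower Laplacian L_{p+1}^down, so D_p
acts as a square root of the whole Laplacian tower and one eigendecomposition
recovers every homological dimension at once. The diagonal sign matrix Q_p
((-1)^k on the dimension-k block) anticommutes with D_p, which forces the
nonzero spectrum into ±λ pairs; the kernel dimension obeys

    dim ker D_p = rank B_{p+2}ᵀ + Σ_{k=0}^{p+1} β_k,

an identity the test suite asserts as an exact integer equality on every
generated complex.

## Weighted Dirac

A weighted complex assigns each simplex a positive weight w_σ. The diagonal
metric G_p accumulates weights downward: G_d = w at the top dimension, and
below, G_p(σ) = w_σ + Σ G_{p+1}(cofaces of σ). The weighted Dirac matrix
carries a_k B_kᵀ in the lower blocks and a_k G_{k-1}^{-1} B_k G_k in the
upper blocks, with a_k = (k+1)^{-1/2}. This matrix is self-adjoint in the
G-inner product — conjugating by the block square-root metric G^{1/2} gives a
symmetric matrix with the same spectrum, which is how eigenvalues are always
computed — and under the coface metric its spectrum lies in [-1, 1]
(property-tested over random weights). With identity metrics and a_k = 1 it
reduces bit-for-bit to the discrete matrix. Shrinking one simplex's weight
inflates the magnitude of the harmonic eigenvector on that simplex; the test
suite checks this inversion is strictly monotone on a weighted 4-cycle.

For molecules, the physicochemical weighting uses |partial charge| on atoms,
Euclidean length (Å) on edges, and Heron area (Å²) on triangles, with a floor
of 1e-6 so degenerate (collinear) triangles and zero charges keep the metric
positive. Higher simplices weigh 1. Charges are consumed from the input (SDF
charge block or a sidecar CSV); no charge-assignment model is bundled.

## Persistent operators

For a nested pair K_a ⊆ K_b, the persistent p-chains C_p^{a,b} are the
chains of K_b whose boundary lands in K_a. The basis of this subspace is the
SVD null space (rank tolerance 1e-10 relative to the largest singular value)
of the rows of B_p^b lying outside K_a; the persistent boundary operator is
B_p^b composed with that basis, restricted to the K_a rows. Its nonzero
singular values are basis-independent (tested against random orthonormal
re-parametrisations).

The persistent Dirac nullity is computed blockwise from persistent
Laplacians. For k ≤ p the up term is the persistent operator product
B_{k+1}^{a,b}(B_{k+1}^{a,b})ᵀ on C_k^a, and the down term is the snapshot
operator of K_a itself — the boundary of a K_a-chain always stays in K_a, so
the restriction adds nothing; with this bookkeeping each kernel dimension is
exactly the k-th persistent Betti number, which the suite verifies against an
independent Z/2 column-reduction barcode on 30 random filtrations. The final
contribution is the kernel of the persistent lower Laplacian on C_{p+1}^{a,b}.
A rectangular persistent Dirac matrix is only meaningful when all block
domains agree (in particular at a = b, where everything reduces to the
snapshot operator); the block-kernel characterisation is used otherwise.
Featurization consumes snapshot (a = b) spectra.

## Attributes and featurization

Each snapshot spectrum is condensed into twelve attributes over the positive
eigenvalues (the negative half mirrors them): Fiedler value, maximum, mean,
population standard deviation, graph energy ζ(-1), signless Euler–Poincaré
number ℓ = (side - nullity)/2, generalised mean energy, second moment ζ(-2),
ζ(2) = 2Σλ^{-2}, quasi-Wiener index (n+1)ζ(1), spanning-tree number
t = ½ log c_1 - log(ℓ+1), and the zero-eigenvalue multiplicity. Logs are
natural; c_1 (the product of all nonzero eigenvalues) is taken in magnitude
as Π λ_j² over the positive half and kept in the log domain; n in the mean,
the generalised energy and the quasi-Wiener prefactor is the positive count
(= ℓ). An all-zero matrix — every snapshot before the first edge — maps to
zeros for the eleven statistics and the matrix side for the multiplicity, so
early-filtration features stay finite.

Feature vectors concatenate attribute blocks in the fixed order atom subset →
grid value → Dirac index → attribute. The two bundled configurations mirror
the studies the operator family was designed for: the perovskite-trajectory
configuration (Alpha complex, grid 1.0–6.5 Å step 0.25, D_0 and D_1: 23 × 2
× 12 = 552 features, 1104 with the hydrogen/no-hydrogen split) and the
solvation configuration (subsets all-atoms / no-H / no-H-no-C, Alpha for the
first and Rips for the others, 120 grid values 0.1–12.0 Å, D_0 and D_1:
8640 features). The 120-value grid starts at 0.1 Å — a 0 Å snapshot is
vertex-only and adds nothing beyond the atom count.

## Numerical choices

- Zero-eigenvalue threshold: 1e-8 relative to the spectral radius (at least
  1e-8 absolute), so integer nullities survive the a_k and metric scalings.
- Eigenproblems are solved densely (`eigvalsh`); every matrix in scope is
  below side ~3000, where this is both fastest and the only way to count
  kernel multiplicities reliably. Rank computations (Betti numbers, the
  nullity identity) use SVD-based `matrix_rank` on the integer boundary
  matrices and serve as an exact cross-check on the spectral nullity.
- Alpha values are circumradii in Å (square roots of the squared-radius
  convention used by common backends). Degenerate clouds are projected onto
  their affine hull before triangulating (a lone pair of atoms gets its edge
  at half the distance); residual qhull degeneracies fall back to a seeded
  1e-9 Å jitter.
- Snapshots are recomputed per grid value rather than updated incrementally:
  complexes in scope are small, and correctness is easier to audit.

## What the synthetic fixtures do and do not show

`generate_fixture` produces point clouds that reproduce the structural
*regimes* of real inputs — isolated atoms (zero matrices, full kernel), unit
n-gons (one persistent loop), a 16-point cloud with bonded-neighbour spacing
of ~1.2–1.5 Å whose Rips filtration reaches the complete complex on 16
vertices (where every quantity is pure combinatorics), uniform clouds, and a
small charged toy molecule. They exercise every code path and all the
worked-example numbers, but they are not conformers: element-specific bond
geometry, realistic charge distributions, and trajectory-scale redundancy are
absent, so passing tests demonstrate correctness of the operators and
plumbing, not predictive performance on chemistry datasets. Clustering and
regression on real trajectory/solvation data remain thin example scripts
around external learners and are deliberately untested.

## Known limitations

- The complex-parameter Dirac family D_p(z) is implemented only at z = 1.
- The |λ| ≤ 1 bound for the weighted Dirac is tested only under the coface
  metric with a_k = (k+1)^{-1/2}; general weightings carry no such guarantee.
- Rips clique expansion is exponential in principle; it is intended for the
  molecular sizes this package targets (tens of atoms per subset).
- The rectangular persistent Dirac matrix is not assembled when the block
  domains disagree (see above); only its kernel decomposition is exposed.
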