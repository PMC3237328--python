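# Methods

## Scope and model

`comap` predicts residue–residue contacts from the covariation of columns
in a multiple sequence alignment and re-balances the resulting score
matrix toward the bulk packing statistics of globular protein domains.
The underlying assumptions are (i) that packed residue pairs co-evolve,
so their alignment columns share mutual information beyond background;
(ii) that the MI matrix can be treated as covariance-like, so its inverse
separates direct from indirect coupling; and (iii) that a physically
realisable contact map obeys reproducible global statistics (total
contacts, per-residue packing distribution, sequence-separation
distribution) that can be imposed on a prediction without modelling the
3-D structure itself.

## Alignment handling

Alignments (FASTA or Stockholm) are masked to the columns where the
target sequence has no gap, so column indices map onto target residues.
A single-pass filter then drops rows more than 95 % identical to the
previously *retained* row, or with more than 20 % gaps, both fractions
over the target-masked columns. Using the previously retained row (rather
than the literal file predecessor, available via a flag) makes the filter
idempotent and order-stable. Identity counts positions with equal
symbols, gap–gap included, over the full masked length: the simplest
reading of "percentages over the un-gapped positions of the target".
The target row is exempt from both filters. Symbols outside the 20
standard amino acids are treated as gaps.

## Entropies and mutual information

Frequencies carry a pseudo-count of one amino acid spread over the
column: `f_a = (c_a + 1/N)/(n+1)` with alphabet size N = 21 for single
columns and 441 for pairs. This keeps every frequency positive (the log
never becomes undefined) and makes the frequencies sum to exactly 1.
Single entropies use log base 21, so a uniformly occupied column scores
exactly 1 and a conserved column tends to 0 as n grows.

For the joint entropy we also use base 21 by default. A base of 441 would
bound the joint entropy itself by [0, 1] but would break the property
that `M = S_i + S_j − S_ij` reaches 1 for identical uniform columns and 0
for independent ones; since both properties cannot hold at once, the
package defaults to the convention that keeps M a true mutual information
in [0, 1], with base 441 available through `joint_base`.

The MI diagonal is set to `S_i` (the value of the formula at i = j),
which doubles as a covariance-like diagonal for inversion. APC/ASC
backgrounds use row means excluding the diagonal and are subtracted from
raw MI by default (`correct_on="mir"` applies them to MIr instead). No
sequence weighting is applied.

Finite alignments carry a positive MI sampling bias of order
`(N−1)²/(2n ln 21)` (about 0.2 at n = 300, 0.03 at n = 2000); the APC/ASC
corrections remove most of its pairwise structure but depth still
matters.

## Direct information

The chosen score matrix (default MIp) has its diagonal restored to `S_i`
and is inverted with the SVD-based Moore–Penrose pseudo-inverse; relative
singular values below `rcond` (default 1e-12) are treated as zero, which
keeps the operation defined for the rank-deficient matrices MI data can
produce. Direct information is the partial correlation
`D_ij = −W_ij/√(W_ii W_jj)` with `D_ii = 0`; non-positive diagonal
entries of W (a symptom of severe ill-conditioning) zero the affected
rows with a warning. Negative off-diagonal entries produced by APC are
retained — partial correlation tolerates signed input and clipping would
discard information.

Treating MI as a covariance is an approximation that is best in the
weak-coupling regime. For a copy-chain i→j→k, true correlations factor
along the path and the partial correlation of (i, k) vanishes; MI does
not factor the same way, so a residual indirect coupling survives
inversion and grows with coupling strength. In simulations with
chain-coupled columns (L = 30, n = 2000), the indirect pair reliably
drops in rank under DI relative to MI at copy probability 0.6, while at
0.8–0.9 the residual exceeds the background partial-correlation noise and
the rank improvement becomes unreliable. The synthetic chain fixture
therefore uses 0.6 — also closer to the weak covariation signal real
families show — and the strong-coupling behaviour is a documented
limitation of the covariance approximation.

## Structural constraints

Default packing coefficients (total contacts `P(N) = 3.21N − 95.7`,
sd ≈ 50, valid over 100–200 residues; per-residue rank curve
`R(x) = 8(1−x) + (1/(x+0.2) − 1)`; separation rank curve
`S(x) = 7(1−x) + 0.8(1/(x+0.2) − 1)`) describe pseudo-centroid contacts
under 8 Å in non-redundant globular domains. Negative curve values are
clamped to 0 (counts cannot be negative). `fit_packing_model` refits all
coefficients (the two curve amplitudes by linear least squares with the
0.2 rank offset fixed) from any user-supplied set of (length, contact
pairs) records.

Contacts are selected as the `round(max(0, P(N)))` top-scoring pairs,
ties broken lexicographically for determinism. The over-packing
relaxation re-derives the contact set once per cycle, compares each
residue's count to its ceiling, and multiplies the offending residue's
pair scores (with its current contact partners, symmetrically) by
`1 − fraction` (default 0.5 %), worst violation first, for up to five
cycles. Two violation modes exist:

- **pointwise** (default): each residue's ceiling is the rank curve read
  at its fractional count-rank;
- **global cap**: a single ceiling, the curve value at rank 0 (= 12).

With a fixed contact budget the pointwise mode is not exactly satisfiable:
`P(N)` implies a mean degree slightly above the curve's average (5.12 vs
4.79 at N = 148), and re-selection against a fixed budget lets damped
pairs re-enter, so residual low-rank violations persist and the loop
simply runs its five cycles. The global-cap mode has a well-defined fixed
point and is what the hub convergence tests exercise; in practice the
pointwise mode still flattens the over-packed head of the distribution,
which is the correction that matters.

The local/distant balance is adjusted multiplicatively:
`D′_ij = D_ij · (1 − a·exp(−s²/2σ²))` with s = |i−j| and σ = 100
residues. Positive `a` shrinks the near-diagonal band so distant contacts
gain rank; the form was chosen to reproduce that stated sign behaviour.
Applying `+a` then `−a` does not exactly invert ((1−a)(1+a) = 1−a²).

## SSE polarity

Maximal H/E runs of the secondary-structure string are cores; flanks
extend into coil by up to 3 residues, never past halfway to the next SSE,
and weigh 0.5 (flank–flank cells 0.25). For an SSE pair, T is the
weighted sum of the score sub-matrix; the weighted centroid splits it
into quadrants, and polarity is the normalised contrast
`((NN+CC) − (NC+CN))/T`, bounded in [−1, 1], positive for parallel
(diagonal) and negative for antiparallel (anti-diagonal) contact
clusters. Residues exactly at a centroid coordinate count to the
N-terminal side (a deterministic tie rule; with even-length blocks the
noise-free diagonal and anti-diagonal cases score exactly ±1). Pairs with
T ≤ 0 (possible since DI is signed) are flagged rather than scored. An
unnormalised variant (raw quadrant contrast) is available.

## Structure-side geometry

Pseudo-centroids approximate side-chain positions from the backbone: a
point 2 Å from CA_i opposite the bisector of the unit vectors toward
CA_{i−1} and CA_{i+1} (the obtuse side of the virtual bond angle).
Terminal residues and collinear interiors fall back to the CA. All
residue types are treated alike, as a CA-only model carries no side-chain
identity. Contacts are centroid pairs under 8 Å with sequence separation
≥ 3 (the floor excludes trivially local pairs and is configurable).

SSE axes are principal-component lines through core CAs (≥ 3 residues),
endpoints by projection, oriented N→C. The reciprocal overlap area (ROA)
samples each segment at 1 Å steps; samples whose projection falls inside
the other segment contribute the reciprocal of their distance to the
other segment's *line*, and the mean is multiplied by the overlap length.
Measuring the reciprocal distance point-to-line (rather than between
sample pairs) makes the score scale exactly as 1/d for parallel segments
and agree with a dense quadrature within sampling error; distances under
1 nÅ are capped to avoid divergence for touching lines. Screening zeroes
the ROA for strand pairs on opposite sheet sides and damps same-layer
pairs by `4^(1−N_adj)` (nearest neighbours undamped; the base 4 reads as
"severe" geometric damping and is configurable). Sheet-side and adjacency
labels are inputs; sheet topology detection is out of scope. The combined
oriented score is `R = A(w_u T + w_o c P)` with c the cosine between the
directed axes and equal default weights — both c and P are signed, so
disagreement between predicted polarity and observed orientation
contributes negatively.

All geometric outputs are rigid-motion equivariant (tested under random
rotations and translations).

## Synthetic data

The generators emulate exactly the features the analysis assumes:
coupled-column alignments (background uniform or Dirichlet over 20 amino
acids, pairwise copy couplings, chain triples that induce purely indirect
correlation), ideal helices (rise 1.5 Å, twist 100°, radius 2.3 Å),
strand pairs at 4.8 Å spacing joined by an arc loop, hub traces, and hub
score matrices whose selected contacts over-pack one residue with 18
partners (the graded hub scores sit just above a tight background band so
multiplicative damping pushes them out a few at a time). They do *not*
emulate phylogenetic correlation between sequences, gap structure within
families, alignment errors, or realistic amino-acid substitution
preferences — so passing tests demonstrate the machinery's correctness
and its behaviour under idealised covariation, not performance on real
families. Every generator is seeded and byte-reproducible.

Problem sizes used in the test suite (alignments up to 2000 × 30, hub
matrices at L = 148, 20–100 seed repetitions) were chosen as the smallest
sizes at which the statistical properties under test are stable.

## Numerical choices

- Pseudo-inverse cutoff `rcond = 1e-12` (relative), exposed because MI
  matrices can be poorly conditioned.
- Contact-selection ties break lexicographically; per-residue rank ties
  break by stable sort on index.
- Entropy sums are evaluated per-column from exact integer counts, so the
  uniform-column value of 1 is exact to rounding.
- Matrix symmetry is enforced to 1e-8 on construction; partial
  correlation symmetrises its output against floating-point drift.

## Known limitations

- No sequence weighting or gap-aware MI treatment; deep, redundant or
  phylogenetically clustered families will carry correlated noise.
- The covariance interpretation of MI degrades for strong couplings (see
  above) — DI ranks, not magnitudes, are the usable output.
- The packing curves are length-range-bound (100–200 residues); outside
  that range `P(N)` is an extrapolation (negative below ~30, clamped).
- Pointwise relaxation with a fixed contact budget cannot reach zero
  violations (infeasible constraint set); it is a head-flattening
  correction, not a projection onto the feasible set.
- ROA is an approximation to buried-surface interaction; its quadrature
  step (1 Å) and screening base (4) are conventions, not fitted values.
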