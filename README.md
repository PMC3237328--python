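# comap

Residue–residue contact prediction from multiple protein sequence
alignments, with structural re-balancing of the predicted contact map and
secondary-structure packing scores for fold filtering.

## What it does

Packed residue pairs in a folded protein constrain each other's mutation,
so covariation between alignment columns carries a (weak) structural
signal. `comap` extracts and refines that signal in four stages:

1. **Mutual information.** For columns *i*, *j* of a filtered alignment,
   `M_ij = S_i + S_j − S_ij`, where entropies use pseudo-counted
   frequencies `f_a = (c_a + 1/N)/(n + 1)` over a 21-letter alphabet (20
   amino acids + gap) and logarithms in base 21, so `M` lies in [0, 1] at
   the uniform extremes. Background corrections (APC/ASC: subtracting
   `m_i·m_j/m̄` or `m_i + m_j − m̄` built from row means) give the MIp and
   MIa variants; normalisation by `S_ij` gives MIr.
2. **Direct information.** The score matrix is treated as covariance-like
   and inverted with the SVD-based Moore–Penrose generalised inverse
   (singular values below `rcond·s_max` dropped). Partial correlations
   `D_ij = −W_ij / √(W_ii W_jj)` suppress indirect (chained) couplings.
3. **Structural constraints.** Predicted contacts are re-balanced toward
   globular-domain bulk statistics derived from pseudo-centroid contacts
   (< 8 Å) over a non-redundant domain set: expected total contacts
   `P = 3.21 N − 95.7`, per-residue rank curve
   `R(x) = 8(1−x) + (1/(x+0.2) − 1)` and separation rank curve
   `S(x) = 7(1−x) + 0.8(1/(x+0.2) − 1)`. Over-packed residues have their
   pair scores damped by 0.5 % per cycle (≤ 5 cycles); a Gaussian factor
   `1 − a·exp(−s²/2σ²)` (σ = 100) trades local against distant contacts.
4. **SSE-level scores.** Contact scores aggregated over secondary-structure
   element pairs (cores + half-weight flanks ≤ 3 residues) yield a total
   interaction `T` and a signed polarity
   `P = ((S_NN + S_CC) − (S_NC + S_CN)) / T` — positive for parallel,
   negative for antiparallel packing. On the structure side, pseudo-
   centroids (2 Å along the obtuse bisector of the virtual CA bond angle),
   axis segments, the reciprocal overlap area (ROA) with β-sheet
   screening, and the combined oriented score `R = A(w_u T + w_o c P)`
   allow predictions to be compared with (model) structures.

## Worked example

```sh
comap simulate msa sim.fa --seed 17        # 500 x 30 coupled-column MSA
comap mi --score mip sim.fa mip.txt
comap di sim.fa di.txt
comap rebalance --a 0.1 di.txt reb.txt
```

which prints

```
500 x 30 alignment -> sim.fa
MIp matrix 30x30 -> mip.txt
DI matrix 30x30 (rank 30) -> di.txt
rebalanced matrix -> reb.txt
```

i.e. a synthetic 500-sequence alignment over 30 columns, its APC-corrected
mutual-information matrix, the direct-information matrix obtained through
the generalised inverse (numerical rank 30 — well conditioned here), and
the re-balanced matrix after over-packing relaxation and Gaussian
separation rescaling with a = 0.1 (shrinking near-diagonal scores so
distant contacts gain rank). The full pipeline, including contact
selection and SSE pair polarities, is `comap run sim.fa out/ --sse sse.txt`.

In Python:

```python
import comap

aln = comap.read_alignment("sim.fa")
D = comap.direct_information(aln, score="mip")
contacts = comap.select_contacts(D, N=aln.L)
```

## Layout

- `src/comap/alignment.py` — FASTA/Stockholm parsing, target masking, 95 %/20 % redundancy-gap filter
- `src/comap/mi.py` — entropies, MI, MIr/MIp/MIa
- `src/comap/direct.py` — generalised inverse, partial correlation
- `src/comap/constraints.py` — packing curves, contact selection, relaxation, Gaussian rescale, curve refitting
- `src/comap/sse.py` — SSE windows and pair polarity
- `src/comap/geometry.py` — pseudo-centroids, contacts, axes, ROA, evaluation
- `src/comap/simulate.py` — seeded synthetic alignments, toy traces, hub matrices
- `src/comap/cli.py` — the `comap` command

See `docs/methods.md` for the model details, default parameters and known
limitations.
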