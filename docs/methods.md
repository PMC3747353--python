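# Methods

## Problem and model

Segmental duplications (SDs) and copy-number variants (CNVs) in primate
genomes are mosaics of smaller duplicated subunits ("duplicons",
minimum ~100 bp) whose juxtaposition composes larger duplication
blocks. Given tabular alignments of a set of SDs against one CNV of
length *n*, the evidence is condensed into a binary *m* × *n* alignment
matrix *A* with *a(i, j)* = 1 when SD *i* aligns over position *j* of
the CNV. Real duplicons appear as column blocks of consecutive 1s
carried by many rows; spurious alignments appear as sparse, short runs.

Duplicons are decoded with a three-state hidden Markov model over the
columns. The states are two duplicon states D1/D2 — two, so that
directly adjacent duplicons can be separated — and a nonduplicon state
N. The chain is **non-homogeneous**: the transition matrix between
columns *j* and *j*+1 is rebuilt from the 0/1 pattern counts of that
column pair,

- f11 = rows set at both *j* and *j*+1,
- f01 = rows set only at *j*+1,
- f10 = rows set only at *j*,

via ω = f11/(f11+f01+f10) and γ = f01/(f01+f10). A duplicon state stays
with probability *p*·ω, switches to the other duplicon state with
(1 − *p*ω)·γ and leaves to N with (1 − *p*ω)(1 − γ), where
*p* = 1 − 1/*L* encodes a geometric duplicon-length prior with mean *L*
(default 4 651 bp, the mean length of duplicons in the published
duplicon library). N transitions to each state with probability 1/3.
Emissions come from the column sum *o(j)*: duplicon states emit the
cumulative binomial P_d = BinomCDF(*o(j)*; *m*, P_o), N emits 1 − P_d.
The maximum-probability path is found by the Viterbi algorithm in log
space, and maximal D1/D2 runs of at least `min_len` = 100 columns
become candidate duplicons.

## Estimating P_o

P_o is the probability that a given SD carries a given duplicon
position; in the original formulation it is the ratio of two
duplicon-library statistics (mean copy number over the number of
catalogued SDs) that are not generally available. The pipeline
therefore estimates it per matrix as the matrix's overall 1-density —
the empirical probability that a given row covers a given column. The
estimate is floored at 1 − 0.5^(1/m) so that an empty column can never
favour a duplicon state (BinomCDF(0; m, P_o) ≤ 1/2), and capped at
0.99. This matters: with a fixed P_o below the background alignment
coverage, the cumulative-binomial emission favours the duplicon state
even on noise columns and decoded segments bleed past true block
boundaries. The same estimate is applied to the artificial matrices of
the permutation test, whose density is identical by construction.
`HmmParams` retains an explicit user-settable P_o (default 0.05) for
direct use of `viterbi`/`emission_prob`.

## Permutation test

The copy number of a candidate is the mean column sum over its
interval. The null relocates every maximal 1-run **within its own
row**: run order is shuffled and the zero gaps are redrawn uniformly at
random over all layouts that keep runs separated (internal gaps ≥ 1,
end gaps ≥ 0, via a stars-and-bars draw), so each row's run-length
multiset — and hence its total alignment footprint — is conserved
exactly. B = 100 artificial matrices are decoded with the same HMM and
the maximum candidate copy number of each is recorded (0 when a matrix
yields no candidate). A candidate's P value is the fraction of
artificial maxima **strictly** greater than its copy number (ties do
not count against it), so P values live on the grid {0, 1/B, …, 1}.
Calls with P < α = 0.01 are kept, then near-identical calls (reciprocal
overlap ≥ 95%) collapse to the lowest-P representative; an optional
sequence mode collapses calls matching at ≥ 95% identity over ≥ 100 bp
when CNV sequences are supplied.

## Mosaic analyses

**Profiles.** A duplication segment's phylogenetic profile is the
binary presence vector over all duplicons, with presence requiring an
aligned occurrence at ≥ 95% identity over ≥ 100 bp. Segments with
fewer than 10 distinct duplicons are dropped, as are duplicons absent
from every retained segment.

**Distance and tree.** Profile distance is the Hamming fraction
(discordant bits over vector length) — the simplest metric on binary
vectors; it is swappable, and pairs sharing no duplicon are flagged as
having no related evolutionary history. Trees are built by
neighbor-joining (scikit-bio); segment ids are sorted before the
distance matrix is assembled so ties resolve deterministically. NJ is
exact on additive distances, which the tests exploit.

**Core duplicons.** The tree is midpoint-rooted (NJ's own rooting is
arbitrary and would hide the clade containing the root), and every
internal node with ≥ 3 leaves is scanned as a clade; duplicons present
in strictly more than 67% of a clade's leaf segments are its cores.
How clades were delimited in the original analysis is not recorded;
internal-node scanning is this package's convention.

**Flanking pairs.** For a CNV of length ℓ the end windows are the first
and last ⌊0.25·ℓ⌋ bases. A flanking pair is one occurrence fully inside
each window with similarity and length > 90%: with sequences, pairwise
identity > 90% (edit-distance based) and shorter/longer length ratio
> 0.90; without sequences, two copies of the same duplicon id qualify.

**Weighted density.** Each duplicon's weight is the number of training
CNVs containing it; the weighted density of a region is the summed
weight of occurrences lying in the region, divided by region length. An
occurrence belongs to a region when ≥ 50% of its bases fall inside
(so a partition of the genome counts each occurrence once, except at
exact ties). Non-CNV regions are the complement of merged CNVs within
the given chromosome bounds. CNV vs non-CNV densities are compared with
a two-tailed Welch's t test (scipy, Welch–Satterthwaite df).

## Synthetic data

`simulate.generate_matrix` plants duplicon column-blocks carried by a
Bernoulli(carrier_fraction) subset of rows and adds, per row,
Poisson(noise_rate) background runs with geometric lengths (mean 20 by
default — short relative to real duplicons, mimicking spurious local
alignments). `generate_segment_set` builds groups of segments sharing a
controlled fraction of group-private duplicons, with one designated
core forced into a chosen fraction (default 80%) of each group's
segments. `generate_flanked_cnv` places duplicon copies once in each
25% end window plus unpaired fillers in the middle. All generators are
bit-reproducible from their seed.

What the fixtures do **not** emulate: real alignment artefacts
(per-base mismatch/gap structure, identity decay with age, tandem
periodicity), correlated noise between related SDs, and nucleotide
sequences themselves (occurrence identities are drawn, not aligned).
Passing tests therefore demonstrate correctness of the decoding and
testing machinery under the stated statistical model, not calling
accuracy on real genomes.

Validation problem sizes: planted-recovery runs use m = 50 SDs,
n = 500 columns, one 150-column block at carrier fraction 0.8,
noise_rate 2, with B = 100 and α = 0.01 over 50 seeds; decoder
exactness is checked against exhaustive path enumeration (3^n paths,
n ≤ 8, m ≤ 5, 200 instances); NJ exactness on 100 random additive
trees of ≤ 8 leaves.

## Numerical conventions and degenerate inputs

- Internal coordinates are 0-based half-open; BLAST tabular input is
  1-based inclusive and reversed subject coordinates are normalised to
  the minus strand.
- The initial distribution puts 1/2 on D1 and 1/2 on N; D2's zero prior
  is a hard −inf in log space. All other zero probabilities are clamped
  to a configurable floor (default 1e-300) before logs; the floor is
  part of the model definition.
- Degenerate transition denominators: f11+f01+f10 = 0 sets ω = 0,
  f01+f10 = 0 sets γ = 0, sending all non-stay mass to N — absent
  switching evidence should not invent a duplicon.
- Viterbi ties prefer N over D1 over D2 at every choice point:
  deterministic and conservative.
- A matrix with no rows decodes to the all-N path (no alignment
  evidence implies no duplicon), bypassing the emission model, which
  would otherwise degenerate (P_d ≡ 1 at m = 0).
- α = 1.0 is accepted as the vacuous filter that retains every
  candidate.
- Rows in one alignment matrix are per-CNV: an SD aligning to several
  CNVs contributes an independent row to each matrix.

## Known limitations

- Tabular alignments lack per-base detail, so by default the whole
  subject span of an HSP is marked 1 (the strict mode consumes an
  optional match-mask column when a producer can supply it).
- The permutation null preserves per-row run multisets but not
  cross-row correlation; strongly correlated noise (e.g. a shared
  repeat family) can inflate null maxima or, conversely, escape them.
- Core-duplicon results depend on the clade convention (every internal
  node ≥ 3 leaves after midpoint rooting); a fixed-depth cut can give
  different tallies.
- Sequence identity in sequence modes is edit-distance over the full
  extracted intervals, not a local alignment; long unrelated flanks
  depress it.
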