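# Methods

## The motif model

A DNA motif of length *m* is a 4 × *m* position frequency matrix (PFM) of
nucleotide counts (rows A, C, G, T).  With pseudocount α ≥ 0 the position
probability matrix is

    PPM(i,j) = (PFM(i,j) + α) / Σ_i (PFM(i,j) + α)

and the position weight matrix (PWM) is the base-2 log-odds against a
background model b = (b_A, b_C, b_G, b_T):

    PWM(i,j) = log2(PPM(i,j) / b_i)   [bits]

The score of a length-*m* window is the sum of the selected weights; an
*occurrence* is a window whose score is **≥** the motif's threshold
(non-strict, so p = 1 admits every window).  Defaults are α = 1 and a
uniform background b_i = 0.25; the background can instead be estimated
from the input's mononucleotide frequencies or supplied as four numbers.
Lowercase (soft-masked) sequence is uppercased before encoding — scanning
deliberately does not skip masked regions.  Non-ACGT symbols contribute
exactly 0 to a score under the default `zero` policy (the one-hot
"otherwise → 0000" encoding); the stricter `exclude` policy drops any
window containing such a symbol, because tools in this space differ on
this point and the choice changes the occurrence set on N-rich input.

## p-value → threshold dynamic program

Under the background model, the window score is a sum of *m* independent
per-column draws.  Weights are discretized to an integer grid of width ε
(nearest integer, ties to even; default ε = 1e-3 bits) and the exact PMF
of the discretized score is built by per-position convolution:

    D_0 = δ_0,   D_{j+1}(s) = Σ_i b_i · D_j(s − e'_{i,j})

The threshold for p-value *p* is the smallest grid score whose upper tail
mass is ≤ p, reported in bits.  The construction equals brute-force
enumeration over all 4^m words bin for bin (tested to 1e-9 for m ≤ 8),
and the true-score error from discretization is bounded by m·ε/2
(≤ 0.015 bits at the defaults for m = 30).  The grid threshold is applied
unchanged to undiscretized floating scores during scanning; the naive
reference applies the identical rule, so the discretization choice cannot
break equivalence.  A bin budget (default 8·10⁶) rejects pathological ε.
Thresholds are computed from each forward PWM's distribution and applied
to both strand columns (under a uniform background the reverse
complement's distribution is identical).

## The matrix-product scan

The brute-force scan is reorganized into dense matrix products:

* **Pattern matrix P** (4m × c): every PWM unrolled column-wise
  (position-major), zero-padded to the longest motif length m; reverse
  complements appended as c further columns when both strands are
  scanned.
* **Sequence matrix S** (h × 4(w+m−1)): a chunk of hw+m−1 symbols is
  one-hot encoded (A=1000, C=0100, G=0010, T=0001, other=0000) and laid
  out with rows overlapping by m−1 symbols; S is a strided view, never a
  copy.
* **Score blocks**: for each offset o ∈ [0, w), R^o = S[:, 4o:4(o+m)] · P
  gives the scores of all pattern columns at chunk positions i·w+o.

Since the one-hot rows merely select weights, each product entry is the
same sum the scalar scorer computes.  Chunk geometry defaults to
h = 1000, w = 250; h and w affect throughput only — output is proven
identical for (1,1), (3,2) and (1000,250) in the test suite.

Multiple FASTA records are concatenated with a single sentinel symbol
(encoded 0000, record index −1) between neighbours.  A validity mask —
window start and end must carry the same non-negative record index —
suppresses every window that would span a junction, the sentinel itself,
or the right-padding of the final chunk, so no occurrence can bridge
records even though the chunks do.  Chunks may be processed by several
worker threads (the BLAS products release the GIL); results are collected
per chunk and finally sorted by (record input order, start, original
pattern-column index), which makes output byte-identical across worker
counts and chunk geometries.

**Numerics.** All matrices are float64 and the products go through
numpy's BLAS.  Scores agree with the scalar reference to ~1e-15
(contractual tolerance 1e-4).  One boundary effect is real: a window
whose score sits *exactly* at its threshold is sensitive to summation
order in the last ulp, because BLAS accumulates dot products in a
different association order than left-to-right scalar addition.
DP-derived thresholds are grid multiples that never coincide with window
scores, so this never affects p-value scanning; it only matters when a
threshold is set to an exactly attainable score (e.g. a consensus score),
which is why `score_window`, `score_extrema` and `naive_scan` share one
accumulation order and planted-site recall is defined through them.

**Naive reference.** `naive_scan` is the three-nested-loop scanner
(records × motifs × positions), vectorized over positions by per-position
gather-and-add — a computation path with no matrix products, used as the
oracle in every equivalence test.

## Tiling

Length-diverse motif sets leave large trailing-zero blocks in P.  Columns
are stable-sorted by motif length; a tile over columns [c_i, c_{i+1})
with internal maximum length m_i uses only rows [0, 4m_i):

    R^o[:, c_i:c_{i+1}] = S[:, 4o:4(o+m_i)] · P[0:4m_i, c_i:c_{i+1}]

Binary splits are placed where the discarded zero area
4·(m_tile − m_left)·(columns left of the split) is maximal (ties toward
the smaller split index) and recursion stops when the best discardable
area falls below `min_area` (default 4096 elements, measured in matrix
elements; elements and multiply-adds are proportional at fixed h).
Zero-area splits are never taken, so the recursion terminates even at
`min_area = 0`.  On 1404 columns with lengths uniform in [5, 30] the
default setting produces 4 tiles and removes ~78% of the structural
zeros (computed by `zero_fraction`).  Tiling never changes occurrences:
positions are identical and scores agree within 1e-5 (observed ~1e-15).

## Synthetic data

The fixture generators emulate a JASPAR-like study setting: motif counts
drawn per column from a sharpened flat Dirichlet (concentration 1 = flat;
large values give single-letter columns; sharpening is done in log space
so extreme values stay finite), depth 100 per column, lengths uniform in
[5, 30] (scan fixtures use [5, 15], the typical core-motif range), and
i.i.d. background sequence — 3 records totaling 10 kb for equivalence
fixtures.  Planted sites overwrite consensus windows (reverse-complement
consensus for minus-strand plants) at non-overlapping positions; truth
scores are realized in the same summation order the scanner uses for that
strand.  Every generator is a pure function of its seed.

What the generators do *not* emulate: repeat structure, CpG islands,
composition heterogeneity, assembly gaps beyond isolated Ns.  Passing
tests therefore demonstrate algorithmic correctness (equivalence with the
exhaustive reference, exact threshold calibration under the stated null),
not biological calibration of p-values on real genomes, where the i.i.d.
background is known to be only an approximation.

## Problem sizes and design choices

Equivalence is tested on 50 seeded 10 kb fixtures across the full grid of
worker counts {1, 4}, tiling {on, off}, and chunk geometries {(1,1),
(3,2), (1000,250)}; threshold exactness on 200 random PWMs with m ≤ 8
(4^m enumeration); scaling on 0.25–1 Mb × 50–200 pattern columns, where
runtime ratios stay within a factor 2 of linear.  These sizes make the
full suite run in a couple of minutes while exercising every code path;
all of them are configurable.

Choices made where the design was genuinely open, and why:

* **Occurrence ordering** is (record input order, start, original pattern
  column); minus-strand hits report the leftmost forward-strand base.
  This matches genome-browser expectations and makes strand symmetry
  directly testable.
* **Record concatenation** materializes O(n) bookkeeping arrays rather
  than streaming them; chunk *processing* is still chunkwise.  At the
  package's intended scale this is simpler and faster; a fully streaming
  concatenator is the natural extension for genome-scale inputs.
* **The in-memory result** collects occurrences and sorts once rather
  than spilling buffers to disk; `n_occ_buf` (default 10⁶) is the CLI's
  write-batching granularity.  Extremely permissive thresholds on large
  inputs can therefore be memory-hungry; use smaller p-values or scan in
  batches.
* **float64 everywhere**: single precision would halve memory traffic but
  makes the 1e-4 score tolerance less comfortable; correctness, not
  throughput, is this implementation's priority.

## Known limitations

* Memory grows with the number of reported occurrences (see above).
* Thread workers help only as much as the BLAS products dominate; at tiny
  h·w the per-chunk Python overhead wins.
* Only mononucleotide (zeroth-order) background models; no higher-order
  motif models; no FDR control across motifs (thresholding is per motif).
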