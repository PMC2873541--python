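# Methods

## Model

`coalign` treats pairwise genome alignment as two nested local-alignment
problems.  At the coarse level the alignment elements are fixed-length
blocks and the "substitution score" of a block pair is the summed
surprise, under a Poisson chance model, of the spaced-seed codes the two
blocks share.  At the fine level the elements are nucleotides, and the
search space is restricted to the envelopes of the coarse alignments.
The coarse stage is what makes the method rearrangement-aware: colonies
off the main diagonal are translocations or duplications, and colonies
found against the reverse complement of the second genome are
inversions.  The fine stage is a conventional seed–extend–chain–fill
local aligner confined to a narrow band.

Key modelling assumptions:

* **Poisson chance occurrences.** The count of a given seed code in one
  block is modelled as Poisson with mean μ_i = N_i/m (genome-wide count
  over number of blocks).  This ignores compositional heterogeneity;
  codes that exceed the repeat cutoff (1024 genome-wide) or the per-block
  cap (3) are excluded rather than modelled.
* **min(f, h) matching.** Credited matches between two blocks are
  min(f_i, h_i), not f_i·h_i, since genuinely homologous occurrences lie
  on one diagonal.
* **Rearrangements ≥ block size.** Events smaller than one block (10 kb
  default) are not searched for; the block DP cannot see them.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| seed pattern | `111*1**1*1**11*111` (11/18) | — | BA and NA seeding; 12/19 and 13/20 available |
| block size J | 10 000 | bp | coarse DP element; num_blocks must stay < 2^16 |
| T_col | 3000 | score (natural-log units) | colony significance and X-drop threshold |
| d | T_col/15 = 200 | score | block-level gap penalty |
| a | 5 | cells | bias design: unrelated run X-drops after ~a cells |
| repeat cutoff | 1024 | count | genome-wide code count above which a code is dropped |
| max_occ | 3 | count | per-block occurrence cap of the Poisson tables |
| merge_dist | 20 | bp | max same-diagonal gap joined into one HSP |
| T_low / T_high / T_dp | 50 / 2J / 200 | bp | fill-stage regime boundaries |
| gap open / extend | 400 / 30 | score | affine penalties (a gap of g costs 400 + 30g) |
| xdrop gapless / gapped | 200 / 600 | score | extension termination |
| hsp_min_score (outer / inner) | 1500 / 500 | score | HSP acceptance after extension |
| pen_overlap slack | 10 | bp | chaining overlap forgiveness |

Score units: block-level seed scores are plain natural-log surprisals
(`BAParams.log_scale = 1.0`).  This scale makes the defaults mutually
consistent — an unrelated cell costs on average T_col/a = 600 after bias
subtraction, so five unrelated cells exhaust exactly T_col — whereas any
multiplied scale would leave T_col incommensurate with the chance
fluctuations of M.  The factor is configurable for users who want
integer-ish scores.  Nucleotide-level scores use the Chiaromonte
match/mismatch table (A·A 91, C·C/G·G 100, T·T 91, mismatches −31 to
−125), shipped as `src/coalign/data/chiaromonte.tsv`; pairs involving
ambiguous bases score −100.

The unstated-threshold choices (xdrop_gapless 200, xdrop_gapped 600,
hsp_min_score 1500) sit on the Chiaromonte scale: 200 tolerates one
mismatch but not two adjacent ones during gapless extension; 600 allows
a short indel (430 + drift) during gapped extension; 1500 requires
roughly 16 matching bases, comfortably above the score of chance
double-seed hits.  The inner (7-mer fill) threshold is 500 because fill
intervals are short and bounded, so chance HSPs are already rare.

## Algorithmic and numerical choices

* **Colony bookkeeping.** Cells are assigned to colonies during the
  row-major DP sweep; a cell whose score falls more than T_col below its
  colony's running maximum is reset to zero (X-drop).  The running
  maximum is tracked in scan order, a faithful and deterministic
  approximation of path-wise drop tracking.  Ties in the DP break
  diagonal > up > left > stop, and colony filtering ties break toward
  the smallest (x_min, y_min), so runs are bit-reproducible.
* **Bias estimation.** B = mean(M) over 1000 block pairs sampled with a
  fixed, logged RNG seed, plus T_col/a.  On highly self-similar inputs
  the sample may include homologous cells, inflating B slightly; this is
  conservative (it suppresses weak colonies, never invents them).
* **M computation.** The shared-code join is vectorised over the two
  index tables and accumulated into a dense m_a × m_b matrix.  Desk-scale
  inputs (up to tens of Mb) fit easily; the strict O(min(m_a, m_b))
  row-streaming formulation of the original design is a memory
  optimisation this implementation does not need.
* **Chaining.** The collinear-chaining DP is O(n²) vectorised rather
  than O(n log n) sparse: the overlap penalty breaks the monotone
  prefix-maximum structure the classical sparse algorithm exploits, and
  after the hsp_min_score filter n is a few hundred per colony, so the
  quadratic DP costs milliseconds.
* **Global affine DP.** `global_dp` delegates to Biopython's
  `PairwiseAligner` (exact algorithm, C implementation) with the
  Chiaromonte matrix and open/extend −430/−30 so that a gap of length g
  costs 400 + 30g.  Path tie-breaking among co-optimal alignments is
  the aligner's deterministic internal order.  A 20 kb hard cap bounds
  memory; longer regions must be seeded or left unaligned.
* **Gapped extension.** The best end cell is located by a row-wise
  affine DP with X-drop termination (extension window capped at 2048 bp
  per side); the alignment path is then recovered by global DP over the
  consumed prefixes.
* **Envelope.** The 3×3-block dilation of the colony path, clipped to
  the sequences.  Seed matches are kept only if their (a, b) pair falls
  in a dilated cell; all fragment coordinates stay inside the envelope's
  bounding rectangle.
* **Degenerate inputs.** Genomes shorter than the seed span yield empty
  tables; absent codes get a μ = 0 Poisson class (p(0) = 1, tails 0);
  empty fill intervals on one side are implied indels and produce no
  fragment; an empty reference in the evaluator yields NaN sensitivity
  with a warning.

## Synthetic data

The generator emulates a homologous genome pair at a chosen
substitution-adjusted identity: point substitutions with a 2:1
transition:transversion ratio, insertions/deletions opened at
`indel_rate` per base (default 5·10⁻⁴, split evenly, geometric lengths
with mean 3 — values typical of closely related mammalian or
intra-species bacterial comparisons), then inversions, translocations
and duplications applied as a segment permutation of the mutated
sequence.  Repeat families can be pasted and lowercased before
divergence, emulating ancestral repeats masked in both genomes.  Every
orthologously aligned base pair is tracked through the permutation into
a truth file; duplication copies are paralogous and excluded from the
truth, so an aligner that reports both copies loses specificity, exactly
as with real references built from orthologous gene sets.

What the generator does **not** emulate: compositional bias (GC
isochores), repeat-family evolution, microsatellite slippage, segmental
duplications with internal divergence, and N-runs/assembly gaps.
Passing tests on this substrate therefore demonstrate correctness of
the algorithms and their rearrangement handling at the stated identity,
not performance on the full messiness of real genomes.

Problem sizes used by the test-suite and acceptance runs — 1 Mb pairs
for the rearrangement study, 100 kb for self-alignment, 5 kb genomes for
exhaustive-oracle comparisons — were chosen so a laptop reproduces every
number in minutes while each computation still spans many blocks,
colonies and fill regimes.

## Known limitations

* Rearrangements smaller than a block are invisible to BA, and the
  fill stage does not search for sub-block inversions.
* Specificity degrades when duplications are present and consistency
  filtering (`-cs`) is off, since both copies may be reported.
* The T_col rescaling rule for non-default block/k-mer sizes
  (`scale_tcol`: linear in the block-size ratio, 4^(−k_diff·c) in the
  seed weight) is a documented heuristic of this package, exposed as
  configuration rather than a canonical formula.
* The colony X-drop uses the scan-order running maximum; adversarial
  score grids with deep internal dips inside one colony can split or
  truncate it relative to an unbounded Smith–Waterman optimum.
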