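# Methods

This note documents the statistical model, the algorithms, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Generative model and likelihood

A metagenomic sample over M reference strains is modeled as a mixture: a
fragment is generated by selecting strain `r_i` with prior probability
Pr(r_i | θ) and then emitting a fragment compatible with that strain.
Fragments aligning to exactly the same set of references are collapsed into
an equivalence class `F^q` labeled by that set, Ω(F^q), with member count
N^q, and the optimized objective is the likelihood of observing the classes,

    L(θ : F) ∝ ∏_{F^q ∈ C} ( Σ_{r_i ∈ Ω(F^q)} Pr(r_i | θ) · Pr(f | F^q, r_i) )^{N^q}.

All N^q fragments of a class are treated identically and share the class's
per-reference conditional probabilities.

**Conditional probabilities.** Alignment scores are mapped to
Pr(f | F^q, r_i) = exp(α · (S_i − S_best)), where S_best is the fragment's
best score across references and α (default 1.0, per score unit) sets how
quickly sub-optimal alignments lose credibility. A fragment's best-scoring
reference always has conditional probability 1. The class weight is the
arithmetic mean of its member fragments' probabilities per reference. Base
qualities do not enter the model.

**Range factorization.** With classes alone, a fragment aligning almost
perfectly and one aligning marginally to the same reference set would be
conflated. Each fragment's per-reference probabilities are therefore binned
into `bins` equal-width bins over (0, 1] (default 4), and the bin signature
becomes part of the class key. `bins = 1` recovers the classical reduction
exactly, which the tests rely on. Binning operates on probabilities, not raw
scores: probabilities are scale-free under α, which makes the bin widths
meaningful across scoring schemes.

## EM updates and the monotone likelihood

E-step: within class q, reference i gets responsibility
∝ prior_i · w_{q,i}, normalized over the class label, with
prior_i = θ_i · c_i (c_i the coverage ratio, below; c_i ≡ 1 when the
coverage prior is off). M-step: est_i = Σ_q N^q · resp_{q,i} and
θ_i ∝ est_i / ℓ̃_i normalized, where ℓ̃_i is the effective length.
Total estimated reads equal the total fragment count after every iteration
by construction — this is the engine's central invariant.

The θ-parameterization above divides by effective length in the M-step, so
it is not literally a classical EM in θ. It is, however, *exactly* classical
EM in read-fraction coordinates π_i = est_i / N with per-class conditionals
v_{q,i} = w_{q,i} · c_i / ℓ̃_i: substituting θ_i ∝ est_i / ℓ̃_i into the
E-step gives responsibilities ∝ π_i · v_{q,i}, and the M-step is the
standard mixture-weight update π_i = est_i / N. The reported log-likelihood

    ℓ(π) = Σ_q N^q log Σ_{i ∈ Ω(q)} π_i · v_{q,i}

is therefore non-decreasing across EM iterations as long as c_i and the
class structure are fixed — i.e., within each stretch between thresholding
rounds. This is the quantity the monotonicity tests check (tolerance 1e-8).
Across rounds the class set and coverage change, so no comparison is made.

**Effective length.** ℓ̃_i = max(1, L_i − μ_frag + 1), with μ_frag the mean
fragment length (default 300 bp, the standard short-insert library setting
that the simulator also uses). It approximates the number of valid fragment
start positions.

**Coverage ratio.** c_i = (number of distinct fragment start positions on
reference i among classes where i's responsibility exceeds 0.01) / ℓ̃_i,
clipped to [1e-6, 1]. A genuinely present reference accumulates starts
across its whole length; a reference that only borrows ambiguous reads from
a similar genome covers a small fraction, and the prior down-weights it.
Ratios are recomputed once per thresholding round and at the start of the
final convergence phase, never inside an EM stretch (which would break
monotonicity). The floor prevents a hard-zero prior from orphaning a class.
Start positions are only available when classes are built from alignments;
collections loaded from the plain-text class table carry no positions and
fall back to c_i = 1 (pure-θ prior). The `use_coverage_prior` option turns
the factor off entirely.

## Iterative mass-preserving thresholding

Low-abundance false positives cannot be fixed by a plain final cutoff
without losing the reads assigned to the discarded references. Instead,
every `k_between_setcover` = 10 EM iterations:

1. **Mark.** References with est ≤ cutoff (default 2, the same value as the
   final cutoff; marking is inclusive) become *potentially removable* (PR).
2. **Safe removal.** A PR reference whose every class contains at least one
   non-PR reference can be deleted without any class losing all its members.
3. **Set-cover.** Each remaining PR reference belongs to at least one
   *critical* class (all members PR). To retain as few PR references as
   possible while keeping every critical class non-empty, the standard
   greedy set-cover approximation repeatedly picks the candidate covering
   the most uncovered critical classes. Ties prefer the higher current
   estimate, then the lexicographically smaller reference id — a pure
   determinism device; for a fully symmetric island any member is an equally
   valid representative. Candidates never picked are removed.
4. **Update.** Removed references are deleted from labels; surviving weights
   are rescaled so the best surviving reference has weight 1 (a no-op for
   the EM, which renormalizes within classes, but it keeps the
   conditional-probability semantics); classes whose (label, bin signature)
   coincide are merged with counts summed. One E/M pass then redistributes
   the removed references' estimated mass, so the round as a whole preserves
   the total exactly.

A round that removes nothing ends the loop; EM then runs until the maximum
absolute change of any estimate is ≤ `convergence_tol` (0.01 fragments — a
conservative bound that is cheap at the problem sizes this package targets)
or the 1000-iteration budget is exhausted. Each non-idempotent round removes
at least one reference, so the number of rounds is bounded by the number of
references; the engine asserts this bound at run time.

**Final cutoff.** References with est ≤ cutoff are dropped from the report
(inclusive, matching the worked example's "equal to or less than 2 reads";
`cutoff_inclusive=False` gives the strict reading). This is the only step
that discards mass, and the discarded amount is reported alongside the
removal log, which attributes every removal to safe-PR, set-cover, or the
final cutoff with its round index.

A consequence worth stating: thresholding only ever touches references at or
below the cutoff. Two *identical* references sharing abundant reads stay at
a symmetric split forever — the machinery sparsifies low-abundance islands,
it does not break high-abundance symmetry, which no evidence could resolve
anyway.

## Mapper

The mapper reproduces selective-alignment semantics at desk scale. The index
is a plain hash from canonical k-mers (lexicographic min of k-mer and
reverse complement; default k = 19, configurable) to occurrence lists;
k-mers containing N are skipped. Per read, every k-mer is looked up, hits
are grouped by (reference, strand) — reverse-strand hits are handled by
aligning the reverse-complemented read — deduplicated per diagonal, and
extended to maximal exact matches. MEMs are chained by an O(m²) DP
maximizing Σ lengths − 0.01 × Σ gap spans with no read/reference overlap;
the best chain per (reference, strand) is kept. Regions between chained MEMs
and at read ends are aligned with an affine-gap global aligner
(Bio.Align.PairwiseAligner; match 2, mismatch −4, gap open 5, gap extend 3 —
conventional short-read values, fully configurable), and the record score is
the sum of matched and aligned regions, clamped to match × read length.
CIGARs are assembled from the chain and alignment paths, and a recomputation
of the score from CIGAR plus sequences must reproduce the stored score
exactly (tested).

Paired mates must hit the same reference in opposite orientations within a
fragment-span bound (default 1000 bp); the fragment score is the mate sum,
and orphan fragments are dropped by default (`keep_orphans` reports the
better mate alone). The score filter keeps records with fragment score
≥ 0.65 × (match × total read length); the bound is inclusive ("at least"),
and for pairs the best possible score sums the mates — a convention, since
the per-fragment definition is not otherwise pinned down.

Coordinates are 0-based half-open internally and 1-based in SAM; multi-maps
are secondary records, scores travel in `AS:i:`, and the SAM reader needs
only that tag, so externally produced alignments can feed the engine.

## Simulator

`simulate_genomes` draws i.i.d. uniform sequences; an island's members are
independent per-base mutations of a shared base sequence at rate
1 − identity, so the *pairwise* identity within an island is ≈ identity²
(e.g. 0.995 → ≈ 0.990 pairwise), which the generator's tests measure
directly. `simulate_reads` places exactly `true_counts[g]` fragments
uniformly per genome, with lengths normal(300, 50) truncated to
[read length, genome length], mate 2 reverse-complemented, substitution
errors i.i.d. (default 0.002, off for error-free scenarios), names carrying
`genome|index` provenance, and global shuffling. Everything is deterministic
given the seed.

What this emulates: the multi-mapping-island regime, absent genomes in the
index, paired-end geometry, and substitution noise. What it does not:
indels and platform-specific error profiles, quality-score structure, GC and
strand biases, real strain phylogenies (island members are star-shaped
around a base sequence), plasmids/repeats, and host contamination. Passing
the recovery tests therefore demonstrates the *inference machinery* —
disambiguation, sparsification, mass preservation — not robustness to every
artifact of real libraries.

The recovery benchmark uses 30 genomes of 10 kb, three 3-member islands at
identity 0.995 with one member of each present, and 50,000 error-free read
pairs with lognormal(0, 1) relative abundances — sizes chosen so a complete
simulate→map→quantify cycle stays comfortable on a laptop-class single CPU
while leaving every island member with enough reads for a meaningful 5%
recovery check.

## Taxonomy

`nodes.dmp`/`names.dmp` are parsed in the NCBI dump dialect ("\t|\t"
separators, "\t|" terminators); only "scientific name" rows are used; the
root is the self-parent node. Cycles fail at load; parent chains that leave
the database fail at lineage time, naming the node. Aggregation groups each
reference's count under its first ancestor (including itself) at the
requested rank; references lacking that rank go to a reserved
"no-rank-at-level" row and references missing from the taxid map to
"unmapped-taxonomy", so the output total equals the input total exactly —
mass preservation is the module's contract, mirroring the engine's.
`merged.dmp`/`delnodes.dmp` are deliberately not consulted; the nodes/names
pair is the single source of truth.

## Evaluation metrics

MSLE = (1/N) Σ (log(y_i+1) − log(ŷ_i+1))², natural log by default (base is
a parameter; only relative comparisons depend on it). Filtering variants:
both-zero removal, and read-threshold removal where taxon i is dropped when
max(y_i, ŷ_i) < t — a taxon is removed only when small in *both* vectors,
which matches removing it "from both vectors"; `estimated` and `either`
rules are available since the governing vector is a protocol choice. N
always updates to the surviving length, and an empty survivor set is an
error, not a zero. False positives at threshold t count taxa with y_i = 0
and ŷ_i > t (strict), so t = 0 counts every falsely reported taxon with at
least one read. Concordance outer-joins two rank tables on taxid, removes
taxa zero in both, and computes Spearman's ρ with average ranks via
scipy; at least 3 survivors are required.

## Interface notes

The engine is exposed statsmodels-style: `CedarModel(collection, options)`
with `fit()` returning `CedarResults` (estimates, removal log, fit trace,
`summary()`, `frame()`), and the individual algorithm steps are importable
functions for testing and reuse. The `cedarquant` CLI wraps the library
thinly; a flat key=value config file can pre-set options (flags win), all
randomness flows from explicit `--seed`s, and outputs are version-stamped
and written atomically. Mapping is single-process: fragments are
independent, so parallelism is possible in principle, but determinism and
the intended problem sizes make a single process the right default
(`--threads` is accepted for interface stability).

## Known limitations

- Fragment-length distributions, GC/sequence bias, and base-quality signals
  are not modeled (the last deliberately — it did not help abundance
  accuracy in this model family).
- The coverage prior needs positional information; text-table inputs run
  with the pure-θ prior.
- Greedy set-cover is an approximation; the tests assert validity and
  agreement with an independent greedy trace, not minimality.
- High-abundance identical references are reported as a symmetric split (see
  above); disambiguating them is out of scope by design.
- Taxonomy merged/deleted nodes are not resolved.
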