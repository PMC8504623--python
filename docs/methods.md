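# Methods

## Model overview and assumptions

spacerlink treats phage–host prediction as a protein-level homology
problem. The core assumptions are:

- Phage genomes are dense in coding sequence, so a protospacer almost
  always overlaps a gene, and a six-frame scan of both spacers and
  phage genomes recovers the homologous peptide pair without gene
  calling. "Putative coding fragment" is defined as a maximal stop-free
  codon run of at least 27 nt (9 aa); no start codon is required,
  because spacers are arbitrary sub-gene fragments and an ATG
  requirement would discard nearly all true protospacers.
- Escape mutations are biased toward synonymous changes, so the
  peptide-level signal outlives the nucleotide-level signal. The
  nucleotide re-alignment step exists to *recognize* (and prioritize)
  still-near-perfect matches, not to gate detection.
- Evidence is combined across spacers: several independent weak-to-
  moderate hits between one host and one phage are jointly far more
  informative than their best single hit.
- Significance is calibrated empirically. No analytic null for the
  combined score is assumed; a decoy database processed with identical
  parameters provides the null score distribution.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `min_nt` | 27 nt | minimum coding-fragment length (9 aa) |
| translation table | 11 | NCBI genetic code, settable per input side |
| prefilter pattern | `10111011` | spaced 6-mer seed; the two `0`s tolerate mismatches |
| matrix | PAM40 | log-odds matrix for short evolutionary distances |
| gap open / extend | 16 / 2 | affine gap costs (length-g gap costs 16 + (g−1)·2) |
| near-perfect rule | ≤ 2 mismatches, ≥ 95% coverage | classic strict nucleotide-match criterion |
| near-perfect P floor | 1e-10 | makes near-perfect hits dominate protein-only hits |
| `tau` | 0.1 | truncation threshold of the p-value product |
| `fdr` | 0.05 | retention threshold on the estimated FDR |
| null decoys/target | 8 | 1 inverted + 7 shuffled decoys per target genome |
| LCA support | 0.5 | strict-majority weight fraction |
| LCA vote weight | clip(−log10 S_comb, 1, 20) | confident matches vote more |
| PAM window | 10 nt | flank scanned on each side, both strands |

The substitution matrix deserves a note: the published matrix family
tuned for short, highly similar peptides at ~40 PAM distance is the
natural choice here, and the bundled default is the PAM40 log-odds
matrix at that same evolutionary distance. Any NCBI-format matrix file
(e.g. VTML40) can be supplied with `--matrix`, together with Gumbel
parameters calibrated for it.

## Per-hit P-values

Local alignment scores of unrelated sequences follow a Gumbel law,
`P(S ≥ s) = 1 − exp(−K·m·n·e^(−λs))`. (λ, K) are fitted once by
aligning 100,000 random i.i.d. fragment pairs drawn from the operating
regime (query lengths 9–14 aa, target lengths 50–300 aa, uniform
residue composition) and maximizing a tail-censored likelihood: scores
at or below the 90th percentile contribute through the CDF only, so
the fit is governed by the tail that P-values actually use; a 0.5
continuity correction is applied to the integer scores. The fitted
values, the seed, and the regime are shipped in
`src/spacerlink/data/gumbel_params.json` and can be regenerated with
`scripts/calibrate_gumbel.py`. At very short query lengths the m·n
length scaling is only approximate (edge effects); the calibration is
validated against independent Monte-Carlo simulation at the 12 aa ×
100 aa operating point in the test suite.

## Evidence combination and FDR

Per spacer and target set, only the best fragment hit is kept and
corrected for the number of fragments tried:
`p_bh = 1 − (1 − p_min)^(n_T)` (minimum order statistic under
independence, computed in log space). Per host–phage pair, best-hit
P-values are combined with a truncated product,
`S_comb = τ·Π_{p≤τ}(p/τ)`; if no p-value reaches τ the smallest one is
used, so a single weak hit still yields a score. S_comb is used only
ordinally (ranking plus empirical calibration), so any strictly
monotone variant of the combination would give identical retained
sets.

The null database is built from the targets themselves: the
character-reversed sequence (reversal destroys codon structure and
homology while preserving composition — reverse-complementing would
leave real ORFs readable on the opposite strand) plus seven seeded
mononucleotide shuffles per target. The extra shuffled decoys exist
because the FDR estimate is a discrete count: with a same-size null
database a handful of null scores per run gives the estimator too
little resolution, and a chance match that happens to beat every null
score would be retained with estimated FDR 0. Eight decoys per target
keep that event rare while staying cheap; `size_ratio`
(real targets / null targets) rescales the counts exactly. At each
cutoff c (the k-th smallest real score),
`FDR_raw(k) = min(1, size_ratio·#{null ≤ c}/k)`, monotonized by a
running minimum from the weakest cutoff downward (q-value convention).
The empirical P-value uses add-one smoothing,
`(1 + #{null ≤ s})/(1 + n_null_pairs)`, with the denominator counting
*all* evaluated query-set/null-target pairs including hitless ones, so
results are reproducible bit for bit.

## Weighted LCA

Votes are accumulated up the taxonomy; the assignment is the deepest
node whose subtree weight strictly exceeds the support threshold times
the total weight. The strict majority makes equal-weight sibling
species resolve to their parent rather than to an arbitrary sibling;
when no node strictly exceeds the threshold (e.g. threshold 1.0 with a
single lineage), nodes reaching it exactly are allowed, and remaining
ties break toward greater depth and then smaller taxid.

## Synthetic data: what it emulates, and what it does not

The generator produces phage genomes as alternating stop-free codon
blocks (~80% coding by default, 3 kb) and random intergenic gaps;
spacers of 28–42 nt are codon-aligned copies of coding regions,
mutated with k synonymous single-nucleotide codon changes (protein
preserved; codons are chosen among those with a Hamming-1 synonym so
the truth table records exact mismatch counts) and j amino-acid
substitutions, emitted on a random strand, with an optional concrete
PAM instance written adjacent to the protospacer in protospacer
orientation. Decoy hosts carry uniform random spacers; decoy phages
receive no planted spacers. A small taxonomy (species per host/phage
under per-triplet genera) accompanies the bundle.

This emulates the signal structure the method exploits — coding
density, synonymous-biased divergence, multi-spacer evidence, PAM
flanks — but not real-data nuisances: uneven GC and codon usage,
repeat-rich arrays, mosaic phages, partially overlapping spacers, or
detector-specific extraction errors. Passing tests therefore
demonstrate correctness of the algorithms and calibration of the
statistics under the modeled conditions, not field performance on
real metagenomes.

Benchmark runs in the tests and the acceptance script use 15 host
genomes (5 with planted spacers, 10 decoys) against 15 phage genomes
of 3 kb each, 20 replicates; these sizes keep every fragment-level
quantity exercised (hundreds of target fragments per set) while a full
run completes in seconds.

## Numerical choices and degenerate inputs

- All P-values and scores are clamped to [1e-300, 1] so logs never
  overflow and S_comb stays strictly positive.
- Alignment tie-breaks are deterministic: among co-optimal local
  alignments, the smallest query start wins, then the smallest target
  start (implemented by a reversed-sequence DP followed by a forward
  re-extension from the fixed start).
- Sequences are upper-cased on read, U→T; IUPAC ambiguity codes are
  kept and score as mismatches; codons containing them translate to X
  (which scores via the matrix's X column and never terminates a
  coding run — stops, not ambiguity, delimit fragments).
- A spacer too short to translate yields an empty query set and a
  warning; a run in which *no* spacer translates is an input error
  (exit code 2). Empty result sets are a success (exit 0, empty
  report).
- The nucleotide re-alignment window is clipped at genome ends;
  coverage is computed on the clipped part, so boundary protospacers
  are never flagged near-perfect spuriously.
- Coordinates are 0-based half-open internally and 1-based inclusive
  in reports; report floats are printed with three significant digits.

## Known limitations

- The search is a correctness-first reimplementation (exhaustive
  spaced-k-mer candidate generation plus exact Smith–Waterman), not a
  high-throughput cascade; it is meant for data-set sizes where an
  all-vs-all fragment comparison is tractable.
- The Gumbel calibration assumes uniform residue composition; strongly
  biased proteomes shift (λ, K) and would need recalibration.
- The per-fragment independence behind the best-hit order statistic is
  approximate: fragments from overlapping frames of the same spacer
  are correlated.
- PAM annotations are reported, never used for scoring; the bundled
  catalog is intentionally small and user-editable.
- GenBank downloading, gzip transport and parallel execution are out
  of scope.
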