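# spacerlink

Prediction of phage–host relationships from CRISPR spacers, at the
protein level.

Prokaryotes that survive a phage infection store a short fragment of
the invader's genome (a *spacer*, typically 28–42 nt) in a CRISPR
array. Matching those spacers back against phage genomes is a direct
way to link phages to their hosts — but classic nucleotide matching
(BLASTN-style, allowing at most ~2 mismatches) only finds nearly
identical protospacers, and phage databases rarely contain a close
relative of the phage that actually infected the host. Because phage
genomes are mostly coding, and because escape mutations are biased
toward synonymous changes, comparing spacers and phages **as
translated peptides** recovers matches that nucleotide identity has
already lost.

## Method

For every prokaryotic genome, the spacer set is translated in six
frames; every stop-free codon run of ≥ 27 nt becomes a query fragment
*q* (a query set *Q* per host genome). Phage genomes are processed
identically into target sets *T* of fragments *t*. Then:

1. **Search** — candidate *q–t* pairs must share a spaced 6-mer
   (pattern `10111011`); candidates are aligned with affine-gap
   Smith–Waterman (gap open 16, extend 2) under a short-distance
   log-odds matrix (PAM40; any NCBI-format matrix such as VTML40 can be
   supplied). Every protein hit is re-aligned at the nucleotide level;
   *near-perfect* hits (≤ 2 mismatches, ≥ 95% spacer coverage) get
   their P-value floored at 1e-10 so they dominate downstream.
   Per-hit significance is a Karlin–Altschul/Gumbel tail
   `p = 1 − exp(−K·m·n·e^(−λ·s))` with (λ, K) calibrated by simulation.
2. **Best hit** — per spacer and target set, the order-1 statistic
   `p_bh = 1 − (1 − p_min)^(n_T)`.
3. **Combination** — best-hit P-values of all spacers supporting one
   *Q–T* pair are combined with a truncated product:
   `S_comb = τ · Π_{p ≤ τ} (p/τ)` (τ = 0.1); smaller is stronger.
4. **FDR** — the identical pipeline runs against a null database
   (character-reversed genomes plus seeded composition-preserving
   shuffles); at each score cutoff the false discovery rate is
   estimated from the null match counts and matches are retained at
   FDR < 0.05.
5. **PAM** — 10 nt on each side of every accepted protospacer are
   scanned against a small IUPAC motif catalog, on both strands.

With taxonomic labels, hosts per phage (and phages per spacer) are
summarized by a weighted lowest common ancestor: the deepest taxon
whose subtree carries a strict majority of −log10(S_comb) vote weight.

## Worked example

Generate a small synthetic data set (two hosts carrying spacers
planted from two phages with two synonymous mutations each, one decoy
host, one decoy phage) and run the pipeline:

```sh
python - <<'EOF'
from spacerlink import make_benchmark
b = make_benchmark(n_hosts=2, n_phages=3, decoy_hosts=1, seed=4,
                   mutation_model={"aa_conserving_nt_subs": 2, "aa_subs": 0})
b.write("demo")
EOF
spacerlink predict demo/spacers/*.fasta \
    --phages demo/phages/phage_0.fasta --phages demo/phages/phage_1.fasta \
    --phages demo/phages/phage_2.fasta \
    --labels demo/labels.tsv --taxdump demo/tree.tsv --out-dir demo/out
```

`demo/out/matches.tsv` then contains exactly the two planted pairs:

```
#host_0	phage_0	5.67e-29	4
host0_ph0_sp0	phage_0	1.49e-08	1	41	2835	2875	3'NGG	3'NGG
host0_ph0_sp1	phage_0	1.56e-08	1	35	1720	1754	3'NGG	3'NGG
host0_ph0_sp2	phage_0	1.56e-08	1	35	1107	1141	3'NGG	-
host0_ph0_sp3	phage_0	1.56e-08	1	28	2280	2307	3'NGG	-
#host_1	phage_1	6.89e-29	4
...
```

Each `#` line is one accepted host–phage match: prokaryote accession,
phage accession, combined score S_comb, number of contributing hits.
The four spacers of `host_0` each hit `phage_0` with best-hit P-value
~1.6e-08 (1-based spacer and phage coordinates follow), the planted
`NGG` PAM is recovered 3' of every protospacer, and the truncated
product concentrates the four P-values into S_comb ≈ 5.7e-29 — far
below every null score, hence FDR 0. The decoy host and decoy phage
are absent. `demo/out/host_lca.tsv` assigns each phage its true host
species with support 1.000, and `manifest.json` records all stage
counts and parameters.

Spacer inputs can also be raw CRISPR-detector reports
(`spacerlink parsespacers --dialect crt|minced|pilercr|crisprdetect ...`),
and `spacerlink makenull` materializes the inverted null database for
inspection.

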