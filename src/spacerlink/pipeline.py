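"""End-to-end orchestration: preprocess, search, combine, FDR, PAM, report.

The null model database defaults to character-reversed phage genomes
(reversal destroys codon structure and homology while preserving
composition; reverse-complementing would keep real ORFs readable on the
opposite strand).  The null side is processed with exactly the same
parameters as the real side.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import io as sio
from .io import GenomeRecord
from .pam import default_catalog, format_pam, load_catalog, scan_pam
from .preprocess import build_sets
from .scoring import ScoringScheme
from .search import search_pair
from .stats import (
    DEFAULT_FDR,
    DEFAULT_TAU,
    PairMatch,
    empirical_pvalue,
    estimate_fdr,
    summarize_pair,
)
from .taxonomy import build_reports

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT_ERROR = 2


@dataclass
class PipelineParams:
    """All tunable thresholds of a prediction run."""

    min_nt: int = 27
    query_table: int = 11
    target_table: int = 11
    tau: float = DEFAULT_TAU
    fdr: float = DEFAULT_FDR
    support_threshold: float = 0.5
    uniform_lca_weights: bool = False
    include_alignments: bool = False
    null_decoys_per_target: int = 8
    pam_catalog_path: str | None = None
    matrix_path: str | None = None
    gumbel_lambda: float = 0.0
    gumbel_K: float = 0.0
    seed: int = 0


@dataclass
class PredictionResult:
    matches: list[PairMatch] = field(default_factory=list)  # sorted by s_comb
    retained: list[PairMatch] = field(default_factory=list)
    null_scores: list[float] = field(default_factory=list)
    n_null_pairs: int = 0
    counts: dict = field(default_factory=dict)


def invert_genome(genome: GenomeRecord) -> GenomeRecord:
    """Null-model genome: character-reversed sequence (not complemented)."""
    return GenomeRecord(
        accession=genome.accession + "|null",
        sequence=genome.sequence[::-1],
        kind="null_target",
    )


def make_null_genomes(
    phages: list[GenomeRecord], decoys_per_target: int = 8, seed: int = 0
) -> list[GenomeRecord]:
    """Default null database: per target, the inverted sequence plus
    seeded composition-preserving shuffles.

    Reversal destroys codon structure and homology while keeping
    composition; the extra shuffled decoys enlarge the null score sample
    so the empirical FDR has enough resolution on small target sets
    (``size_ratio`` in the FDR estimate rescales for the size).
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    nulls: list[GenomeRecord] = []
    for g in phages:
        nulls.append(invert_genome(g))
        for i in range(1, decoys_per_target):
            arr = np.frombuffer(g.sequence.encode("ascii"), dtype=np.uint8).copy()
            rng.shuffle(arr)
            nulls.append(
                GenomeRecord(
                    accession=f"{g.accession}|null{i}",
                    sequence=arr.tobytes().decode("ascii"),
                    kind="null_target",
                )
            )
    return nulls


def make_scheme(params: PipelineParams) -> ScoringScheme:
    if params.matrix_path:
        return ScoringScheme.from_file(
            params.matrix_path, params.gumbel_lambda, params.gumbel_K
        )
    return ScoringScheme()


def _search_side(queries, targets, genomes_by_acc, spacers_by_acc, scheme, tau):
    """All pair matches (with hits) of query sets against target sets.

    Target k-mer indexes and query k-mer sets are built once and reused
    across all set pairs.
    """
    from .search import build_target_index, spaced_kmers

    offsets = scheme.pattern_offsets
    span = len(scheme.kmer_pattern)
    query_kmers = {
        Q.set_id: [spaced_kmers(f.aa_sequence, offsets, span) for f in Q.fragments]
        for Q in queries
    }
    matches = []
    n_hits = 0
    for T in targets:
        if not T.fragments:
            continue
        index = build_target_index(T, scheme)
        genome = genomes_by_acc[T.set_id]
        for Q in queries:
            if not Q.fragments:
                continue
            hits = search_pair(
                Q, T, scheme, spacers_by_acc, genome,
                index=index, query_kmers=query_kmers[Q.set_id],
            )
            n_hits += len(hits)
            if not hits:
                continue
            by_spacer: dict[str, list] = {}
            for h in hits:
                by_spacer.setdefault(h.query_fragment.parent_accession, []).append(h)
            matches.append(
                summarize_pair(by_spacer, T.n_fragments, Q.set_id, T.set_id, tau=tau)
            )
    return matches, n_hits


def run_analysis(
    spacers_by_genome: dict,
    phage_genomes: list[GenomeRecord],
    null_genomes: list[GenomeRecord] | None = None,
    params: PipelineParams | None = None,
    scheme: ScoringScheme | None = None,
) -> PredictionResult:
    """In-memory prediction pipeline (the CLI wraps file I/O around this)."""
    params = params or PipelineParams()
    scheme = scheme or make_scheme(params)
    if null_genomes is None:
        null_genomes = make_null_genomes(
            phage_genomes, params.null_decoys_per_target, params.seed
        )

    queries, targets = build_sets(
        spacers_by_genome, phage_genomes, params.min_nt, params.query_table, params.target_table
    )
    _, null_targets = build_sets(
        spacers_by_genome, null_genomes, params.min_nt, params.query_table, params.target_table
    )
    spacers_by_acc = {
        sp.accession: sp for spl in spacers_by_genome.values() for sp in spl
    }
    genomes_by_acc = {g.accession: g for g in phage_genomes + null_genomes}

    real_matches, n_hits = _search_side(
        queries, targets, genomes_by_acc, spacers_by_acc, scheme, params.tau
    )
    null_matches, n_null_hits = _search_side(
        queries, null_targets, genomes_by_acc, spacers_by_acc, scheme, params.tau
    )

    n_query_sets = sum(1 for q in queries if q.fragments)
    n_null_pairs = n_query_sets * len(null_targets)
    null_scores = sorted(m.s_comb for m in null_matches)

    for m in real_matches:
        m.empirical_p = empirical_pvalue(m.s_comb, null_scores, n_null_pairs)
    size_ratio = len(targets) / len(null_targets) if null_targets else 1.0
    ordered = estimate_fdr(real_matches, null_scores, size_ratio, threshold=params.fdr)
    retained = [m for m in ordered if m.retained]

    catalog = (
        load_catalog(params.pam_catalog_path)
        if params.pam_catalog_path
        else default_catalog()
    )
    for m in retained:
        genome = genomes_by_acc[m.target_set_id]
        for bh in m.best_hits:
            h = bh.hit
            if h.proto_end > h.proto_start:
                res = scan_pam(genome, h.proto_start, h.proto_end, h.proto_strand, catalog)
                h.pam_fwd = format_pam(res.matched_motif_fwd, res.motif_side)
                h.pam_rev = format_pam(res.matched_motif_rev, res.motif_side_rev)

    counts = {
        "spacers": sum(len(v) for v in spacers_by_genome.values()),
        "query_sets": len(queries),
        "query_fragments": sum(q.n_fragments for q in queries),
        "target_sets": len(targets),
        "target_fragments": sum(t.n_fragments for t in targets),
        "null_target_sets": len(null_targets),
        "hits": n_hits,
        "null_hits": n_null_hits,
        "matches_before_fdr": len(real_matches),
        "matches_after_fdr": len(retained),
        "null_matches": len(null_matches),
    }
    return PredictionResult(
        matches=ordered,
        retained=retained,
        null_scores=null_scores,
        n_null_pairs=n_null_pairs,
        counts=counts,
    )


def run_predict(
    spacer_inputs: list,
    phage_inputs: list,
    out_dir,
    null_inputs: list | None = None,
    spacer_dialect: str = "fasta",
    labels: sio.TaxLabelTable | None = None,
    params: PipelineParams | None = None,
) -> int:
    """File-based pipeline: read inputs, run, write reports and manifest.

    Returns an exit code: 0 on success (including empty results), 2 on
    input errors.  Deterministic given identical inputs and parameters.
    """
    params = params or PipelineParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        spacers_by_genome: dict[str, list] = {}
        for path in spacer_inputs:
            if spacer_dialect == "fasta":
                recs = sio.read_spacer_fasta(path)
            else:
                recs = sio.read_crispr_tool_output(path, spacer_dialect)
            spacers_by_genome[recs[0].genome_id] = recs
        phages = [g for path in phage_inputs for g in sio.read_genome_fasta(path)]
        nulls = None
        if null_inputs:
            nulls = [
                g
                for path in null_inputs
                for g in sio.read_genome_fasta(path, kind="null_target")
            ]
        result = run_analysis(spacers_by_genome, phages, nulls, params)
    except (ValueError, OSError) as exc:
        logger.error("input error: %s", exc)
        return EXIT_INPUT_ERROR

    sio.write_match_report(
        result.retained, out_dir / "matches.tsv", include_alignments=params.include_alignments
    )
    if labels is not None and len(labels):
        host_rep, spacer_rep = build_reports(
            result.retained,
            labels,
            support_threshold=params.support_threshold,
            uniform_weights=params.uniform_lca_weights,
        )
        sio.write_lca_report(host_rep, out_dir / "host_lca.tsv")
        sio.write_lca_report(spacer_rep, out_dir / "phage_lca.tsv")

    manifest = {
        "params": asdict(params),
        "counts": result.counts,
        "n_null_pairs": result.n_null_pairs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    for stage, value in sorted(result.counts.items()):
        logger.info("%s: %s", stage, value)
    return EXIT_OK
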