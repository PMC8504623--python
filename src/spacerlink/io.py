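"""Readers and writers for spacer inputs, genomes, taxonomy and reports.

Spacers arrive either as FASTA (one file per prokaryotic genome) or as
plain-text reports from the CRISPR detectors PILER-CR, CRT, MinCED or
CRISPRDetect (MinCED output follows the CRT layout).  All sequences are
upper-cased on read, U is mapped to T, and IUPAC ambiguity codes are
kept (they score as mismatches downstream).

The match report is a '#'-prefixed two-tier TSV: one header line per
accepted host-phage match followed by one line per contributing hit.
Missing fields use the single-character sentinel "-".  Scores and
P-values are printed in scientific notation with three significant
digits, which makes reports byte-diffable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

IUPAC_DNA = set("ACGTNRYSWKMBDHV")
MISSING = "-"

SOURCE_TOOLS = ("fasta", "pilercr", "crt", "minced", "crisprdetect")


@dataclass(frozen=True)
class SpacerRecord:
    """One CRISPR spacer from one prokaryotic genome."""

    accession: str
    genome_id: str
    sequence: str
    source_tool: str = "fasta"
    array_index: int = 0
    position_in_array: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"spacer {self.accession}: empty sequence")
        if self.source_tool not in SOURCE_TOOLS:
            raise ValueError(f"unknown source tool {self.source_tool!r}")


@dataclass(frozen=True)
class GenomeRecord:
    """One phage (or null-model) genome."""

    accession: str
    sequence: str
    kind: str = "phage_target"  # "phage_target" | "null_target"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"genome {self.accession}: empty sequence")
        if self.kind not in ("phage_target", "null_target"):
            raise ValueError(f"unknown genome kind {self.kind!r}")


def normalize_sequence(seq: str, name: str) -> str:
    """Upper-case, map U->T, reject non-IUPAC characters."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - IUPAC_DNA
    if bad:
        raise ValueError(
            f"record {name!r}: invalid sequence characters {''.join(sorted(bad))!r}"
        )
    return s


# ---------------------------------------------------------------------------
# spacer input


def read_spacer_fasta(path, genome_id: str | None = None) -> list[SpacerRecord]:
    """Read one FASTA of spacers belonging to a single prokaryotic genome.

    The header up to the first whitespace becomes the accession.  Raises
    on an empty file ("no spacers") and on duplicate accessions.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    records: list[SpacerRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        acc = rec.id
        if acc in seen:
            raise ValueError(f"{path}: duplicate spacer accession {acc!r}")
        seen.add(acc)
        records.append(
            SpacerRecord(
                accession=acc,
                genome_id=genome_id,
                sequence=normalize_sequence(str(rec.seq), acc),
                source_tool="fasta",
                array_index=0,
                position_in_array=i,
            )
        )
    if not records:
        raise ValueError(f"{path}: no spacers")
    return records


def _is_dna(token: str) -> bool:
    return bool(token) and not (set(token.upper()) - IUPAC_DNA)


def _parse_crt(lines: list[str]) -> list[tuple[int, str]]:
    """CRT / MinCED grammar: 'CRISPR n Range: a - b' sections with
    POSITION / REPEAT / SPACER rows; the last row of each array carries
    only the repeat."""
    spacers: list[tuple[int, str]] = []
    array = -1
    for ln in lines:
        s = ln.strip()
        if not s:
            continue
        if re.match(r"CRISPR\s+\d+", s):
            array += 1
            continue
        if s.startswith(("ORGANISM", "POSITION", "-", "Repeats:", "Time", "Sequence")):
            continue
        toks = s.split()
        if toks[0].isdigit():
            if array < 0:
                raise ValueError(f"unparseable line (data row before any array): {s!r}")
            dna = [t for t in toks[1:] if _is_dna(t)]
            if len(dna) >= 2:
                spacers.append((array, dna[1]))
            elif len(dna) == 1:
                continue  # trailing repeat-only row
            else:
                raise ValueError(f"unparseable line: {s!r}")
    if array < 0:
        raise ValueError(f"unrecognized CRT/MinCED layout; first line: {lines[0].strip()!r}")
    return spacers


def _parse_pilercr(lines: list[str]) -> list[tuple[int, str]]:
    """PILER-CR report: 'Array n' sections; data rows are
    pos / repeat-len / %id / spacer-len / [flank] / repeat / spacer,
    where the repeat may show '.' for consensus agreement."""
    spacers: list[tuple[int, str]] = []
    array = -1
    in_summary = False
    for ln in lines:
        s = ln.strip()
        if not s:
            continue
        if re.match(r"Array\s+\d+", s):
            array += 1
            in_summary = False
            continue
        if s.startswith("SUMMARY"):
            in_summary = True
            continue
        if in_summary or s.startswith((">", "Pos", "=")):
            continue
        toks = s.split()
        if toks[0].isdigit():
            if array < 0:
                raise ValueError(f"unparseable line (data row before any array): {s!r}")
            # spacer rows carry an integer spacer length in column 4
            if len(toks) >= 6 and toks[3].isdigit() and _is_dna(toks[-1]):
                spacers.append((array, toks[-1]))
            elif len(toks) >= 3:
                continue  # trailing repeat-only / consensus row
            else:
                raise ValueError(f"unparseable line: {s!r}")
    if array < 0:
        raise ValueError(f"unrecognized PILER-CR layout; first line: {lines[0].strip()!r}")
    return spacers


def _parse_crisprdetect(lines: list[str]) -> list[tuple[int, str]]:
    """CRISPRDetect report: 'Array n' blocks; tabular rows are
    position / repeat-len / %id / spacer-len / repeat / spacer / indel.
    Low-confidence annotations are ignored (all arrays are emitted)."""
    spacers: list[tuple[int, str]] = []
    array = -1
    for ln in lines:
        s = ln.strip()
        if not s:
            continue
        if re.match(r"(>?Array\s+\d+|Array\s+\d+)", s) and "Orientation" not in s:
            array += 1
            continue
        if s.startswith((">", "=", "Position", "#")):
            continue
        toks = s.split()
        if toks[0].lstrip("-").isdigit():
            if array < 0:
                raise ValueError(f"unparseable line (data row before any array): {s!r}")
            if len(toks) >= 6 and _is_dna(toks[5]):
                spacers.append((array, toks[5]))
            elif len(toks) >= 5:
                continue  # last row: spacer column is '|' or absent
            else:
                raise ValueError(f"unparseable line: {s!r}")
    if array < 0:
        raise ValueError(
            f"unrecognized CRISPRDetect layout; first line: {lines[0].strip()!r}"
        )
    return spacers


_DIALECTS = {
    "crt": _parse_crt,
    "minced": _parse_crt,  # MinCED is a CRT re-implementation
    "pilercr": _parse_pilercr,
    "crisprdetect": _parse_crisprdetect,
}


def read_crispr_tool_output(path, dialect: str, genome_id: str | None = None) -> list[SpacerRecord]:
    """Extract all spacers (repeats discarded) from a detector report.

    All arrays are emitted regardless of any confidence annotation;
    filtering on confidence is the caller's concern.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    lines = path.read_text().splitlines()
    if not any(ln.strip() for ln in lines):
        raise ValueError(f"{path}: no spacers")
    pairs = _DIALECTS[dialect](lines)
    if not pairs:
        raise ValueError(f"{path}: no spacers")
    records: list[SpacerRecord] = []
    pos_in_array: dict[int, int] = {}
    for array, seq in pairs:
        k = pos_in_array.get(array, 0)
        pos_in_array[array] = k + 1
        acc = f"{genome_id}_arr{array}_sp{k}"
        records.append(
            SpacerRecord(
                accession=acc,
                genome_id=genome_id,
                sequence=normalize_sequence(seq, acc),
                source_tool=dialect,
                array_index=array,
                position_in_array=k,
            )
        )
    return records


# ---------------------------------------------------------------------------
# genomes


def read_genome_fasta(path, kind: str = "phage_target") -> list[GenomeRecord]:
    """Read genome FASTA; one record per entry, duplicates rejected."""
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate genome accession {rec.id!r}")
        seen.add(rec.id)
        records.append(
            GenomeRecord(
                accession=rec.id,
                sequence=normalize_sequence(str(rec.seq), rec.id),
                kind=kind,
            )
        )
    if not records:
        raise ValueError(f"{path}: empty genome FASTA")
    return records


def write_spacer_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# match report


def format_float(x: float) -> str:
    """Three significant digits, scientific notation."""
    return f"{x:.2e}"


def write_match_report(matches, path, include_alignments: bool = False) -> None:
    """Write the two-tier TSV match report.

    Per match: a header line
    ``#<prokaryote>\\t<phage>\\t<S_comb>\\t<n hits>`` followed by one line
    per hit with columns: spacer accession, phage accession, p_bh,
    spacer start, spacer end, phage start, phage end, possible
    5'/3' PAM, possible 5'/3' PAM on the reverse strand.  Coordinates
    are 1-based inclusive; missing PAMs are "-".  An empty match list
    yields an empty file.
    """
    with open(path, "w") as fh:
        for match in matches:
            fh.write(
                f"#{match.query_set_id}\t{match.target_set_id}\t"
                f"{format_float(match.s_comb)}\t{len(match.best_hits)}\n"
            )
            for bh in match.best_hits:
                hit = bh.hit
                fh.write(
                    "\t".join(
                        [
                            bh.spacer_accession,
                            match.target_set_id,
                            format_float(bh.p_bh),
                            str(hit.spacer_start + 1),
                            str(hit.spacer_end),
                            str(hit.proto_start + 1),
                            str(hit.proto_end),
                            hit.pam_fwd or MISSING,
                            hit.pam_rev or MISSING,
                        ]
                    )
                    + "\n"
                )
                if include_alignments:
                    fh.write(f";spacer\t{hit.aln_spacer_seq or MISSING}\n")
                    fh.write(f";phage\t{hit.aln_target_seq or MISSING}\n")


def read_match_report(path):
    """Parse a match report back into plain dicts (round-trip checking)."""
    matches = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith(";"):
                continue
            if ln.startswith("#"):
                prok, phage, s_comb, n_hits = ln[1:].split("\t")
                matches.append(
                    {
                        "query_set_id": prok,
                        "target_set_id": phage,
                        "s_comb": float(s_comb),
                        "n_hits": int(n_hits),
                        "hits": [],
                    }
                )
            else:
                f = ln.split("\t")
                matches[-1]["hits"].append(
                    {
                        "spacer_accession": f[0],
                        "target_accession": f[1],
                        "p_bh": float(f[2]),
                        "spacer_start": int(f[3]),
                        "spacer_end": int(f[4]),
                        "phage_start": int(f[5]),
                        "phage_end": int(f[6]),
                        "pam_fwd": f[7],
                        "pam_rev": f[8],
                    }
                )
    return matches


# ---------------------------------------------------------------------------
# taxonomy


@dataclass
class TaxLabelTable:
    """Accession -> taxid mapping plus the taxonomy tree it refers to."""

    mapping: dict = field(default_factory=dict)
    taxonomy: object = None

    def __len__(self) -> int:
        return len(self.mapping)


def read_tax_labels(mapping_path, taxdump_path) -> TaxLabelTable:
    """Read a 2-column accession->taxid TSV and a taxonomy tree.

    ``taxdump_path`` may be a directory with NCBI-style ``nodes.dmp`` /
    ``names.dmp`` or a 4-column TSV (taxid, parent, rank, name).  Every
    mapped taxid must exist in the tree.  An empty mapping produces an
    empty table (LCA reporting is later skipped with a warning).
    """
    from .taxonomy import Taxonomy

    taxdump_path = Path(taxdump_path)
    if taxdump_path.is_dir():
        tax = Taxonomy.from_taxdump(taxdump_path)
    else:
        tax = Taxonomy.from_tsv(taxdump_path)

    mapping: dict[str, int] = {}
    for ln in Path(mapping_path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        acc, taxid = ln.split("\t")[:2]
        mapping[acc] = int(taxid)
    missing = sorted({t for t in mapping.values() if t not in tax})
    if missing:
        raise ValueError(f"taxids missing from taxonomy tree: {missing}")
    if not mapping:
        logger.warning("empty taxonomic label mapping; LCA reports will be skipped")
    return TaxLabelTable(mapping=mapping, taxonomy=tax)


def write_lca_report(assignments, path) -> None:
    """One row per subject: accession, LCA taxid, rank, name, support, votes."""
    with open(path, "w") as fh:
        fh.write("#subject\tlca_taxid\trank\tname\tsupport\tn_votes\n")
        for a in assignments:
            fh.write(
                f"{a.subject_accession}\t{a.lca_taxid}\t{a.lca_rank}\t"
                f"{a.lca_name}\t{a.support:.3f}\t{a.n_votes}\n"
            )
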