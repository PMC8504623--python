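"""Synthetic phage/host fixtures with known ground truth.

The generator emulates the study conditions this tool targets: phage
genomes that are mostly coding (stop-free stretches of random codons
interleaved with short non-coding gaps), host spacer sets of 28-42 nt
copied from those coding regions, optional planted PAM flanks, decoy
hosts and phages, and a small taxonomy.  The mutation model mirrors the
selective pressure on real protospacers: ``aa_conserving_nt_subs`` (k)
synonymous single-nucleotide codon changes that leave the encoded
protein untouched, plus ``aa_subs`` (j) amino-acid-changing codon
replacements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import GenomeRecord, SpacerRecord, TaxLabelTable, write_spacer_fasta
from .pam import IUPAC
from .preprocess import codon_map, revcomp
from .taxonomy import Taxonomy

DEFAULT_PHAGE_LENGTH = 3000
DEFAULT_CODING_FRACTION = 0.8
DEFAULT_SPACER_LEN = (28, 42)
DEFAULT_SPACERS_PER_PAIR = 4
DEFAULT_DECOY_SPACERS = 6
DEFAULT_PAM = ("NGG", "3prime")

_NT = "ACGT"


def _codon_tables(table: int = 11):
    cmap = codon_map(table)
    coding = [c for c, aa in cmap.items() if aa != "*"]
    by_aa: dict[str, list[str]] = {}
    for c in coding:
        by_aa.setdefault(cmap[c], []).append(c)
    return cmap, coding, by_aa


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def make_phage(
    length: int,
    coding_fraction: float = DEFAULT_CODING_FRACTION,
    seed: int = 0,
    accession: str = "phage",
    table: int = 11,
) -> tuple[GenomeRecord, list[dict]]:
    """Random phage genome with planned stop-free coding regions.

    Returns the genome and a plan: a list of ``{"start", "end",
    "strand"}`` coding regions (forward strand, codon-aligned, no
    in-frame stops) for later planting and audit.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    _, coding, _ = _codon_tables(table)
    chunks: list[str] = []
    plan: list[dict] = []
    pos = 0
    coded = 0
    while pos < length:
        want_coding = coded <= coding_fraction * max(pos, 1)
        if want_coding:
            block = 3 * int(rng.integers(100, 220))
            block = min(block, (length - pos) // 3 * 3)
            if block >= 27:
                idx = rng.integers(0, len(coding), size=block // 3)
                chunks.append("".join(coding[i] for i in idx))
                plan.append({"start": pos, "end": pos + block, "strand": "+"})
                coded += block
                pos += block
                continue
        gap = min(length - pos, int(rng.integers(30, 120)))
        chunks.append("".join(_NT[i] for i in rng.integers(0, 4, size=gap)))
        pos += gap
    sequence = "".join(chunks)[:length]
    if not plan:
        raise ValueError("genome too short to hold a coding region")
    return GenomeRecord(accession=accession, sequence=sequence), plan


def _instantiate_pam(pattern: str, rng) -> str:
    """One concrete realization of an IUPAC motif."""
    return "".join(IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in pattern)


def plant_protospacers(
    genome: GenomeRecord,
    plan: list[dict],
    n_spacers: int,
    spacer_len=DEFAULT_SPACER_LEN,
    mutation_model: dict | None = None,
    pam_motif: tuple[str, str] | None = None,
    seed: int = 0,
    genome_id: str = "host",
    spacer_prefix: str = "sp",
    table: int = 11,
) -> tuple[list[SpacerRecord], list[dict], GenomeRecord]:
    """Copy protospacers out of planned coding regions into spacers.

    Each spacer is a codon-aligned window of ``spacer_len`` nt from a
    coding region, mutated with k synonymous single-nucleotide codon
    changes and j amino-acid substitutions, and emitted on a random
    strand.  If ``pam_motif = (iupac, side)`` is given, a concrete
    instance is written into the genome adjacent to the protospacer (in
    protospacer orientation).  Returns (spacers, truth table, genome
    with PAMs written); the truth table records coordinates, strand and
    exact planned mismatch counts.
    """
    mm = {"aa_conserving_nt_subs": 0, "aa_subs": 0, **(mutation_model or {})}
    k, j = mm["aa_conserving_nt_subs"], mm["aa_subs"]
    rng = np.random.default_rng(seed)
    cmap, coding, by_aa = _codon_tables(table)
    gseq = list(genome.sequence)
    used: list[tuple[int, int]] = []
    spacers: list[SpacerRecord] = []
    truth: list[dict] = []
    pam_len = len(pam_motif[0]) if pam_motif else 0

    for si in range(n_spacers):
        slen = (
            int(rng.integers(spacer_len[0], spacer_len[1] + 1))
            if isinstance(spacer_len, tuple)
            else int(spacer_len)
        )
        # find a codon-aligned, non-overlapping window inside a coding region
        for _ in range(200):
            region = plan[rng.integers(0, len(plan))]
            n_codons = (region["end"] - region["start"]) // 3
            max_c = n_codons - slen // 3 - 3
            if max_c < 2:
                continue
            c = int(rng.integers(2, max_c))
            start = region["start"] + 3 * c
            end = start + slen
            lo, hi = start - pam_len - 1, end + pam_len + 1
            if all(hi <= a or lo >= b for a, b in used):
                break
        else:
            raise ValueError("could not place protospacer; genome too small")
        used.append((lo, hi))

        window = list("".join(gseq[start:end]))
        n_full = slen // 3  # codons fully inside the window
        mutated_nt = 0

        # synonymous changes: pick codons having a synonym at Hamming 1
        syn_ok = [
            ci
            for ci in range(n_full)
            if any(
                _hamming(c2, "".join(window[3 * ci : 3 * ci + 3])) == 1
                for c2 in by_aa[cmap["".join(window[3 * ci : 3 * ci + 3])]]
            )
        ]
        if k > len(syn_ok):
            raise ValueError("not enough codons for requested synonymous changes")
        chosen_syn = list(rng.choice(syn_ok, size=k, replace=False)) if k else []
        for ci in chosen_syn:
            codon = "".join(window[3 * ci : 3 * ci + 3])
            options = [c2 for c2 in by_aa[cmap[codon]] if _hamming(c2, codon) == 1]
            new = options[rng.integers(0, len(options))]
            window[3 * ci : 3 * ci + 3] = list(new)
            mutated_nt += 1

        # amino-acid substitutions on other codons
        other = [ci for ci in range(n_full) if ci not in chosen_syn]
        if j > len(other):
            raise ValueError("not enough codons for requested aa substitutions")
        chosen_aa = list(rng.choice(other, size=j, replace=False)) if j else []
        for ci in chosen_aa:
            codon = "".join(window[3 * ci : 3 * ci + 3])
            options = [c2 for c2 in coding if cmap[c2] != cmap[codon]]
            new = options[rng.integers(0, len(options))]
            window[3 * ci : 3 * ci + 3] = list(new)
            mutated_nt += _hamming(new, codon)

        strand = "+" if rng.integers(0, 2) == 0 else "-"
        spacer_seq = "".join(window)
        if strand == "-":
            spacer_seq = revcomp(spacer_seq)

        if pam_motif:
            pattern, side = pam_motif
            inst = _instantiate_pam(pattern, rng)
            # in protospacer orientation; on the forward strand that is
            # the right flank for 3' (left for 5'), mirrored on '-'
            written = inst if strand == "+" else revcomp(inst)
            if (side == "3prime") == (strand == "+"):
                p0, p1 = end, min(len(gseq), end + pam_len)
                gseq[p0:p1] = list(written)[: p1 - p0]
            else:
                p0, p1 = max(0, start - pam_len), start
                gseq[p0:p1] = list(written)[pam_len - (p1 - p0) :]

        acc = f"{spacer_prefix}{si}"
        spacers.append(
            SpacerRecord(
                accession=acc,
                genome_id=genome_id,
                sequence=spacer_seq,
                source_tool="fasta",
                array_index=0,
                position_in_array=si,
            )
        )
        truth.append(
            {
                "spacer_accession": acc,
                "genome_id": genome_id,
                "phage_accession": genome.accession,
                "proto_start": start,
                "proto_end": end,
                "strand": strand,
                "nt_mismatches": mutated_nt,
                "aa_conserving_nt_subs": k,
                "aa_subs": j,
            }
        )
    out_genome = GenomeRecord(
        accession=genome.accession, sequence="".join(gseq), kind=genome.kind
    )
    return spacers, truth, out_genome


def random_spacer(rng, spacer_len=DEFAULT_SPACER_LEN) -> str:
    slen = int(rng.integers(spacer_len[0], spacer_len[1] + 1))
    return "".join(_NT[i] for i in rng.integers(0, 4, size=slen))


@dataclass
class Benchmark:
    """A full synthetic input bundle with ground truth."""

    spacers_by_genome: dict = field(default_factory=dict)
    phages: list = field(default_factory=list)
    truth_pairs: set = field(default_factory=set)
    truth: list = field(default_factory=list)
    labels: TaxLabelTable | None = None

    def write(self, directory) -> None:
        """Materialize as FASTAs + taxonomy TSVs + truth JSON."""
        d = Path(directory)
        (d / "spacers").mkdir(parents=True, exist_ok=True)
        (d / "phages").mkdir(parents=True, exist_ok=True)
        for gid, spacers in self.spacers_by_genome.items():
            write_spacer_fasta(spacers, d / "spacers" / f"{gid}.fasta")
        for g in self.phages:
            (d / "phages" / f"{g.accession}.fasta").write_text(
                f">{g.accession}\n{g.sequence}\n"
            )
        if self.labels:
            with open(d / "labels.tsv", "w") as fh:
                for acc, taxid in sorted(self.labels.mapping.items()):
                    fh.write(f"{acc}\t{taxid}\n")
            tax = self.labels.taxonomy
            with open(d / "tree.tsv", "w") as fh:
                for taxid, (parent, rank, name) in sorted(tax.nodes.items()):
                    fh.write(f"{taxid}\t{parent}\t{rank}\t{name}\n")
        (d / "truth.json").write_text(
            json.dumps(
                {"pairs": sorted(self.truth_pairs), "spacers": self.truth}, indent=2
            )
        )


def _toy_taxonomy(host_ids: list[str], phage_accs: list[str]) -> TaxLabelTable:
    nodes: dict[int, tuple[int, str, str]] = {
        1: (1, "no rank", "root"),
        2: (1, "superkingdom", "Bacteria"),
        3: (1, "superkingdom", "Viruses"),
    }
    mapping: dict[str, int] = {}
    for i, hid in enumerate(host_ids):
        genus = 10 + i // 3
        nodes.setdefault(genus, (2, "genus", f"Hostgenus{i // 3}"))
        nodes[100 + i] = (genus, "species", f"Hostspecies{i}")
        mapping[hid] = 100 + i
    for jx, acc in enumerate(phage_accs):
        genus = 50 + jx // 3
        nodes.setdefault(genus, (3, "genus", f"Phagegenus{jx // 3}"))
        nodes[1000 + jx] = (genus, "species", f"Phagespecies{jx}")
        mapping[acc] = 1000 + jx
    return TaxLabelTable(mapping=mapping, taxonomy=Taxonomy(nodes))


def make_benchmark(
    n_hosts: int = 5,
    n_phages: int = 15,
    pairing: list[tuple[int, int]] | None = None,
    decoy_hosts: int = 10,
    seed: int = 0,
    spacers_per_pair: int = DEFAULT_SPACERS_PER_PAIR,
    decoy_spacers: int = DEFAULT_DECOY_SPACERS,
    spacer_len=DEFAULT_SPACER_LEN,
    mutation_model: dict | None = None,
    pam_motif: tuple[str, str] | None = DEFAULT_PAM,
    phage_length: int = DEFAULT_PHAGE_LENGTH,
    coding_fraction: float = DEFAULT_CODING_FRACTION,
) -> Benchmark:
    """Hosts with planted spacer sets plus decoy hosts and phages.

    ``pairing`` lists (host index, phage index) true relationships;
    the default pairs host i with phage i.  Phages not referenced by the
    pairing act as decoys, as do the ``decoy_hosts`` extra hosts whose
    spacers are random sequences.  Same seed, same bundle.
    """
    rng = np.random.default_rng(seed)
    if pairing is None:
        pairing = [(i, i) for i in range(min(n_hosts, n_phages))]
    phages: list[GenomeRecord] = []
    plans: list[list[dict]] = []
    for jx in range(n_phages):
        g, plan = make_phage(
            phage_length,
            coding_fraction,
            seed=int(rng.integers(0, 2**31 - 1)),
            accession=f"phage_{jx}",
        )
        phages.append(g)
        plans.append(plan)

    spacers_by_genome: dict[str, list[SpacerRecord]] = {}
    truth: list[dict] = []
    truth_pairs: set[tuple[str, str]] = set()
    for i in range(n_hosts):
        spacers_by_genome[f"host_{i}"] = []
    for hi, pj in pairing:
        gid = f"host_{hi}"
        sp, tr, mutated = plant_protospacers(
            phages[pj],
            plans[pj],
            spacers_per_pair,
            spacer_len=spacer_len,
            mutation_model=mutation_model,
            pam_motif=pam_motif,
            seed=int(rng.integers(0, 2**31 - 1)),
            genome_id=gid,
            spacer_prefix=f"host{hi}_ph{pj}_sp",
        )
        phages[pj] = mutated
        spacers_by_genome[gid].extend(sp)
        truth.extend(tr)
        truth_pairs.add((gid, phages[pj].accession))
    for d in range(decoy_hosts):
        gid = f"decoy_{d}"
        spacers_by_genome[gid] = [
            SpacerRecord(
                accession=f"{gid}_sp{si}",
                genome_id=gid,
                sequence=random_spacer(rng, spacer_len),
                position_in_array=si,
            )
            for si in range(decoy_spacers)
        ]
    labels = _toy_taxonomy(sorted(spacers_by_genome), [g.accession for g in phages])
    return Benchmark(
        spacers_by_genome=spacers_by_genome,
        phages=phages,
        truth_pairs=truth_pairs,
        truth=truth,
        labels=labels,
    )
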