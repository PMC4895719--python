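"""Synteny-anchored gene-loss and remnant detection.

Conserved syntenic blocks are chains of colinear orthologue anchor pairs
between two annotated genomes.  A query gene inside a block is tested by
aligning each of its coding exons against the other genome's
inter-anchor sequence: near-complete coverage means the gene is present,
intermediate coverage means a decayed remnant (with a per-exon hit map),
and background-level coverage means the gene is absent.  A promoter
motif scan (IUPAC-degenerate, both strands) covers the regulatory-loss
signal, and a species x gene presence/absence matrix summarises calls
against a phenotype rule.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .homology import ScoringParams, align_pair, nt_params
from .io import GeneRecord

INTACT_FLOOR = 0.8  # fraction of coding length for a "present" call
NOISE_FLOOR = 0.1  # below this the gene is "absent"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass
class SyntenyBlock:
    """A colinear run of orthologous gene anchors between two genomes."""

    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]  # (gene in A, gene in B), ordered by A
    orientation: int = 1  # +1 colinear, -1 inverted

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def _ranks(annot: Sequence[GeneRecord]) -> dict[str, tuple[str, int, GeneRecord]]:
    out = {}
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in annot:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, genes in by_chrom.items():
        for rank, g in enumerate(sorted(genes, key=lambda x: x.start)):
            out[g.id] = (chrom, rank, g)
    return out


def find_blocks(
    annot_a: Sequence[GeneRecord],
    annot_b: Sequence[GeneRecord],
    ortholog_pairs: Iterable[tuple[str, str]],
    max_gap_genes: int = 5,
) -> list[SyntenyBlock]:
    """Greedy chaining of colinear anchors into maximal synteny blocks.

    Anchors are orthologous gene pairs; a chain may skip at most
    ``max_gap_genes`` interleaved non-anchor genes on either genome and
    must advance monotonically on both (one orientation per block).
    Blocks need >= 2 anchors.
    """
    ra, rb = _ranks(annot_a), _ranks(annot_b)
    per_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for ga, gb in ortholog_pairs:
        if ga not in ra or gb not in rb:
            continue
        ca, ia, _ = ra[ga]
        cb, ib, _ = rb[gb]
        per_pair.setdefault((ca, cb), []).append((ia, ib, ga, gb))

    blocks: list[SyntenyBlock] = []
    step = max_gap_genes + 1
    for (ca, cb), anchors in sorted(per_pair.items()):
        anchors.sort()
        chain: list[tuple[int, int, str, str]] = []
        direction = 0

        def flush():
            nonlocal chain, direction
            if len(chain) >= 2:
                blocks.append(SyntenyBlock(
                    chrom_a=ca, chrom_b=cb,
                    anchors=[(ga, gb) for _, _, ga, gb in chain],
                    orientation=direction or 1,
                ))
            chain, direction = [], 0

        for a in anchors:
            if not chain:
                chain.append(a)
                continue
            pa, pb = chain[-1][0], chain[-1][1]
            da, db = a[0] - pa, a[1] - pb
            if 0 < da <= step and db != 0 and abs(db) <= step:
                d = 1 if db > 0 else -1
                if direction == 0 or d == direction:
                    direction = d
                    chain.append(a)
                    continue
            flush()
            chain.append(a)
        flush()
    return blocks


# ---------------------------------------------------------------------------
# Presence calling inside a block

@dataclass
class PresenceCall:
    species: str
    gene: str
    status: str  # present | absent | remnant
    coverage: float = 0.0
    exon_map: list[int] = field(default_factory=list)  # 1-based exon numbers
    promoter_status: str = "not-assessed"  # found | missing | not-assessed
    evidence: str = ""


def _exon_sequences(gene: GeneRecord) -> list[str]:
    """Coding exon sequences, in order, reconstructed from the CDS."""
    if not gene.exons:
        return [gene.seq]
    lens = [e - s for s, e in gene.exons]
    out, off = [], 0
    for L in lens:
        out.append(gene.seq[off:off + L])
        off += L
    return out


def block_span_b(
    block: SyntenyBlock,
    gene: GeneRecord,
    annot_b_by_id: Mapping[str, GeneRecord],
    rank_a: Mapping[str, tuple],
    margin: int = 200,
) -> tuple[str, int, int]:
    """B-genome interval between the anchors flanking ``gene`` on A."""
    if gene.id not in rank_a:
        raise ValueError(f"gene {gene.id} has no rank on genome A")
    _, grank, _ = rank_a[gene.id]
    left = right = None
    for ga, gb in block.anchors:
        arank = rank_a[ga][1]
        if arank < grank:
            left = gb
        elif arank > grank and right is None:
            right = gb
    if left is None or right is None:
        raise ValueError(
            f"block span undefined on B for gene {gene.id}: no flanking "
            f"anchors on both sides"
        )
    bl, br = annot_b_by_id[left], annot_b_by_id[right]
    lo = min(bl.start, br.start)
    hi = max(bl.end, br.end)
    return bl.chrom, max(0, lo - margin), hi + margin


def call_loss_in_block(
    block: SyntenyBlock,
    gene: GeneRecord,
    genome_b: Mapping[str, str],
    annot_b: Sequence[GeneRecord] | Mapping[str, GeneRecord],
    annot_a: Sequence[GeneRecord] | None = None,
    intact_floor: float = INTACT_FLOOR,
    noise_floor: float = NOISE_FLOOR,
    exon_evalue: float = 1e-5,
    params: ScoringParams | None = None,
    species_b: str = "B",
) -> PresenceCall:
    """Presence / remnant / absent call for one A-gene inside a block.

    Each coding exon is locally aligned against the B inter-anchor
    sequence (both strands).  Coverage is the aligned-exon fraction of
    coding length: >= ``intact_floor`` -> present; in
    (``noise_floor``, ``intact_floor``) -> remnant with per-exon hit map;
    <= ``noise_floor`` -> absent.
    """
    if params is None:
        params = nt_params(prefilter_k=11)
    if isinstance(annot_b, Mapping):
        annot_b_by_id = dict(annot_b)
        annot_b_list = list(annot_b.values())
    else:
        annot_b_by_id = {g.id: g for g in annot_b}
        annot_b_list = list(annot_b)
    rank_a = _ranks(annot_a) if annot_a is not None else {
        gene.id: (gene.chrom, _infer_rank(block, gene), gene)}
    chrom, lo, hi = block_span_b(block, gene, annot_b_by_id, rank_a)
    region = genome_b[chrom][lo:hi]
    region_rc = str(Seq(region).reverse_complement())
    exons = _exon_sequences(gene)
    hit_len = 0
    exon_map: list[int] = []
    from dataclasses import replace as _replace
    p = _replace(params, evalue_max=exon_evalue)
    for i, ex in enumerate(exons, start=1):
        if not ex:
            continue
        hit = align_pair(ex, region, p, qid=f"{gene.id}.exon{i}", sid="region")
        if hit is None:
            hit = align_pair(ex, region_rc, p,
                             qid=f"{gene.id}.exon{i}", sid="region_rc")
        if hit is not None:
            hit_len += len(ex)
            exon_map.append(i)
    total = sum(len(e) for e in exons)
    coverage = hit_len / total if total else 0.0
    if coverage >= intact_floor:
        status, evidence = "present", "intact ORF coverage"
    elif coverage > noise_floor:
        status, evidence = "remnant", "partial alignment fraction"
    else:
        status, evidence = "absent", "no hit"
    return PresenceCall(species=species_b, gene=gene.id, status=status,
                        coverage=coverage, exon_map=exon_map,
                        evidence=evidence)


def _infer_rank(block: SyntenyBlock, gene: GeneRecord) -> int:
    raise ValueError(
        f"annot_a is required to place gene {gene.id} within the block"
    )


# ---------------------------------------------------------------------------
# Promoter motif scan

def iupac_regex(motif: str) -> re.Pattern:
    try:
        return re.compile("".join(IUPAC[c] for c in motif.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character in motif {motif!r}") from exc


def promoter_check(
    genome: Mapping[str, str] | str,
    chrom: str | None,
    expected_start: int,
    motifs: Iterable[str],
    window: int = 2000,
) -> dict[str, str]:
    """Scan the window upstream of an expected gene position for motifs.

    IUPAC-degenerate exact scan on both strands; returns found/missing
    per motif.  A window running off the contig end is truncated with a
    warning.
    """
    seq = genome if isinstance(genome, str) else genome[chrom]
    lo = expected_start - window
    if lo < 0:
        warnings.warn(
            f"promoter window truncated at contig start ({lo})", stacklevel=2
        )
        lo = 0
    if expected_start > len(seq):
        warnings.warn("promoter window truncated at contig end", stacklevel=2)
    upstream = seq[lo:expected_start].upper()
    upstream_rc = str(Seq(upstream).reverse_complement())
    out = {}
    for motif in motifs:
        rx = iupac_regex(motif)
        found = bool(rx.search(upstream)) or bool(rx.search(upstream_rc))
        out[motif] = "found" if found else "missing"
    return out


# ---------------------------------------------------------------------------
# Presence/absence matrix and phenotype-rule consistency

def presence_matrix(calls: Iterable[PresenceCall]) -> pd.DataFrame:
    """Species x gene status matrix from individual presence calls."""
    rows = [{"species": c.species, "gene": c.gene, "status": c.status}
            for c in calls]
    df = pd.DataFrame(rows)
    return df.pivot(index="species", columns="gene", values="status")


PhenotypeRule = Callable[[str, Mapping[str, str]], bool]


def check_phenotype_rule(
    matrix: pd.DataFrame,
    phenotypes: Mapping[str, str],
    rule: PhenotypeRule,
) -> list[str]:
    """Species whose presence row violates the phenotype rule."""
    violations = []
    for species in matrix.index:
        row = matrix.loc[species].to_dict()
        if not rule(phenotypes.get(species, ""), row):
            violations.append(species)
    return violations
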