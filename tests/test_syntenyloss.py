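"""Synteny blocks, loss/remnant calls, promoter scan, presence matrix."""

import numpy as np
import pytest
from Bio.Seq import Seq

from subtracta.io import GeneRecord
from subtracta.syntenyloss import (PresenceCall, call_loss_in_block,
                                   check_phenotype_rule, find_blocks,
                                   iupac_regex, presence_matrix,
                                   promoter_check)
from subtracta.synthgen import PROMOTER_MOTIF, PROMOTER_OFFSET


def _toy_annot(order, chrom="c1", species="sp"):
    return [GeneRecord(id=g, species=species, chrom=chrom, start=1000 * i,
                       end=1000 * i + 500) for i, g in enumerate(order)]


def test_identical_annotations_single_block_per_chromosome(sim):
    annot = sim.annotations["carp"]
    ids = sorted(g.id for g in annot)
    blocks = find_blocks(annot, annot, [(g, g) for g in ids])
    chroms = sorted({g.chrom for g in annot})
    assert sorted(b.chrom_a for b in blocks) == chroms
    per_chrom = {c: sum(1 for g in annot if g.chrom == c) for c in chroms}
    for b in blocks:
        assert b.n_anchors == per_chrom[b.chrom_a]
        assert b.orientation == 1


def test_shuffled_gene_order_yields_no_long_blocks(rng):
    """Permutation null: random gene orders almost never chain five
    colinear anchors."""
    n, reps = 50, 300
    order_a = [f"g{i}" for i in range(n)]
    annot_a = _toy_annot(order_a)
    long_blocks = 0
    for _ in range(reps):
        order_b = list(rng.permutation(order_a))
        annot_b = _toy_annot(order_b)
        blocks = find_blocks(annot_a, annot_b, [(g, g) for g in order_a])
        if any(b.n_anchors >= 5 for b in blocks):
            long_blocks += 1
    assert long_blocks / reps < 0.05


def test_planted_deletion_skips_anchor_but_keeps_block(sim, truth):
    annot_a = sim.annotations["carp"]
    annot_b = sim.annotations["catfish"]
    blocks = find_blocks(annot_a, annot_b,
                         sim.ortholog_pairs("carp", "catfish"))
    lost = truth.lost_genes("catfish")
    assert len(blocks) == 2  # one per chromosome despite the gaps
    for b in blocks:
        anchor_as = {a for a, _ in b.anchors}
        assert not anchor_as & lost


def test_block_anchor_ranks_strictly_increase(sim):
    annot_a = sim.annotations["carp"]
    annot_b = sim.annotations["catfish"]
    rank_a = {g.id: i for c in ("chr1", "chr2")
              for i, g in enumerate(sorted(
                  [x for x in annot_a if x.chrom == c], key=lambda x: x.start))}
    blocks = find_blocks(annot_a, annot_b,
                         sim.ortholog_pairs("carp", "catfish"))
    for b in blocks:
        ranks = [rank_a[a] for a, _ in b.anchors]
        assert ranks == sorted(ranks) and len(set(ranks)) == len(ranks)


@pytest.fixture(scope="module")
def loss_calls(sim):
    annot_a = sim.annotations["carp"]
    annot_b = sim.annotations["catfish"]
    blocks = find_blocks(annot_a, annot_b,
                         sim.ortholog_pairs("carp", "catfish"))
    by_id = {g.id: g for g in annot_a}
    calls = {}
    for gid, status in sim.truth.presence["catfish"].items():
        gene = by_id[gid]
        block = next(b for b in blocks if b.chrom_a == gene.chrom)
        try:
            calls[gid] = call_loss_in_block(block, gene,
                                            sim.genomes["catfish"], annot_b,
                                            annot_a=annot_a,
                                            species_b="catfish")
        except ValueError:
            calls[gid] = None
    return calls


def test_presence_calls_match_planted_truth(sim, loss_calls):
    for gid, status in sim.truth.presence["catfish"].items():
        call = loss_calls[gid]
        if call is None:  # genes at block edges cannot be called
            continue
        assert call.status == status, gid


def test_remnant_exon_map_is_exon_five(sim, loss_calls):
    remnants = [g for g, s in sim.truth.presence["catfish"].items()
                if s == "remnant"]
    for g in remnants:
        call = loss_calls[g]
        assert call.status == "remnant"
        assert call.exon_map == [5]
        assert 0.1 < call.coverage < 0.8


def test_loss_call_invariant_to_strand_relabeling(sim, loss_calls):
    """Reverse-complementing the target chromosome leaves calls intact."""
    annot_a = sim.annotations["carp"]
    annot_b = sim.annotations["catfish"]
    blocks = find_blocks(annot_a, annot_b,
                         sim.ortholog_pairs("carp", "catfish"))
    genome_rc = {c: str(Seq(s).reverse_complement())
                 for c, s in sim.genomes["catfish"].items()}
    lengths = {c: len(s) for c, s in sim.genomes["catfish"].items()}
    annot_b_rc = []
    for g in annot_b:
        L = lengths[g.chrom]
        annot_b_rc.append(GeneRecord(
            id=g.id, species=g.species, chrom=g.chrom, start=L - g.end,
            end=L - g.start, strand="-", seq=g.seq, scaffold=g.scaffold))
    by_id = {g.id: g for g in annot_a}
    for gid in list(sim.truth.lost_genes("catfish"))[:4]:
        gene = by_id[gid]
        block = next(b for b in find_blocks(annot_a, annot_b_rc,
                                            sim.ortholog_pairs("carp", "catfish"))
                     if b.chrom_a == gene.chrom)
        call = call_loss_in_block(block, gene, genome_rc, annot_b_rc,
                                  annot_a=annot_a, species_b="catfish")
        assert call.status == loss_calls[gid].status


def test_missing_flank_is_an_error(sim):
    annot_a = sim.annotations["carp"]
    annot_b = sim.annotations["catfish"]
    blocks = find_blocks(annot_a, annot_b,
                         sim.ortholog_pairs("carp", "catfish"))
    first = sorted((g for g in annot_a if g.chrom == "chr1"),
                   key=lambda g: g.start)[0]
    block = next(b for b in blocks if b.chrom_a == "chr1")
    with pytest.raises(ValueError, match="block span undefined"):
        call_loss_in_block(block, first, sim.genomes["catfish"], annot_b,
                           annot_a=annot_a)


# ---------------------------------------------------------------------------
# Promoter scan

def test_promoter_motif_found_for_intact_gene(sim):
    gene = next(g for g in sim.annotations["catfish"] if g.id == "g002")
    status = promoter_check(sim.genomes["catfish"], gene.chrom, gene.start,
                            [PROMOTER_MOTIF], window=PROMOTER_OFFSET + 50)
    assert status[PROMOTER_MOTIF] == "found"


def test_promoter_missing_in_scrambled_window(rng):
    window = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
    status = promoter_check(window, None, len(window), [PROMOTER_MOTIF])
    assert status[PROMOTER_MOTIF] == "missing"


def test_iupac_degeneracy():
    rx = iupac_regex("GGAW")
    assert rx.fullmatch("GGAT") and rx.fullmatch("GGAA")
    assert not rx.fullmatch("GGAC")
    status = promoter_check("TTTTGGATTTTT", None, 12, ["GGAW"], window=12)
    assert status["GGAW"] == "found"


def test_truncated_window_warns():
    with pytest.warns(UserWarning, match="truncated"):
        promoter_check("ACGTACGT", None, 4, ["ACGT"], window=100)


# ---------------------------------------------------------------------------
# Presence matrix + phenotype rule

def test_presence_matrix_shape_and_rule_consistency():
    species = ["carp", "catfish", "stickleback"]
    genes = ["SCPP1", "SCPP5"]
    status = {("carp", "SCPP1"): "present", ("carp", "SCPP5"): "present",
              ("catfish", "SCPP1"): "absent", ("catfish", "SCPP5"): "remnant",
              ("stickleback", "SCPP1"): "present",
              ("stickleback", "SCPP5"): "absent"}
    calls = [PresenceCall(species=s, gene=g, status=status[(s, g)])
             for s in species for g in genes]
    matrix = presence_matrix(calls)
    assert matrix.shape == (3, 2)

    phenotypes = {"carp": "scaled", "catfish": "scaleless",
                  "stickleback": "scaleless"}

    def rule(phenotype, row):
        intact = all(row[g] == "present" for g in genes)
        return intact if phenotype == "scaled" else not intact

    assert check_phenotype_rule(matrix, phenotypes, rule) == []
    phenotypes["catfish"] = "scaled"  # now inconsistent
    assert check_phenotype_rule(matrix, phenotypes, rule) == ["catfish"]


def test_all_present_matrix_satisfies_monotone_rules():
    calls = [PresenceCall(species=s, gene=g, status="present")
             for s in ("a", "b") for g in ("x", "y")]
    matrix = presence_matrix(calls)
    rule = lambda ph, row: all(v == "present" for v in row.values())
    assert check_phenotype_rule(matrix, {"a": "scaled", "b": "scaled"},
                                rule) == []
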