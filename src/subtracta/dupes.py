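"""Duplicated-gene landscape analyses.

Covers the self-similarity threshold ladder (cluster counts as the E-value
cutoff tightens), tandem / intrachromosomal / interchromosomal
classification of duplicate pairs, Nei-Gojobori (1986) Ka/Ks with
Jukes-Cantor correction, recent-duplication calling (Ks < 1), and
outgroup-anchored ohnolog chromosome pairing.

NG86 is used as the deterministic, closed-form substitution-rate
estimator; absolute Ks values differ from model-averaged estimators, but
the Ks < 1 recency classification is robust in the simulated regime.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .homology import (HomologyHit, ScoringParams, SimilarityGraph, aa_params,
                       align_pair, all_vs_all, mcl_cluster)
from .io import GeneRecord

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = set(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)
NTS = "ACGT"

TANDEM_MAX_GAP = 10_000  # bp, inclusive


# ---------------------------------------------------------------------------
# NG86

@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Fraction-weighted synonymous site count of one codon.

    Changes that create a stop codon count as nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NTS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    All mutational orderings between the two codons are enumerated;
    orderings passing through a stop codon are excluded (unless every
    ordering does, in which case all are used).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                valid = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            paths.append((sd, nd))
    if not paths:  # degenerate: every ordering hits a stop
        for order in itertools.permutations(diff_pos):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                aa1 = CODON_TO_AA.get(cur)
                aa2 = CODON_TO_AA.get(nxt)
                if aa1 is not None and aa1 == aa2:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


@dataclass
class KaKsResult:
    ka: float | None
    ks: float | None
    ka_saturated: bool
    ks_saturated: bool
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


def _codons(cds: str, name: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"{name}: length {len(cds)} not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon {c} at codon {i}")
        if c not in CODON_TO_AA:
            raise ValueError(f"{name}: non-ACGT codon {c!r} at codon {i}")
    return codons


def _jukes_cantor(p: float) -> tuple[float | None, bool]:
    if p >= 0.75:
        return None, True
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0), False


def ng86(cds1: str, cds2: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks of two aligned, equal-length coding sequences.

    Synonymous/nonsynonymous site counts are averaged over both sequences;
    difference counts are pathway-averaged per codon pair; proportions are
    Jukes-Cantor corrected (p >= 3/4 -> saturated, value ``None``).
    """
    co1 = _codons(cds1, "cds1")
    co2 = _codons(cds2, "cds2")
    if len(co1) != len(co2):
        raise ValueError(f"unequal lengths: {len(cds1)} vs {len(cds2)}")
    s1 = sum(_syn_sites(c) for c in co1)
    s2 = sum(_syn_sites(c) for c in co2)
    S = 0.5 * (s1 + s2)
    N = 3.0 * len(co1) - S
    sd = nd = 0.0
    for c1, c2 in zip(co1, co2):
        d_s, d_n = _pair_differences(c1, c2)
        sd += d_s
        nd += d_n
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks, ks_sat = _jukes_cantor(ps)
    ka, ka_sat = _jukes_cantor(pn)
    return KaKsResult(ka=ka, ks=ks, ka_saturated=ka_sat, ks_saturated=ks_sat,
                      syn_sites=S, nonsyn_sites=N, syn_diffs=sd, nonsyn_diffs=nd)


# ---------------------------------------------------------------------------
# Codon alignment (protein alignment back-threaded onto nucleotides)

_PROT_ALIGNER: Align.PairwiseAligner | None = None


def _protein_global_aligner() -> Align.PairwiseAligner:
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11
        al.extend_gap_score = -1
        _PROT_ALIGNER = al
    return _PROT_ALIGNER


def codon_align(cds1: str, cds2: str) -> tuple[str, str]:
    """Codon-aware pairwise alignment; gapped codon columns dropped pairwise."""
    p1 = str(Seq(cds1).translate()).rstrip("*")
    p2 = str(Seq(cds2).translate()).rstrip("*")
    aln = next(iter(_protein_global_aligner().align(p1, p2)))
    b1, b2 = aln.aligned
    out1, out2 = [], []
    for (qs, qe), (ss, se) in zip(b1, b2):
        out1.append(cds1[3 * qs:3 * qe])
        out2.append(cds2[3 * ss:3 * se])
    return "".join(out1), "".join(out2)


# ---------------------------------------------------------------------------
# Duplicate pair classification

@dataclass
class DupPair:
    gene1: str
    gene2: str
    category: str  # tandem | intrachromosomal | interchromosomal | unplaced
    ka: float | None = None
    ks: float | None = None
    ks_saturated: bool = False

    @property
    def recent(self) -> bool:
        """Recent duplication: Ks < 1.0 and not saturated."""
        return (not self.ks_saturated) and self.ks is not None and self.ks < 1.0


def classify_dup(
    gene1: str, gene2: str, annotations: Mapping[str, GeneRecord]
) -> str:
    """Genomic category of a duplicate pair.

    Same scaffold with an inter-gene gap <= 10 kb -> tandem; same
    chromosome otherwise -> intrachromosomal; different chromosomes ->
    interchromosomal.  The gap runs from the end of the upstream gene to
    the start of the downstream one (inclusive boundary at 10,000).
    """
    a = annotations.get(gene1)
    b = annotations.get(gene2)
    if a is None or b is None or not a.chrom or not b.chrom:
        return "unplaced"
    if a.scaffold == b.scaffold:
        first, second = (a, b) if a.start <= b.start else (b, a)
        gap = max(0, second.start - first.end)
        if gap <= TANDEM_MAX_GAP:
            return "tandem"
    if a.chrom == b.chrom:
        return "intrachromosomal"
    return "interchromosomal"


def annotate_pairs(
    pairs: Iterable[tuple[str, str]],
    annotations: Mapping[str, GeneRecord],
    cds_of: Mapping[str, str] | None = None,
) -> list[DupPair]:
    """Classify duplicate pairs and (when CDS are given) attach NG86 Ka/Ks."""
    out = []
    for g1, g2 in pairs:
        cat = classify_dup(g1, g2, annotations)
        dp = DupPair(g1, g2, cat)
        if cds_of is not None and g1 in cds_of and g2 in cds_of:
            a1, a2 = codon_align(cds_of[g1], cds_of[g2])
            if a1:
                r = ng86(a1, a2)
                dp.ka, dp.ks, dp.ks_saturated = r.ka, r.ks, r.ks_saturated
        out.append(dp)
    return out


def pairs_from_clusters(clusters: Iterable[frozenset[str]]) -> list[tuple[str, str]]:
    pairs = []
    for c in clusters:
        members = sorted(c)
        pairs.extend(itertools.combinations(members, 2))
    return pairs


# ---------------------------------------------------------------------------
# Threshold ladder

@dataclass
class ThresholdCurve:
    """Cluster statistics along a strictly decreasing E-value ladder."""

    evalues: list[float]
    n_clusters: list[int]  # total clusters incl. singletons
    n_multi: list[int]  # clusters with >= 2 members
    mean_multi_size: list[float]
    clusters: list[list[frozenset[str]]] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"evalue": self.evalues, "n_clusters": self.n_clusters,
             "n_multi": self.n_multi, "mean_multi_size": self.mean_multi_size}
        )


def threshold_ladder(
    genes: Mapping[str, str],
    ladder: Sequence[float],
    params: ScoringParams | None = None,
    inflation: float = 1.5,
) -> ThresholdCurve:
    """Self-similarity clustering across an E-value cutoff ladder.

    Hits are computed once at the loosest cutoff; each stricter rung
    re-clusters inside the previous rung's clusters, so rungs are nested
    refinements by construction (tightening a cutoff can only split).
    """
    ladder = list(ladder)
    if any(b >= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("E-value ladder must be strictly decreasing")
    if params is None:
        params = aa_params(prefilter_k=4)
    params = replace(params, evalue_max=ladder[0])
    sg = all_vs_all(genes, params)

    curve = ThresholdCurve([], [], [], [], [])
    prev: list[frozenset[str]] | None = None
    for e in ladder:
        hits_e = [h for h in sg.hits if h.evalue <= e]
        if prev is None:
            g = SimilarityGraph(sg.nodes)
            for h in hits_e:
                g.add_hit(h)
            rung = mcl_cluster(g, inflation=inflation)
        else:
            rung = []
            for cluster in prev:
                if len(cluster) == 1:
                    rung.append(cluster)
                    continue
                sub = SimilarityGraph(sorted(cluster))
                for h in hits_e:
                    if h.qid in cluster and h.sid in cluster:
                        sub.add_hit(h)
                rung.extend(mcl_cluster(sub, inflation=inflation))
        rung = sorted(rung, key=lambda c: sorted(c)[0])
        multi = [c for c in rung if len(c) >= 2]
        curve.evalues.append(e)
        curve.n_clusters.append(len(rung))
        curve.n_multi.append(len(multi))
        curve.mean_multi_size.append(
            float(np.mean([len(c) for c in multi])) if multi else 0.0
        )
        curve.clusters.append(rung)
        prev = rung
    return curve


# ---------------------------------------------------------------------------
# Ohnolog chromosome pairing against an outgroup proteome

def ohnolog_pairs(
    fish_proteins: Mapping[str, str],
    chrom_of: Mapping[str, str],
    outgroup_proteins: Mapping[str, str],
    params: ScoringParams | None = None,
    evalue_max: float = 1e-10,
    min_links: int = 25,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Pair chromosomes by counting outgroup-anchored paralogue pairs.

    For every outgroup protein the best-matching fish genes are recorded;
    when two or more fish genes match, the top two by bit score form a
    paralogue pair, tallied per unordered chromosome pair.  The returned
    frame flags pairs supported by >= ``min_links`` links.
    """
    if params is None:
        params = aa_params(prefilter_k=4)
    params = replace(params, evalue_max=evalue_max,
                     db_residues=sum(len(s) for s in fish_proteins.values()))
    pair_list: list[tuple[str, str, str]] = []
    tally: dict[tuple[str, str], int] = {}
    for oid, oseq in outgroup_proteins.items():
        hits: list[HomologyHit] = []
        for fid, fseq in fish_proteins.items():
            h = align_pair(oseq, fseq, params, qid=oid, sid=fid)
            if h is not None:
                hits.append(h)
        if len(hits) < 2:
            continue
        hits.sort(key=lambda h: (-h.bit_score, h.sid))
        g1, g2 = hits[0].sid, hits[1].sid
        pair_list.append((oid, g1, g2))
        c1, c2 = chrom_of.get(g1), chrom_of.get(g2)
        if c1 is None or c2 is None:
            continue  # unplaced genes excluded from tallies
        key = tuple(sorted((c1, c2)))
        tally[key] = tally.get(key, 0) + 1
    rows = [
        {"chrom1": k[0], "chrom2": k[1], "n_pairs": v, "strong": v >= min_links}
        for k, v in sorted(tally.items())
    ]
    return pair_list, pd.DataFrame(rows, columns=["chrom1", "chrom2",
                                                  "n_pairs", "strong"])
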