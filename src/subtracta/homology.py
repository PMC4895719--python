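"""Pairwise homology search, family clustering and orthology classification.

The search kernel is full Smith-Waterman local alignment (Biopython's
PairwiseAligner) with a Karlin-Altschul significance proxy
``E = K * m * n * exp(-lambda * S)``.  The constants are frozen per scoring
scheme so that E-value thresholds behave like those of heuristic search
tools; the contract is threshold-equivalence, not score equality.

Clustering layers:

* single-linkage family clustering over identity/overlap-filtered hits
  (SiLiX-style transitive closure);
* Markov clustering (MCL) of the similarity graph for orthologue groups;
* the nine-way two-species orthology classification
  (one/two/many x one/two/many).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")

#: Frozen Karlin-Altschul constants per scoring scheme (gapped regimes).
KA_CONSTANTS = {"aa": (0.318, 0.13), "nt": (1.28, 0.46)}


@dataclass(frozen=True)
class ScoringParams:
    """Local-alignment scoring configuration.

    Defaults: nt +1/-2, gap open -5 extend -2; aa BLOSUM62, open -11
    extend -1.  ``evalue_max`` is the no-hit threshold; ``db_residues``
    (when set) fixes the search-space size n, otherwise the subject
    length is used.
    """

    alphabet: str = "aa"
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -11.0
    gap_extend: float = -1.0
    evalue_max: float | None = 1e-5  # None disables the no-hit gate
    db_residues: int | None = None
    prefilter_k: int | None = None  # shared-k-mer prefilter; None = off

    def __post_init__(self):
        if self.alphabet not in ("nt", "aa"):
            raise ValueError(f"alphabet must be 'nt' or 'aa', got {self.alphabet!r}")

    @property
    def karlin_altschul(self) -> tuple[float, float]:
        return KA_CONSTANTS[self.alphabet]


def nt_params(**kw) -> ScoringParams:
    return ScoringParams(alphabet="nt", match=1, mismatch=-2,
                         gap_open=-5, gap_extend=-2, **kw)


def aa_params(**kw) -> ScoringParams:
    return ScoringParams(alphabet="aa", gap_open=-11, gap_extend=-1, **kw)


@dataclass
class HomologyHit:
    """One pairwise local-alignment result with a significance proxy."""

    qid: str
    sid: str
    identity: float  # percent, 0-100
    length: int  # alignment columns, gaps included
    qcov: float
    scov: float
    raw_score: float
    bit_score: float
    evalue: float
    qstart: int = 0  # 1-based, inclusive
    qend: int = 0
    sstart: int = 0
    send: int = 0
    mismatch_n: int = 0
    gapopen_n: int = 0

    def as_tabular(self) -> str:
        """12-column tab-separated row (standard tabular hit format)."""
        return "\t".join(
            [self.qid, self.sid, f"{self.identity:.2f}", str(self.length),
             str(self.mismatch_n), str(self.gapopen_n),
             str(self.qstart), str(self.qend), str(self.sstart), str(self.send),
             f"{self.evalue:.3g}", f"{self.bit_score:.1f}"]
        )


class SimilarityGraph:
    """Undirected weighted similarity graph plus the hits that built it."""

    def __init__(self, nodes: Iterable[str] = (), weight: str = "bit_score"):
        self.graph = nx.Graph()
        self.graph.add_nodes_from(nodes)
        self.weight_kind = weight
        self.hits: list[HomologyHit] = []

    def add_hit(self, hit: HomologyHit) -> None:
        self.hits.append(hit)
        if hit.qid == hit.sid:
            return  # no self-loops retained for clustering
        w = hit.bit_score if self.weight_kind == "bit_score" else -math.log10(hit.evalue)
        prev = self.graph.get_edge_data(hit.qid, hit.sid)
        if prev is None or w > prev["weight"]:
            self.graph.add_edge(hit.qid, hit.sid, weight=w)

    @property
    def nodes(self):
        return list(self.graph.nodes)


def _check_alphabet(seq: str, alphabet: str, name: str) -> None:
    allowed = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET
    bad = sorted(set(seq.upper()) - allowed)
    if bad:
        raise ValueError(
            f"sequence {name!r} has characters {bad} outside the "
            f"{alphabet!r} alphabet"
        )


_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _aligner_for(params: ScoringParams) -> Align.PairwiseAligner:
    key = (params.alphabet, params.match, params.mismatch,
           params.gap_open, params.gap_extend)
    if key not in _ALIGNER_CACHE:
        al = Align.PairwiseAligner()
        al.mode = "local"
        if params.alphabet == "nt":
            al.match_score = params.match
            al.mismatch_score = params.mismatch
        else:
            al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = params.gap_open
        al.extend_gap_score = params.gap_extend
        _ALIGNER_CACHE[key] = al
    return _ALIGNER_CACHE[key]


def shares_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return a in b or b in a
    kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
    return any(b[i:i + k] in kmers for i in range(len(b) - k + 1))


def evalue_from_score(score: float, m: int, n: int, params: ScoringParams) -> float:
    lam, K = params.karlin_altschul
    return K * m * n * math.exp(-lam * score)


def bit_score_from_raw(score: float, params: ScoringParams) -> float:
    lam, K = params.karlin_altschul
    return (lam * score - math.log(K)) / math.log(2)


def align_pair(
    a: str,
    b: str,
    params: ScoringParams | None = None,
    qid: str = "query",
    sid: str = "subject",
    alphabet: str | None = None,
) -> HomologyHit | None:
    """Smith-Waterman local alignment of two sequences.

    Returns a :class:`HomologyHit`, or ``None`` (no-hit) when the
    Karlin-Altschul E-proxy exceeds ``params.evalue_max``.
    """
    if params is None:
        params = ScoringParams(alphabet=alphabet or "aa")
    elif alphabet is not None and alphabet != params.alphabet:
        params = replace(params, alphabet=alphabet)
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    _check_alphabet(a, params.alphabet, qid)
    _check_alphabet(b, params.alphabet, sid)

    if params.prefilter_k and not shares_kmer(a, b, params.prefilter_k):
        return None

    aligner = _aligner_for(params)
    score = aligner.score(a, b)
    n_db = params.db_residues if params.db_residues else len(b)
    evalue = evalue_from_score(score, len(a), n_db, params)
    if score <= 0:
        return None
    if params.evalue_max is not None and evalue > params.evalue_max:
        return None

    aln = next(iter(aligner.align(a, b)))
    qblocks, sblocks = aln.aligned
    matches = 0
    mismatches = 0
    columns = 0
    gapopens = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        for i in range(qe - qs):
            columns += 1
            if a[qs + i] == b[ss + i]:
                matches += 1
            else:
                mismatches += 1
    for i in range(1, len(qblocks)):
        qgap = qblocks[i][0] - qblocks[i - 1][1]
        sgap = sblocks[i][0] - sblocks[i - 1][1]
        columns += qgap + sgap
        gapopens += (qgap > 0) + (sgap > 0)
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    sstart, send = int(sblocks[0][0]), int(sblocks[-1][1])
    return HomologyHit(
        qid=qid, sid=sid,
        identity=100.0 * matches / columns if columns else 0.0,
        length=columns,
        qcov=(qend - qstart) / len(a),
        scov=(send - sstart) / len(b),
        raw_score=float(score),
        bit_score=bit_score_from_raw(score, params),
        evalue=evalue,
        qstart=qstart + 1, qend=qend, sstart=sstart + 1, send=send,
        mismatch_n=mismatches, gapopen_n=gapopens,
    )


def all_vs_all(
    genes: Mapping[str, str],
    params: ScoringParams | None = None,
    weight: str = "bit_score",
) -> SimilarityGraph:
    """All-versus-all pairwise search; one edge per unordered pair.

    The graph is symmetrized by keeping the better direction's weight.
    The total database residue count fixes the E-value search space,
    matching database-size scaling of heuristic search tools.
    """
    if params is None:
        params = aa_params(prefilter_k=4)
    items = list(genes.items()) if isinstance(genes, Mapping) else list(genes)
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in all_vs_all input")
    genes = dict(items)
    total_residues = sum(len(s) for s in genes.values())
    params = replace(params, db_residues=total_residues)
    sg = SimilarityGraph(ids, weight=weight)
    for i, qid in enumerate(ids):
        for sid in ids:
            if qid == sid:
                continue
            hit = align_pair(genes[qid], genes[sid], params, qid=qid, sid=sid)
            if hit is not None:
                sg.add_hit(hit)
    return sg


# ---------------------------------------------------------------------------
# SiLiX-style single-linkage family clustering

def silix_cluster(
    graph: SimilarityGraph | Iterable[str],
    hits: Sequence[HomologyHit] | None = None,
    min_identity: float = 30.0,
    min_overlap: float = 0.5,
) -> list[frozenset[str]]:
    """Single-linkage transitive closure over hits passing BOTH thresholds.

    ``overlap`` is min(query coverage, subject coverage).  Every input gene
    lands in exactly one cluster; singletons allowed.
    """
    if isinstance(graph, SimilarityGraph):
        universe = list(graph.nodes)
        if hits is None:
            hits = graph.hits
    else:
        universe = list(graph)
        hits = hits or []
    g = nx.Graph()
    g.add_nodes_from(universe)
    for h in hits:
        if h.qid == h.sid:
            continue
        if h.identity >= min_identity and min(h.qcov, h.scov) >= min_overlap:
            g.add_edge(h.qid, h.sid)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: sorted(c)[0])


# ---------------------------------------------------------------------------
# Markov clustering

class MCLConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"MCL did not converge within {max_iter} iterations "
            f"(residual {residual:.3g})"
        )
        self.residual = residual


def _mcl_component(
    nodes: list[str],
    adj: np.ndarray,
    inflation: float,
    expansion: int,
    prune_threshold: float,
    ceil_keep: int,
    max_iter: int,
    tol: float,
) -> list[frozenset[str]]:
    n = len(nodes)
    M = adj.astype(float).copy()
    # self-loops: each node's max incident weight (1.0 for isolated nodes)
    for i in range(n):
        mx = M[i].max()
        M[i, i] = mx if mx > 0 else 1.0
    M /= M.sum(axis=0, keepdims=True)
    residual = np.inf
    for _ in range(max_iter):
        Mn = np.linalg.matrix_power(M, expansion)
        np.power(Mn, inflation, out=Mn)
        Mn[Mn < prune_threshold] = 0.0
        if ceil_keep < n:
            # keep at most ceil_keep entries per column
            for j in range(n):
                col = Mn[:, j]
                nz = np.count_nonzero(col)
                if nz > ceil_keep:
                    cutoff = np.partition(col, n - ceil_keep)[n - ceil_keep]
                    col[col < cutoff] = 0.0
        colsum = Mn.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        Mn /= colsum
        residual = float(np.max(np.abs(Mn - M)))
        M = Mn
        if residual < tol:
            break
    else:
        raise MCLConvergenceError(residual, max_iter)
    support = (M > 0) | (M > 0).T
    g = nx.from_numpy_array(support.astype(int))
    out = []
    for comp in nx.connected_components(g):
        out.append(frozenset(nodes[i] for i in comp))
    return out


def mcl_cluster(
    graph: SimilarityGraph | nx.Graph,
    inflation: float = 1.5,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    ceil_keep: int = 200,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> list[frozenset[str]]:
    """Markov clustering of a similarity graph.

    Column-normalized random-walk matrix with self-loops, iterated
    expansion/inflation/prune to convergence; run per connected component
    so clusters can never span disconnected parts of the graph.  Output
    order (and hence tie-breaking) is lexicographic by smallest member.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    g = graph.graph if isinstance(graph, SimilarityGraph) else graph
    clusters: list[frozenset[str]] = []
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            clusters.append(frozenset(nodes))
            continue
        sub = g.subgraph(nodes)
        adj = nx.to_numpy_array(sub, nodelist=nodes, weight="weight")
        clusters.extend(
            _mcl_component(nodes, adj, inflation, expansion,
                           prune_threshold, ceil_keep, max_iter, tol)
        )
    return sorted(clusters, key=lambda c: sorted(c)[0])


# ---------------------------------------------------------------------------
# Orthology classification (two-species)

ORTHOLOGY_CLASSES = [
    "one to one", "one to two", "one to many",
    "two to one", "two to two", "two to many",
    "many to one", "many to two", "many to many",
]


@dataclass
class OrthologGroup:
    group_id: str
    members: dict[str, frozenset[str]]  # species -> gene ids
    class_label: str


def _count_word(n: int) -> str:
    return {1: "one", 2: "two"}.get(n, "many")


def classify_orthologs(
    clusters: Iterable[frozenset[str]],
    species_of: Mapping[str, str],
) -> tuple[list[OrthologGroup], list[frozenset[str]]]:
    """Map each two-species cluster to one of the nine orthology classes.

    Clusters containing a single species are excluded from the groups and
    returned separately for species-specific analysis.
    """
    species = sorted(set(species_of.values()))
    if len(species) > 2:
        raise ValueError(
            f"classification is pairwise; got {len(species)} species "
            f"{species} - run per species pair"
        )
    groups, single = [], []
    for k, cluster in enumerate(clusters):
        per = {sp: frozenset(g for g in cluster if species_of[g] == sp)
               for sp in species}
        counts = {sp: len(v) for sp, v in per.items()}
        if sum(1 for c in counts.values() if c > 0) < 2:
            single.append(cluster)
            continue
        a, b = species
        label = f"{_count_word(counts[a])} to {_count_word(counts[b])}"
        groups.append(OrthologGroup(group_id=f"OG{k:05d}", members=per,
                                    class_label=label))
    return groups, single


@dataclass
class SpeciesSpecificResult:
    in_paralogues: dict[str, str]  # gene -> group id it attaches to
    single_copy: set[str]
    cross_matched: set[str]  # unassigned genes rescued by reciprocal search


def species_specific(
    genes_a: Mapping[str, str],
    genes_b: Mapping[str, str],
    groups: Sequence[OrthologGroup],
    params: ScoringParams | None = None,
    evalue_inparalogue: float = 1e-10,
    evalue_reciprocal: float = 1e-5,
) -> tuple[SpeciesSpecificResult, SpeciesSpecificResult]:
    """Partition genes outside the orthologue groups.

    Unassigned genes matching a grouped same-species gene at
    E <= ``evalue_inparalogue`` become in-paralogues of that group; the
    remainder go through a reciprocal cross-species search at
    E <= ``evalue_reciprocal``; survivors with no hit anywhere are
    single-copy species-specific genes.
    """
    if params is None:
        params = aa_params(prefilter_k=4)
    species = sorted({sp for g in groups for sp in g.members})
    by_species: dict[str, dict[str, str]] = {}
    if len(species) == 2:
        names = species
    else:
        names = ["A", "B"]
    by_species[names[0]] = dict(genes_a)
    by_species[names[1]] = dict(genes_b)

    grouped: dict[str, set[str]] = {n: set() for n in names}
    group_of: dict[str, str] = {}
    for g in groups:
        for sp, members in g.members.items():
            grouped.setdefault(sp, set()).update(members)
            for m in members:
                group_of[m] = g.group_id

    results = []
    for me, other in ((names[0], names[1]), (names[1], names[0])):
        mine = by_species[me]
        theirs = by_species[other]
        unassigned = [g for g in mine if g not in grouped.get(me, set())]
        res = SpeciesSpecificResult({}, set(), set())
        p_in = replace(params, evalue_max=evalue_inparalogue)
        p_rec = replace(params, evalue_max=evalue_reciprocal)
        for gid in unassigned:
            best = None
            for tid in grouped.get(me, set()):
                hit = align_pair(mine[gid], mine[tid], p_in, qid=gid, sid=tid)
                if hit and (best is None or hit.bit_score > best.bit_score):
                    best = hit
            if best is not None:
                res.in_paralogues[gid] = group_of[best.sid]
                continue
            cross = False
            for tid, seq in theirs.items():
                if align_pair(mine[gid], seq, p_rec, qid=gid, sid=tid):
                    cross = True
                    break
            if cross:
                res.cross_matched.add(gid)
            else:
                res.single_copy.add(gid)
        results.append(res)
    return results[0], results[1]
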