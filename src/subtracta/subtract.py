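"""Interspecific comparative subtraction.

Three procedures built on the homology kernel:

* ``transcriptome_subtract`` - the four-step skin-transcriptome
  subtraction: compile unique protein-coding transcripts of species A,
  query each against species B's transcriptome (translated, six-frame),
  rescue-requery unmatched transcripts via their reference best match,
  and report what remains as expressed-in-A-but-not-B;
* ``genome_subtract`` - multi-evidence genome subtraction: a query gene
  is called absent only when no evidence layer (genome, resequencing,
  RNA-seq, ESTs, BAC ends) yields a passing hit, with full-length
  reference substitution for flagged incomplete queries;
* ``cross_subtract`` - label-matched intersection of two candidate lists
  with per-gene provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .homology import (HomologyHit, ScoringParams, aa_params, align_pair,
                       nt_params, shares_kmer)

EVIDENCE_KINDS = ("genome", "resequencing", "rnaseq", "est", "bes")


@dataclass
class EvidenceResource:
    """One evidence layer: a named sequence collection of a known kind."""

    name: str
    kind: str
    sequences: Mapping[str, str]

    def __post_init__(self):
        if not self.name:
            raise ValueError("evidence resource needs a non-empty name")
        if self.kind not in EVIDENCE_KINDS:
            raise ValueError(
                f"evidence kind {self.kind!r} not in {EVIDENCE_KINDS}"
            )


@dataclass
class ReferenceDB:
    """Annotation reference: sequences plus an id -> gene label map."""

    sequences: Mapping[str, str]
    labels: Mapping[str, str]
    alphabet: str = "nt"

    def label_of(self, ref_id: str) -> str:
        return self.labels.get(ref_id, ref_id)


@dataclass
class SubtractionReport:
    """Outcome of one subtraction with a per-gene evidence trail."""

    query_set: str
    target_set: str
    absent: list[str]
    trail: dict[str, dict]  # label -> {step, hit, ...}
    params: dict = field(default_factory=dict)
    representatives: dict[str, str] = field(default_factory=dict)
    unannotated: list[str] = field(default_factory=list)

    @property
    def eliminated(self) -> list[str]:
        return [g for g, t in self.trail.items()
                if t["step"] in ("direct", "rescue", "evidence-layer")]


# ---------------------------------------------------------------------------
# Translated (six-frame) comparison

@lru_cache(maxsize=16384)
def six_frames(nt: str) -> tuple[str, ...]:
    """All six conceptual translations (3 forward + 3 reverse-complement)."""
    nt = nt.upper()
    rc = str(Seq(nt).reverse_complement())
    out = []
    for src in (nt, rc):
        for off in range(3):
            sub = src[off:off + 3 * ((len(src) - off) // 3)]
            out.append(str(Seq(sub).translate()))
    return tuple(out)


def translated_hit(
    query_nt: str,
    subject_nt: str,
    params: ScoringParams | None = None,
    best: bool = False,
) -> HomologyHit | None:
    """Best-scoring frame-pair local alignment over all 6x6 frame
    combinations (translated-search stand-in).  With ``best=False`` the
    first frame pair passing the E threshold is returned."""
    if params is None:
        params = aa_params(prefilter_k=4)
    top: HomologyHit | None = None
    for qf in six_frames(query_nt):
        if len(qf) < 5:
            continue
        for sf in six_frames(subject_nt):
            if len(sf) < 5:
                continue
            hit = align_pair(qf, sf, params, qid="q", sid="s")
            if hit is None:
                continue
            if not best:
                return hit
            if top is None or hit.bit_score > top.bit_score:
                top = hit
    return top


def _best_reference_match(
    query_nt: str, db: ReferenceDB, params: ScoringParams
) -> tuple[str, HomologyHit] | None:
    top = None
    for rid, rseq in db.sequences.items():
        if db.alphabet == "nt":
            hit = translated_hit(query_nt, rseq, params, best=True)
        else:
            hit = None
            for qf in six_frames(query_nt):
                if len(qf) < 5:
                    continue
                h = align_pair(qf, rseq, params, qid="q", sid=rid)
                if h and (hit is None or h.bit_score > hit.bit_score):
                    hit = h
        if hit and (top is None or hit.bit_score > top[1].bit_score):
            top = (rid, hit)
    return top


# ---------------------------------------------------------------------------
# Transcriptome subtraction (4 steps)

def transcriptome_subtract(
    a_transcripts: Mapping[str, str],
    b_transcripts: Mapping[str, str],
    reference_db: ReferenceDB | None = None,
    evalue_max: float = 1e-5,
    rescue: bool = True,
    params: ScoringParams | None = None,
    query_set: str = "A",
    target_set: str = "B",
) -> SubtractionReport:
    """Genes expressed in species A's transcriptome but not in species B's.

    Steps: (i) compile unique protein-coding transcripts of A (collapse
    transcripts sharing a reference gene label, keep the longest);
    (ii) query each against B's transcriptome, translated six-frame, at
    E <= ``evalue_max``; (iii) for unmatched transcripts with a reference
    best match, re-query that reference sequence against B (the rescue
    step); (iv) transcripts still unmatched form the absent list.
    """
    if rescue and reference_db is None:
        raise ValueError("rescue re-query requires a reference_db")
    if params is None:
        params = aa_params(prefilter_k=4)
    params = replace(params, evalue_max=evalue_max)

    # step (i): annotate and collapse to unique protein-coding transcripts
    label_best: dict[str, tuple[str, str | None]] = {}
    unannotated: list[str] = []
    if reference_db is not None:
        for tid, seq in a_transcripts.items():
            m = _best_reference_match(seq, reference_db, params)
            if m is None:
                unannotated.append(tid)
                continue
            label = reference_db.label_of(m[0])
            cur = label_best.get(label)
            if cur is None or len(seq) > len(a_transcripts[cur[0]]):
                label_best[label] = (tid, m[0])
    else:
        label_best = {tid: (tid, None) for tid in a_transcripts}

    trail: dict[str, dict] = {}
    absent: list[str] = []
    for label in sorted(label_best):
        tid, ref_id = label_best[label]
        # step (ii): direct six-frame query against B
        direct = None
        for sid in sorted(b_transcripts):
            h = translated_hit(a_transcripts[tid], b_transcripts[sid], params)
            if h is not None:
                direct = sid
                break
        if direct is not None:
            trail[label] = {"step": "direct", "hit": direct}
            continue
        # step (iii): rescue via the reference best match
        if rescue and ref_id is not None:
            rseq = reference_db.sequences[ref_id]
            rescued = None
            for sid in sorted(b_transcripts):
                if reference_db.alphabet == "nt":
                    h = translated_hit(rseq, b_transcripts[sid], params)
                else:
                    h = None
                    for sf in six_frames(b_transcripts[sid]):
                        if len(sf) >= 5 and align_pair(rseq, sf, params):
                            h = True
                            break
                if h:
                    rescued = sid
                    break
            if rescued is not None:
                trail[label] = {"step": "rescue", "hit": rescued,
                                "reference": ref_id}
                continue
            trail[label] = {"step": "absent", "hit": None,
                            "detail": "direct+rescue unmatched"}
        else:
            trail[label] = {"step": "absent", "hit": None,
                            "detail": "direct unmatched"}
        absent.append(label)
    return SubtractionReport(
        query_set=query_set, target_set=target_set, absent=absent,
        trail=trail,
        params={"evalue_max": evalue_max, "rescue": rescue},
        representatives={lb: t[0] for lb, t in label_best.items()},
        unannotated=unannotated,
    )


# ---------------------------------------------------------------------------
# Multi-evidence genome subtraction

def genome_subtract(
    query_genes: Mapping[str, str],
    target_resources: Sequence[EvidenceResource],
    evalue_max: float = 1e-5,
    rescue_db: Mapping[str, str] | None = None,
    incomplete: Iterable[str] = (),
    min_query_coverage: float | None = None,
    params: ScoringParams | None = None,
    query_set: str = "query",
    target_set: str = "target",
) -> SubtractionReport:
    """Query genes with no passing hit in ANY evidence layer are absent.

    Flagged incomplete queries are replaced by their full-length reference
    sequence (from ``rescue_db``) before the final call.  By default the
    only gate is the E threshold; ``min_query_coverage`` optionally
    requires intact-scale coverage, in which case partial (remnant-like)
    hits are recorded but do not rescue the gene.
    """
    if not target_resources:
        raise ValueError("at least one evidence resource is required")
    if params is None:
        params = nt_params(prefilter_k=12)
    params = replace(params, evalue_max=evalue_max)
    incomplete = set(incomplete)

    trail: dict[str, dict] = {}
    absent: list[str] = []
    for label in sorted(query_genes):
        seq = query_genes[label]
        substituted = False
        if label in incomplete and rescue_db and label in rescue_db:
            seq = rescue_db[label]
            substituted = True
        found = None
        partial = None
        for res in target_resources:
            for sid in sorted(res.sequences):
                hit = align_pair(seq, res.sequences[sid], params,
                                 qid=label, sid=sid)
                if hit is None:
                    continue
                if min_query_coverage is not None and hit.qcov < min_query_coverage:
                    partial = (res.name, sid, hit.qcov)
                    continue
                found = (res.name, res.kind, sid)
                break
            if found:
                break
        if found:
            trail[label] = {"step": "evidence-layer", "hit": found[2],
                            "resource": found[0], "kind": found[1],
                            "substituted": substituted}
        else:
            detail = "no hit in any evidence layer"
            entry = {"step": "absent", "hit": None, "detail": detail,
                     "substituted": substituted}
            if partial is not None:
                entry["detail"] = "partial hit below coverage"
                entry["partial"] = {"resource": partial[0], "hit": partial[1],
                                    "query_coverage": partial[2]}
            trail[label] = entry
            absent.append(label)
    return SubtractionReport(
        query_set=query_set, target_set=target_set, absent=absent,
        trail=trail,
        params={"evalue_max": evalue_max,
                "min_query_coverage": min_query_coverage,
                "resources": [r.name for r in target_resources]},
    )


# ---------------------------------------------------------------------------
# Cross subtraction

Matcher = Callable[[str, str], bool]


def cross_subtract(
    list1: Iterable[str],
    list2: Iterable[str],
    matcher: str | Matcher = "casefold",
) -> tuple[set[str], dict[str, str]]:
    """Intersection of two candidate gene lists with per-gene provenance.

    Default matcher is case-folded symbol equality; "exact" requires
    byte equality; a callable matcher(a, b) -> bool enables homology- or
    alias-aware matching.  Symmetric in its inputs.
    """
    l1, l2 = list(list1), list(list2)
    out: set[str] = set()
    provenance: dict[str, str] = {}
    if matcher == "exact":
        common = set(l1) & set(l2)
        for g in common:
            provenance[g] = "exact"
        return common, provenance
    if matcher == "casefold":
        fold2 = {str(g).strip().casefold(): g for g in l2}
        for g in l1:
            key = str(g).strip().casefold()
            if key in fold2:
                out.add(g)
                provenance[g] = "casefold"
        return out, provenance
    for g1 in l1:
        for g2 in l2:
            if matcher(g1, g2):
                out.add(g1)
                provenance[g1] = f"matched:{g2}"
                break
    return out, provenance
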