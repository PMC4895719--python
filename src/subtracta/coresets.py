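"""Orthologue core-set algebra for lineage-hallmark gene discovery.

A core set is the union, over a clade, of reference-anchored orthologue
calls (reciprocal best hits by default).  Clade-specific genes come from
a homology-aware difference of an in-clade and an out-clade core set,
followed by a presence rule (reference plus a minimum number of other
in-clade species) and exclusion searches against outgroup sequence
databases.  Intersecting the specific-versus-A and specific-versus-B
lists yields the hallmark set absent from both outgroup clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

from .homology import ScoringParams, aa_params, align_pair


def reciprocal_best_hits(
    ref_genes: Mapping[str, str],
    other_genes: Mapping[str, str],
    params: ScoringParams | None = None,
) -> dict[str, str]:
    """Reference gene -> other-species gene map of reciprocal best hits."""
    if params is None:
        params = aa_params(prefilter_k=4)

    def best(query: str, db: Mapping[str, str]) -> str | None:
        top_id, top_bit = None, -1.0
        for sid in sorted(db):
            h = align_pair(query, db[sid], params, sid=sid)
            if h and h.bit_score > top_bit:
                top_id, top_bit = sid, h.bit_score
        return top_id

    fwd = {rid: best(seq, other_genes) for rid, seq in ref_genes.items()}
    out = {}
    for rid, oid in fwd.items():
        if oid is None:
            continue
        back = best(other_genes[oid], ref_genes)
        if back == rid:
            out[rid] = oid
    return out


OrthologyCaller = Callable[[Mapping[str, str], Mapping[str, str]], dict[str, str]]


@dataclass
class CoreSet:
    """Reference-anchored orthologue core set with per-species support."""

    reference: str
    members: dict[str, set[str]]  # reference gene -> supporting species
    sequences: dict[str, str] = field(default_factory=dict)

    def support(self, gene: str) -> int:
        return len(self.members.get(gene, ()))

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


def build_core_set(
    reference: str,
    reference_genes: Mapping[str, str],
    other_species: Mapping[str, Mapping[str, str]],
    caller: OrthologyCaller | None = None,
    params: ScoringParams | None = None,
) -> CoreSet:
    """Union over species of reference-anchored orthologue calls.

    Each member records which species contributed it; genes orthologous
    nowhere are excluded.
    """
    if not other_species:
        raise ValueError("need at least one non-reference species")
    if caller is None:
        caller = lambda r, o: reciprocal_best_hits(r, o, params)
    members: dict[str, set[str]] = {}
    for sp, genes in other_species.items():
        for rid in caller(reference_genes, genes):
            members.setdefault(rid, set()).add(sp)
    return CoreSet(reference=reference, members=members,
                   sequences={g: reference_genes[g] for g in members})


def clade_specific(
    core_in: CoreSet,
    core_out: CoreSet,
    exclusion_dbs: Sequence[tuple[str, Mapping[str, str]]] = (),
    min_other_species: int = 2,
    evalue_max: float = 1e-5,
    params: ScoringParams | None = None,
) -> tuple[list[str], dict[str, dict]]:
    """In-clade core-set genes absent from the out-clade core set.

    Membership in the out-clade set is homology-aware: a gene counts as
    present there if its id is a member or its sequence matches any
    out-core sequence at E <= ``evalue_max``.  Survivors must satisfy the
    presence rule (reference + >= ``min_other_species`` supporting
    species) and must miss every exclusion database.  Returns the gene
    list and a full per-gene elimination trail.
    """
    if params is None:
        params = aa_params(prefilter_k=4)
    params = replace(params, evalue_max=evalue_max)
    kept: list[str] = []
    trail: dict[str, dict] = {}
    for gene in sorted(core_in.members):
        seq = core_in.sequences.get(gene, "")
        if gene in core_out:
            trail[gene] = {"fate": "in out-clade core set", "rule": "id"}
            continue
        hom = None
        for oid in sorted(core_out.sequences):
            if seq and align_pair(seq, core_out.sequences[oid], params,
                                  qid=gene, sid=oid):
                hom = oid
                break
        if hom is not None:
            trail[gene] = {"fate": "in out-clade core set",
                           "rule": "homology", "hit": hom}
            continue
        if core_in.support(gene) < min_other_species:
            trail[gene] = {"fate": "fails presence rule",
                           "support": core_in.support(gene)}
            continue
        excluded = None
        for name, db in exclusion_dbs:
            for sid in sorted(db):
                if seq and align_pair(seq, db[sid], params, qid=gene, sid=sid):
                    excluded = (name, sid)
                    break
            if excluded:
                break
        if excluded:
            trail[gene] = {"fate": "matches exclusion db",
                           "db": excluded[0], "hit": excluded[1]}
            continue
        trail[gene] = {"fate": "clade-specific"}
        kept.append(gene)
    return kept, trail


def hallmark_intersect(
    specific_vs_a: Iterable[str],
    specific_vs_b: Iterable[str],
) -> tuple[list[str], dict[str, str]]:
    """Genes specific against BOTH outgroup clades (shared namespace)."""
    a, b = set(specific_vs_a), set(specific_vs_b)
    genes = sorted(a & b)
    return genes, {g: "absent from both outgroup clades" for g in genes}
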