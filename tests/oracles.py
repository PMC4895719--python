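"""Independent reference implementations used only as test oracles.

Deliberately naive, written from the primary definitions rather than by
refactoring the package code, so they stay an independent check.
"""

import itertools

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

_T = unambiguous_dna_by_id[1]
_BASES = "ACGT"


def _aa(codon):
    return "*" if codon in _T.stop_codons else _T.forward_table[codon]


def ng86_oracle(cds1, cds2):
    """Nei-Gojobori 1986, coded directly from the published formulas."""
    assert len(cds1) == len(cds2) and len(cds1) % 3 == 0
    co1 = [cds1[i:i + 3] for i in range(0, len(cds1), 3)]
    co2 = [cds2[i:i + 3] for i in range(0, len(cds2), 3)]

    def syn_sites(codon):
        total = 0.0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if _aa(alt) != "*" and _aa(alt) == _aa(codon):
                    total += 1.0 / 3.0
        return total

    S = 0.5 * (sum(map(syn_sites, co1)) + sum(map(syn_sites, co2)))
    N = 3.0 * len(co1) - S

    sd = nd = 0.0
    for c1, c2 in zip(co1, co2):
        pos = [i for i in range(3) if c1[i] != c2[i]]
        if not pos:
            continue
        outcomes = []
        for perm in itertools.permutations(pos):
            cur, s, n, ok = c1, 0, 0, True
            for p in perm:
                nxt = cur[:p] + c2[p] + cur[p + 1:]
                if _aa(nxt) == "*":
                    ok = False
                    break
                if _aa(cur) == _aa(nxt):
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                outcomes.append((s, n))
        if not outcomes:
            for perm in itertools.permutations(pos):
                cur, s, n = c1, 0, 0
                for p in perm:
                    nxt = cur[:p] + c2[p] + cur[p + 1:]
                    if _aa(cur) != "*" and _aa(cur) == _aa(nxt):
                        s += 1
                    else:
                        n += 1
                    cur = nxt
                outcomes.append((s, n))
        sd += sum(o[0] for o in outcomes) / len(outcomes)
        nd += sum(o[1] for o in outcomes) / len(outcomes)

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)

    return jc(nd / N if N else 0.0), jc(sd / S if S else 0.0)  # (Ka, Ks)


def bh_oracle(pvals):
    """Benjamini-Hochberg by the literal definition:
    sort, q_(i) = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0
        )
    q = np.empty(m)
    q[order] = q_sorted
    return q


def transitive_closure_oracle(ids, edges):
    """Single-linkage clusters by explicit reachability (DFS)."""
    adj = {i: set() for i in ids}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, out = set(), []
    for start in ids:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        out.append(frozenset(comp))
    return sorted(out, key=lambda c: sorted(c)[0])


def smith_waterman_oracle(a, b, match=1.0, mismatch=-2.0,
                          gap_open=-5.0, gap_extend=-2.0):
    """Affine-gap local alignment best score by explicit dynamic programming."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (left moves)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (up moves)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
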