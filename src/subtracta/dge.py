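"""Scale-regeneration differential expression.

Single pooled library per time point (the study design this emulates
pools nine fish per time point), so the default test is a two-proportion
exact-style count test: conditional on the two libraries' total, the
focal gene's count is binomial, and the doubled smaller tail gives a
two-sided p-value.  Fold changes are computed on RPKM with a pseudocount;
calls require both a minimum fold change and a Benjamini-Hochberg FDR
within each contrast; the study-level DE set is the union over
timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Genes x samples raw counts plus gene lengths and time metadata."""

    counts: np.ndarray
    genes: list[str]
    samples: list[str]
    lengths: np.ndarray  # bp per gene
    timepoint_of: dict[str, str] = field(default_factory=dict)
    library_sizes: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.lengths = np.asarray(self.lengths)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match genes x samples")
        if np.any(self.lengths <= 0):
            raise ValueError("gene lengths must be > 0")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.timepoint_of:
            self.timepoint_of = {s: s for s in self.samples}
        # library size = column sum, recomputed unless supplied
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = np.asarray(self.library_sizes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.genes, columns=self.samples)
        df.index.name = "gene"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, lengths: Mapping[str, int],
                   timepoint_of: Mapping[str, str] | None = None
                   ) -> "ExpressionMatrix":
        genes = list(df.index)
        return cls(counts=df.to_numpy(), genes=genes,
                   samples=list(df.columns),
                   lengths=np.array([lengths[g] for g in genes]),
                   timepoint_of=dict(timepoint_of or {}))

    def pooled_by_timepoint(self) -> "ExpressionMatrix":
        """Sum samples sharing a timepoint into one pooled column."""
        tps = list(dict.fromkeys(self.timepoint_of[s] for s in self.samples))
        cols = []
        for tp in tps:
            idx = [i for i, s in enumerate(self.samples)
                   if self.timepoint_of[s] == tp]
            cols.append(self.counts[:, idx].sum(axis=1))
        return ExpressionMatrix(
            counts=np.column_stack(cols), genes=self.genes, samples=tps,
            lengths=self.lengths, timepoint_of={t: t for t in tps},
        )


# ---------------------------------------------------------------------------
# Read-mapping rule filter

def map_filter(
    alignments: pd.DataFrame,
    transcript_lengths: Mapping[str, int],
    min_align_frac: float = 0.90,
    max_mismatches: int = 2,
) -> pd.Series:
    """Count reads per transcript under the mapping rule.

    A read counts toward a transcript only if its aligned length covers at
    least ``min_align_frac`` of the transcript length and it has at most
    ``max_mismatches`` mismatches; reads passing for more than one
    transcript are ambiguous and dropped.

    ``alignments`` columns: read, transcript, aligned_length, mismatches.
    """
    df = alignments.copy()
    req = df["transcript"].map(transcript_lengths).astype(float) * min_align_frac
    ok = (df["aligned_length"] >= req) & (df["mismatches"] <= max_mismatches)
    df = df[ok]
    per_read = df.groupby("read")["transcript"].nunique()
    unambiguous = per_read[per_read == 1].index
    df = df[df["read"].isin(unambiguous)].drop_duplicates(["read", "transcript"])
    counts = df.groupby("transcript").size()
    return counts.reindex(sorted(transcript_lengths), fill_value=0)


# ---------------------------------------------------------------------------
# RPKM

def rpkm(
    counts: np.ndarray,
    lengths: np.ndarray,
    library_sizes: np.ndarray,
) -> np.ndarray:
    """Reads per kilobase of exon model per million mapped reads."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if np.any(library_sizes == 0):
        raise ValueError("zero library size")
    return counts / (lengths[:, None] / 1e3) / (library_sizes[None, :] / 1e6)


def rpkm_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    vals = rpkm(matrix.counts, matrix.lengths, matrix.library_sizes)
    return pd.DataFrame(vals, index=matrix.genes, columns=matrix.samples)


# ---------------------------------------------------------------------------
# Differential expression

def binomial_proportion_test(
    c_t: np.ndarray, c_0: np.ndarray, lib_t: float, lib_0: float
) -> np.ndarray:
    """Two-sided exact-style test of a gene's count split across two
    libraries: conditional on c_t + c_0 the focal count is binomial with
    p = lib_t / (lib_t + lib_0); the doubled smaller tail is the p-value."""
    n = np.asarray(c_t) + np.asarray(c_0)
    p0 = lib_t / (lib_t + lib_0)
    lower = stats.binom.cdf(c_t, n, p0)
    upper = stats.binom.sf(np.asarray(c_t) - 1, n, p0)
    p = 2.0 * np.minimum(lower, upper)
    p = np.where(n == 0, 1.0, p)
    return np.minimum(p, 1.0)


CountTest = Callable[[np.ndarray, np.ndarray, float, float], np.ndarray]


def call_de(
    matrix: ExpressionMatrix,
    control_timepoint: str = "0h",
    fold_min: float = 2.0,
    fdr_max: float = 0.05,
    pseudocount: float = 1.0,
    test: CountTest = binomial_proportion_test,
) -> pd.DataFrame:
    """Per-timepoint differential expression calls against the control.

    Returns a frame (gene, timepoint, log2fc, p, q, status) with BH
    correction applied within each contrast.  up/down require both
    |fold| >= ``fold_min`` and q < ``fdr_max``; all-zero genes are 'ns'
    with defined values.
    """
    pooled = matrix.pooled_by_timepoint()
    if control_timepoint not in pooled.samples:
        raise ValueError(
            f"control timepoint {control_timepoint!r} not present "
            f"(have {pooled.samples})"
        )
    r = rpkm(pooled.counts, pooled.lengths, pooled.library_sizes)
    ci = pooled.samples.index(control_timepoint)
    out = []
    log2_fold_min = np.log2(fold_min)
    for j, tp in enumerate(pooled.samples):
        if j == ci:
            continue
        c_t = pooled.counts[:, j]
        c_0 = pooled.counts[:, ci]
        p = test(c_t, c_0, float(pooled.library_sizes[j]),
                 float(pooled.library_sizes[ci]))
        q = multipletests(p, method="fdr_bh")[1]
        log2fc = np.log2((r[:, j] + pseudocount) / (r[:, ci] + pseudocount))
        status = np.full(len(p), "ns", dtype=object)
        sig = q < fdr_max
        status[sig & (log2fc >= log2_fold_min)] = "up"
        status[sig & (log2fc <= -log2_fold_min)] = "down"
        out.append(pd.DataFrame(
            {"gene": pooled.genes, "timepoint": tp, "log2fc": log2fc,
             "p": p, "q": q, "status": status}
        ))
    return pd.concat(out, ignore_index=True)


def de_gene_union(calls: pd.DataFrame) -> set[str]:
    """The study-level DE set: union over timepoints of significant genes."""
    return set(calls.loc[calls["status"] != "ns", "gene"])


def de_direction(calls: pd.DataFrame) -> dict[str, str]:
    """Dominant direction per DE gene (by count of significant timepoints)."""
    sig = calls[calls["status"] != "ns"]
    out = {}
    for gene, sub in sig.groupby("gene"):
        ups = (sub["status"] == "up").sum()
        downs = (sub["status"] == "down").sum()
        out[gene] = "up" if ups >= downs else "down"
    return out


def induction_profile(
    matrix: ExpressionMatrix,
    genes: Iterable[str],
    control_timepoint: str = "0h",
    calls: pd.DataFrame | None = None,
    **de_kwargs,
) -> tuple[pd.DataFrame, dict[str, str | None]]:
    """RPKM-by-timepoint table plus first-induction timepoint per gene.

    First induction is the earliest timepoint with a significant 'up'
    call; ``None`` for never-induced genes.
    """
    genes = list(genes)
    unknown = sorted(set(genes) - set(matrix.genes))
    if unknown:
        raise ValueError(f"unknown gene ids: {unknown}")
    pooled = matrix.pooled_by_timepoint()
    table = rpkm_matrix(pooled).loc[genes]
    if calls is None:
        calls = call_de(matrix, control_timepoint, **de_kwargs)
    tp_order = {tp: i for i, tp in enumerate(pooled.samples)}
    first: dict[str, str | None] = {g: None for g in genes}
    ups = calls[(calls["status"] == "up") & calls["gene"].isin(genes)]
    for gene, sub in ups.groupby("gene"):
        first[gene] = min(sub["timepoint"], key=lambda t: tp_order[t])
    return table, first
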