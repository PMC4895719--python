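"""Genome QC and variation summaries.

SNP quality filtering, 100-kb density windows with per-chromosome
hotspots, genetic-map/scaffold concordance, BAC mate-pair validation,
the 100-bp heterozygosity bin encoding consumed by coalescent-based
demographic inference, and the generation-time scaling formula
g = a + s/(1 - s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

SNP_THRESHOLDS = dict(base_quality=20.0, mapping_quality=20.0,
                      maf=0.05, depth=6)
WINDOW_BP = 100_000
MATE_MAX_INSERT = 300_000
PSMC_BIN_BP = 100
PSMC_MUTATION_RATE = 2.5e-8  # per site per generation (medaka-derived)


# ---------------------------------------------------------------------------
# SNP filtering

def filter_snps(
    records: pd.DataFrame,
    base_quality: float = SNP_THRESHOLDS["base_quality"],
    mapping_quality: float = SNP_THRESHOLDS["mapping_quality"],
    maf: float = SNP_THRESHOLDS["maf"],
    depth: int = SNP_THRESHOLDS["depth"],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep records with baseQ >= 20, mapQ >= 20, MAF >= 5% and depth >= 6
    (inclusive thresholds, each configurable).  Returns the passing frame
    and counts of each failure reason."""
    req = ["base_quality", "mapping_quality", "maf", "depth"]
    missing = [c for c in req if c not in records.columns]
    if missing:
        raise ValueError(f"SNP table lacks columns {missing}")
    if len(records) and (records["maf"].min() < 0 or records["maf"].max() > 0.5):
        raise ValueError("minor-allele frequency outside [0, 0.5]")
    if len(records) and records["depth"].min() < 0:
        raise ValueError("negative sequencing depth")
    fails = {
        "base_quality": int((records["base_quality"] < base_quality).sum()),
        "mapping_quality": int((records["mapping_quality"] < mapping_quality).sum()),
        "maf": int((records["maf"] < maf).sum()),
        "depth": int((records["depth"] < depth).sum()),
    }
    ok = (
        (records["base_quality"] >= base_quality)
        & (records["mapping_quality"] >= mapping_quality)
        & (records["maf"] >= maf)
        & (records["depth"] >= depth)
    )
    return records[ok].copy(), fails


# ---------------------------------------------------------------------------
# Window densities and hotspots

def window_density(
    snps: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    window_bp: int = WINDOW_BP,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """SNP counts in half-open windows [k*w, (k+1)*w) per chromosome.

    Counts conserve the total number of SNPs; the hotspot is the argmax
    window per chromosome, ties broken toward the lowest coordinate.
    """
    rows = []
    hotspots: dict[str, int] = {}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_bins = max(1, math.ceil(length / window_bp))
        pos = snps.loc[snps["chrom"] == chrom, "pos"].to_numpy()
        bins = pos // window_bp
        counts = np.bincount(bins.astype(int), minlength=n_bins)
        for k in range(n_bins):
            rows.append({"chrom": chrom, "bin": k, "start": k * window_bp,
                         "end": min((k + 1) * window_bp, length),
                         "count": int(counts[k])})
        hotspots[chrom] = int(np.argmax(counts))  # argmax takes first tie
    return pd.DataFrame(rows), hotspots


# ---------------------------------------------------------------------------
# Genetic-map concordance

def map_concordance(
    markers: pd.DataFrame,
    min_markers: int = 2,
    tolerance_cm: float = 0.5,
) -> pd.DataFrame:
    """Per-scaffold concordance between physical and genetic positions.

    Expects columns: marker, linkage_group, cm, scaffold, bp.  For each
    scaffold with >= ``min_markers`` markers: the linkage groups touched,
    the cM span, a Spearman-style monotonicity (rho of bp vs cM), the
    assigned orientation, and breakpoint flags.  Scaffolds mixing linkage
    groups are chimeric; backward cM steps larger than ``tolerance_cm``
    (after orienting) flag candidate mis-assembly breakpoints.
    """
    rows = []
    for scaffold, sub in markers.groupby("scaffold"):
        if len(sub) < min_markers:
            continue
        sub = sub.sort_values("bp")
        lgs = sorted(sub["linkage_group"].unique())
        chimeric = len(lgs) > 1
        cm = sub["cm"].to_numpy(dtype=float)
        span = float(cm.max() - cm.min())
        if len(sub) > 1 and not chimeric and np.ptp(cm) > 0:
            rho = stats.spearmanr(sub["bp"], cm).statistic
            if np.isnan(rho):
                rho = 0.0
        else:
            rho = 0.0
        orientation = "+" if rho >= 0 else "-"
        steps = np.diff(cm if rho >= 0 else cm[::-1])
        breakpoints = [int(i) for i in np.where(steps < -tolerance_cm)[0]]
        congruent = (not chimeric) and not breakpoints
        rows.append({
            "scaffold": scaffold, "n_markers": len(sub),
            "linkage_groups": ",".join(str(x) for x in lgs),
            "span_cm": span, "rho": float(rho), "orientation": orientation,
            "chimeric": chimeric, "breakpoints": breakpoints,
            "congruent": congruent,
        })
    return pd.DataFrame(rows)


def kb_per_cm(markers: pd.DataFrame) -> pd.DataFrame:
    """Physical-to-genetic scale per linkage group: anchored bp span / cM span."""
    rows = []
    for lg, sub in markers.groupby("linkage_group"):
        bp_span = float(sub["bp"].max() - sub["bp"].min())
        cm_span = float(sub["cm"].max() - sub["cm"].min())
        rows.append({"linkage_group": lg,
                     "kb_per_cm": bp_span / 1e3 / cm_span if cm_span else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BAC mate pairs

@dataclass
class MatePairSummary:
    inserts: pd.Series  # co-scaffold implied insert sizes (bp)
    outliers: pd.DataFrame  # insert > max_insert
    cross_scaffold: pd.DataFrame

    @property
    def mean_insert(self) -> float:
        return float(self.inserts.mean()) if len(self.inserts) else float("nan")


def matepair_check(
    pairs: pd.DataFrame,
    max_insert: int = MATE_MAX_INSERT,
) -> MatePairSummary:
    """Implied insert sizes of co-scaffold mate pairs; pairs spanning
    scaffolds are reported separately and excluded from the histogram.

    Expects columns: clone, scaffold1, pos1, scaffold2, pos2.
    """
    same = pairs["scaffold1"] == pairs["scaffold2"]
    co = pairs[same].copy()
    co["insert"] = (co["pos2"] - co["pos1"]).abs()
    outliers = co[co["insert"] > max_insert]
    return MatePairSummary(
        inserts=co.set_index("clone")["insert"],
        outliers=outliers,
        cross_scaffold=pairs[~same].copy(),
    )


# ---------------------------------------------------------------------------
# Heterozygosity bin encoding for demographic inference

def psmc_encode(
    consensus_states: str,
    bin_bp: int = PSMC_BIN_BP,
    missing_max_frac: float = 0.9,
) -> str:
    """Encode per-site states into 100-bp heterozygosity bins.

    ``consensus_states`` uses 'H' (heterozygous site), 'O' (homozygous)
    and 'N' (missing).  A bin is 'K' if it holds >= 1 heterozygote,
    'N' if its missing fraction exceeds ``missing_max_frac``, else 'T'.
    Output length is ceil(len / bin_bp).
    """
    bad = set(consensus_states.upper()) - set("HON")
    if bad:
        raise ValueError(f"unknown consensus state(s) {sorted(bad)}")
    s = consensus_states.upper()
    out = []
    for i in range(0, len(s), bin_bp):
        chunk = s[i:i + bin_bp]
        if chunk.count("N") > missing_max_frac * len(chunk):
            out.append("N")
        elif "H" in chunk:
            out.append("K")
        else:
            out.append("T")
    return "".join(out)


def write_psmcfa(encoded: Mapping[str, str], path, width: int = 60) -> None:
    lines = []
    for name in sorted(encoded):
        lines.append(f">{name}")
        s = encoded[name]
        lines.extend(s[i:i + width] for i in range(0, len(s), width))
    Path(path).write_text("\n".join(lines) + "\n")


def psmc_scaling_params(generation_time_years: float = 7.0,
                        mutation_rate: float = PSMC_MUTATION_RATE) -> dict:
    """Time-scaling constants surfaced for the external coalescent tool."""
    return {"-u": mutation_rate, "-g": generation_time_years}


# ---------------------------------------------------------------------------
# Generation time

def generation_time(maturation_age_years: float, adult_survival: float) -> float:
    """g = a + s / (1 - s): sexual maturation age plus the expected number
    of further breeding seasons implied by adult survival ``s``."""
    if not 0 <= adult_survival < 1:
        raise ValueError(
            f"adult survival must be in [0, 1), got {adult_survival}"
        )
    return maturation_age_years + adult_survival / (1.0 - adult_survival)
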