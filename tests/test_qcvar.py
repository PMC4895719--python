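"""SNP filters, windows/hotspots, map concordance, mates, encoding."""

import numpy as np
import pandas as pd
import pytest

from subtracta.qcvar import (filter_snps, generation_time, kb_per_cm,
                             map_concordance, matepair_check, psmc_encode,
                             window_density)


def _snps(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "base_quality",
                                       "mapping_quality", "maf", "depth"])


# ---------------------------------------------------------------------------
# filter_snps

def test_thresholds_are_inclusive():
    df = _snps([("c1", 10, 20.0, 20.0, 0.05, 6)])
    passing, fails = filter_snps(df)
    assert len(passing) == 1 and sum(fails.values()) == 0


@pytest.mark.parametrize("col,val", [
    ("base_quality", 19.9), ("mapping_quality", 19.9),
    ("maf", 0.049), ("depth", 5),
])
def test_each_threshold_fails_just_below(col, val):
    row = {"chrom": "c1", "pos": 1, "base_quality": 30.0,
           "mapping_quality": 30.0, "maf": 0.2, "depth": 10}
    row[col] = val
    passing, fails = filter_snps(pd.DataFrame([row]))
    assert len(passing) == 0 and fails[col] == 1


def test_empty_input_empty_output():
    passing, _ = filter_snps(_snps([]))
    assert passing.empty


def test_filter_is_idempotent_and_order_independent(rng):
    df = _snps([("c1", int(p), float(b), float(m), float(f), int(d))
                for p, b, m, f, d in zip(
                    rng.integers(0, 1_000_000, 200),
                    rng.uniform(0, 40, 200), rng.uniform(0, 40, 200),
                    rng.uniform(0, 0.5, 200), rng.integers(0, 20, 200))])
    once, _ = filter_snps(df)
    twice, _ = filter_snps(once)
    assert once.equals(twice)
    shuffled, _ = filter_snps(df.sample(frac=1, random_state=0))
    assert sorted(shuffled["pos"]) == sorted(once["pos"])


def test_invalid_maf_rejected():
    with pytest.raises(ValueError, match="frequency"):
        filter_snps(_snps([("c1", 1, 30.0, 30.0, 0.7, 10)]))


# ---------------------------------------------------------------------------
# window_density

def test_half_open_window_boundary():
    df = _snps([("c1", 100_000, 30, 30, 0.2, 10)])
    windows, _ = window_density(df, {"c1": 300_000})
    w = windows.set_index("bin")["count"]
    assert w[0] == 0 and w[1] == 1


def test_counts_conserve_totals(rng):
    df = _snps([("c1", int(p), 30, 30, 0.2, 10)
                for p in rng.integers(0, 1_000_000, 500)])
    windows, _ = window_density(df, {"c1": 1_000_000})
    assert windows["count"].sum() == 500


def test_uniform_ties_pick_first_bin():
    df = _snps([("c1", p, 30, 30, 0.2, 10)
                for p in (50_000, 150_000, 250_000)])
    _, hotspots = window_density(df, {"c1": 300_000})
    assert hotspots["c1"] == 0


def test_planted_hotspot_found():
    rows = [("c1", 10_000 * i, 30, 30, 0.2, 10) for i in range(30)]
    rows += [("c1", 710_000 + 7 * i, 30, 30, 0.2, 10) for i in range(30)]
    _, hotspots = window_density(_snps(rows), {"c1": 1_000_000})
    assert hotspots["c1"] == 7


# ---------------------------------------------------------------------------
# map_concordance

def _markers(rows):
    return pd.DataFrame(rows, columns=["marker", "linkage_group", "cm",
                                       "scaffold", "bp"])


def test_collinear_scaffold_congruent():
    rows = [(f"m{i}", 1, float(i), "s1", 10_000 * i) for i in range(10)]
    rep = map_concordance(_markers(rows))
    r = rep.iloc[0]
    assert r["congruent"] and not r["chimeric"] and r["orientation"] == "+"
    assert r["span_cm"] == 9.0


def test_reversed_scaffold_gets_minus_orientation():
    rows = [(f"m{i}", 1, float(9 - i), "s1", 10_000 * i) for i in range(10)]
    r = map_concordance(_markers(rows)).iloc[0]
    assert r["orientation"] == "-" and r["congruent"]


def test_two_linkage_groups_flagged_chimeric():
    rows = [(f"m{i}", 1, float(i), "s1", 10_000 * i) for i in range(5)]
    rows += [(f"n{i}", 2, float(i), "s1", 10_000 * (5 + i)) for i in range(5)]
    r = map_concordance(_markers(rows)).iloc[0]
    assert r["chimeric"] and not r["congruent"]


def test_translocated_segment_breakpoint_interval():
    cm = [0, 1, 2, 3, 4, 20, 21, 22, 5, 6]  # 3-marker segment out of place
    rows = [(f"m{i}", 1, float(c), "s1", 10_000 * i) for i, c in enumerate(cm)]
    r = map_concordance(_markers(rows)).iloc[0]
    assert not r["congruent"]
    assert 7 in r["breakpoints"]  # the 22 -> 5 backward step


def test_chimera_and_clean_detection_rates(rng):
    rows = []
    for s in range(40):  # clean scaffolds with mild cM jitter
        base = rng.uniform(0, 50)
        for i in range(6):
            rows.append((f"c{s}_{i}", 1, base + i + rng.normal(0, 0.05),
                         f"clean{s}", 10_000 * i))
    for s in range(20):  # chimeric: two linkage groups on one scaffold
        for i in range(3):
            rows.append((f"x{s}_{i}", 1, float(i), f"chim{s}", 10_000 * i))
            rows.append((f"y{s}_{i}", 2, float(i), f"chim{s}",
                         10_000 * (3 + i)))
    rep = map_concordance(_markers(rows)).set_index("scaffold")
    chim = rep[rep.index.str.startswith("chim")]
    clean = rep[rep.index.str.startswith("clean")]
    assert (~chim["congruent"]).all()  # 100% of chimeras flagged
    assert (~clean["congruent"]).mean() <= 0.05


def test_kb_per_cm_scale():
    rows = [("m0", 1, 0.0, "s1", 0), ("m1", 1, 100.0, "s1", 21_840_000)]
    out = kb_per_cm(_markers(rows))
    assert out.iloc[0]["kb_per_cm"] == pytest.approx(218.4)


# ---------------------------------------------------------------------------
# matepair_check

def _pairs(rows):
    return pd.DataFrame(rows, columns=["clone", "scaffold1", "pos1",
                                       "scaffold2", "pos2"])


def test_insert_outlier_boundary():
    df = _pairs([("k1", "s1", 0, "s1", 300_000),
                 ("k2", "s1", 0, "s1", 300_001)])
    summ = matepair_check(df)
    assert list(summ.outliers["clone"]) == ["k2"]


def test_cross_scaffold_pairs_reported_separately():
    df = _pairs([("k1", "s1", 0, "s2", 100)])
    summ = matepair_check(df)
    assert len(summ.inserts) == 0
    assert list(summ.cross_scaffold["clone"]) == ["k1"]


def test_simulated_library_mean_recovered(rng):
    n = 5000
    inserts = rng.normal(161_000, 20_000, n).astype(int)
    df = _pairs([(f"k{i}", "s1", 0, "s1", int(x))
                 for i, x in enumerate(np.abs(inserts))])
    summ = matepair_check(df)
    se = 20_000 / np.sqrt(n)
    assert abs(summ.mean_insert - 161_000) < 2 * se + 1


# ---------------------------------------------------------------------------
# psmc_encode + generation time

def test_all_homozygous_encodes_T():
    assert psmc_encode("O" * 1000) == "T" * 10


def test_single_het_marks_its_bin():
    s = ["O"] * 1000
    s[250] = "H"
    assert psmc_encode("".join(s)) == "TT" + "K" + "T" * 7


def test_bin_count_is_ceiling():
    assert len(psmc_encode("O" * 950)) == 10


def test_mostly_missing_bin_is_N():
    assert psmc_encode("N" * 95 + "O" * 5) == "N"


def test_unknown_state_rejected():
    with pytest.raises(ValueError, match="state"):
        psmc_encode("OXO")


@pytest.mark.parametrize("a,s,expected", [
    (3.0, 0.80, 7.0), (5.0, 0.0, 5.0), (2.0, 0.5, 3.0),
])
def test_generation_time_closed_form(a, s, expected):
    assert generation_time(a, s) == pytest.approx(expected)


def test_generation_time_survival_bounds():
    with pytest.raises(ValueError):
        generation_time(3, 1.0)
    with pytest.raises(ValueError):
        generation_time(3, -0.1)
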