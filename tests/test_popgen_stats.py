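import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import musadmix as mx
from musadmix.genotypes import MISSING, GenotypeMatrix
from musadmix import popgen_stats as pg

from conftest import make_geno


def random_geno(rng, n_sites=40, panel_sizes=None, missing_rate=0.0):
    panel_sizes = panel_sizes or {"A": 3, "B": 2, "C": 4, "D": 2}
    samples, panels = [], []
    for p, n in panel_sizes.items():
        samples += [f"{p}{i}" for i in range(n)]
        panels += [p] * n
    dosage = rng.integers(0, 3, size=(n_sites, len(samples))).astype(np.int8)
    if missing_rate:
        dosage[rng.random(dosage.shape) < missing_rate] = MISSING
    return GenotypeMatrix(
        chrom=np.full(n_sites, "chr1", dtype=object),
        pos=np.arange(1, n_sites + 1),
        dosage=dosage,
        samples=samples,
        panels=pd.Series(panels, index=samples),
    )


# ------------------------------------------------------------ frequencies


def test_allele_frequency_basics():
    g = GenotypeMatrix(
        chrom=np.array(["chr1"] * 3, dtype=object),
        pos=np.array([1, 2, 3]),
        dosage=np.array(
            [[1, 0, 1, 2], [MISSING, 0, 1, 2], [MISSING, MISSING, MISSING, 0]],
            dtype=np.int8,
        ),
        samples=["a1", "b1", "b2", "b3"],
        panels=pd.Series({"a1": "A", "b1": "B", "b2": "B", "b3": "B"}),
    )
    # one heterozygous diploid -> 0.5
    assert mx.allele_frequency(g, "A")[0] == 0.5
    # dosages (0,1,2) over 3 samples -> 3/6
    assert mx.allele_frequency(g, "B")[0] == 0.5
    # missing excluded per site, all-missing undefined (NaN, not 0)
    f_a = mx.allele_frequency(g, "A")
    assert np.isnan(f_a[1]) and np.isnan(f_a[2])
    with pytest.raises(KeyError):
        mx.allele_frequency(g, "Z")


# ------------------------------------------------------------------- f4


def test_f4_zero_when_cd_identical():
    rng = np.random.default_rng(0)
    g = random_geno(rng)
    # make D columns an exact copy of C's first two columns
    c_cols = g.panel_columns("C")[:2]
    d_cols = g.panel_columns("D")
    g.dosage[:, d_cols] = g.dosage[:, c_cols]
    # C: use only the duplicated samples so freqs match exactly
    g2_panels = g.panels.copy()
    keep = [s for s in g.samples if not s.startswith("C") or s in ("C0", "C1")]
    idx = [g.sample_index(s) for s in keep]
    g2 = GenotypeMatrix(
        chrom=g.chrom, pos=g.pos, dosage=g.dosage[:, idx], samples=keep,
        panels=g2_panels[keep],
    )
    f4, n = mx.patterson_f4(g2, ("A", "B", "C", "D"))
    assert f4 == pytest.approx(0.0, abs=1e-12)
    assert n == g2.n_sites


def test_f4_two_site_hand_example():
    # site1 freqs (1, 0, 1, 0); site2 freqs (0.5, 0.5, 0.3, 0.9)
    g = make_geno(
        [
            {"A": 1.0, "B": 0.0, "C": 1.0, "D": 0.9},
            {"A": 0.5, "B": 0.5, "C": 0.3, "D": 0.9},
        ],
        {"A": 1, "B": 1, "C": 5, "D": 5},
    )
    # adjust site1 D frequency to exactly 0
    g.dosage[0, g.panel_columns("D")] = 0
    f4, n = mx.patterson_f4(g, ("A", "B", "C", "D"))
    # (1*1 + 0*(-0.6)) / 2 = 0.5
    assert f4 == pytest.approx(0.5, abs=1e-12)
    assert n == 2


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_f4_antisymmetry(seed):
    g = random_geno(np.random.default_rng(seed), missing_rate=0.1)
    try:
        f_abcd, _ = mx.patterson_f4(g, ("A", "B", "C", "D"))
        f_abdc, _ = mx.patterson_f4(g, ("A", "B", "D", "C"))
        f_bacd, _ = mx.patterson_f4(g, ("B", "A", "C", "D"))
    except ValueError:
        return  # no usable sites at this missingness draw
    assert f_abcd == pytest.approx(-f_abdc, abs=1e-12)
    assert f_abcd == pytest.approx(-f_bacd, abs=1e-12)


def test_f4_requires_usable_sites_and_distinct_labels():
    g = random_geno(np.random.default_rng(1))
    g.dosage[:, g.panel_columns("A")] = MISSING
    with pytest.raises(ValueError, match="usable"):
        mx.patterson_f4(g, ("A", "B", "C", "D"))
    with pytest.raises(ValueError, match="distinct"):
        mx.patterson_f4(random_geno(np.random.default_rng(2)), ("A", "A", "C", "D"))


# ------------------------------------------------------------- f4 ratio


def oriented_quartet(x_freq, n_sites=50):
    """Panels with exact frequencies oriented so the f4 denominator > 0."""
    return make_geno(
        [
            {"KAZ": 0.9, "SPR": 0.1, "KOR": 0.8, "IND": 0.2, "X": x_freq}
            for _ in range(n_sites)
        ],
        {"KAZ": 5, "SPR": 5, "KOR": 5, "IND": 5, "X": 5},
    )


def test_alpha_is_one_when_x_matches_kor():
    g = oriented_quartet(0.8)  # X frequency-identical to KOR
    alpha = mx.f4_ratio_alpha(
        g, "X", quartet=("KAZ", "SPR", "KOR", "IND"), cap=False
    )
    # numerator == denominator exactly; no capping involved
    assert alpha == pytest.approx(1.0, abs=1e-12)


def test_alpha_is_zero_when_x_matches_ind():
    g = oriented_quartet(0.2)  # X frequency-identical to IND
    alpha = mx.f4_ratio_alpha(g, "X", quartet=("KAZ", "SPR", "KOR", "IND"))
    assert alpha == pytest.approx(0.0, abs=1e-12)


def test_alpha_nonpositive_denominator_raises():
    g = oriented_quartet(0.8)
    # swapping KOR and IND flips the denominator sign
    with pytest.raises(ValueError, match="denominator"):
        mx.f4_ratio_alpha(g, "X", quartet=("KAZ", "SPR", "IND", "KOR"))


def test_alpha_genome_wide_recovery(small_cohort):
    alpha = mx.f4_ratio_alpha(small_cohort.geno, "FOCAL")
    truth = small_cohort.truth_sample["ancestry"].mean()
    assert abs(alpha - truth) < 0.05


# --------------------------------------------------------- windowed alpha


def constant_ratio_geno(n_sites, ratio, window_bp=1000):
    """Sites where per-site alpha equals ``ratio`` exactly.

    Frequencies: KAZ=1, SPR=0, IND=0, KOR=0.5, X=0.5*ratio.
    """
    return make_geno(
        [
            {"KAZ": 1.0, "SPR": 0.0, "KOR": 0.5, "IND": 0.0, "X": 0.5 * ratio}
            for _ in range(n_sites)
        ],
        {"KAZ": 1, "SPR": 1, "KOR": 2, "IND": 1, "X": 100},
        positions=np.linspace(1, window_bp - 1, n_sites).astype(int),
    )


def test_window_with_99_snvs_is_excluded():
    g = constant_ratio_geno(99, 0.5)
    tab = mx.windowed_alpha(g, "X", window_bp=1000, min_snvs=100,
                            chrom_lengths={"chr1": 1000})
    assert tab["status"].tolist() == ["too_few_snvs"]
    assert np.isnan(tab["alpha"].iloc[0])
    g2 = constant_ratio_geno(100, 0.5)
    tab2 = mx.windowed_alpha(g2, "X", window_bp=1000, min_snvs=100,
                             chrom_lengths={"chr1": 1000})
    assert tab2["status"].tolist() == ["pass"]
    assert tab2["alpha"].iloc[0] == pytest.approx(0.5)


def test_window_alpha_capped_at_one():
    # raw ratio 1.07 > 1 -> capped
    g = constant_ratio_geno(120, 1.07)
    tab = mx.windowed_alpha(g, "X", window_bp=1000, min_snvs=100,
                            chrom_lengths={"chr1": 1000})
    assert tab["status"].iloc[0] == "pass"
    assert tab["alpha"].iloc[0] == 1.0
    assert tab["f4_num"].iloc[0] > tab["f4_den"].iloc[0]


def test_window_nonpositive_term_flagged():
    # numerator (pKAZ-pSPR)(pX-pIND) < 0 at every site, denominator > 0
    g = make_geno(
        [
            {"KAZ": 1.0, "SPR": 0.0, "KOR": 0.5, "IND": 0.2, "X": 0.1}
            for _ in range(120)
        ],
        {"KAZ": 1, "SPR": 1, "KOR": 2, "IND": 5, "X": 100},
        positions=np.linspace(1, 999, 120).astype(int),
    )
    tab = mx.windowed_alpha(g, "X", window_bp=1000, min_snvs=100,
                            chrom_lengths={"chr1": 1000})
    assert tab["status"].iloc[0] == "nonpositive_term"
    assert np.isnan(tab["alpha"].iloc[0])


def test_windowed_alpha_recovers_planted_block():
    spec = mx.DemographicSpec(
        seed=3,
        n_chromosomes=1,
        chrom_length=4_000_000,
        planted_blocks=(mx.PlantedBlock("chr1", 1_000_000, 3_000_000, 0.3),),
        panel_sizes={"KAZ": 5, "SPR": 7, "KOR": 9, "IND": 2, "FOCAL": 10},
    )
    cohort = mx.simulate_cohort(spec)
    tab = mx.windowed_alpha(cohort.geno, "FOCAL",
                            chrom_lengths={"chr1": spec.chrom_length})
    blk = tab[(tab.start >= 1_000_000) & (tab.end <= 3_000_000)]
    mean_alpha = blk.loc[blk.status == "pass", "alpha"].mean()
    assert abs(mean_alpha - 0.3) < 0.1


def test_windowed_alpha_slope_against_truth():
    """Window alpha regresses on truth ancestry with slope ~ 1.

    A balanced (a = 0.5) cohort is used so truth spans the unit interval
    and the cap at 1 rarely binds; near-saturated cohorts shrink the slope
    by construction (only downward noise survives the cap).
    """
    spec = mx.DemographicSpec(
        seed=7,
        n_chromosomes=1,
        chrom_length=2_000_000,
        admixture_proportion=0.5,
        panel_sizes={"KAZ": 5, "SPR": 7, "KOR": 9, "IND": 2, "FOCAL": 6},
    )
    cohort = mx.simulate_cohort(spec)
    tab = mx.windowed_alpha(cohort.geno, "FOCAL",
                            chrom_lengths={"chr1": spec.chrom_length})
    truth = (
        cohort.truth_window.groupby(["chrom", "start", "end"])["ancestry"]
        .mean()
        .reset_index()
    )
    merged = tab[tab.status == "pass"].merge(truth, on=["chrom", "start", "end"])
    t = merged["ancestry"].to_numpy()
    a = merged["alpha"].to_numpy()
    slope = np.cov(a, t)[0, 1] / np.var(t)
    assert abs(slope - 1.0) < 0.15


def test_windowed_alpha_invalid_window():
    g = constant_ratio_geno(10, 0.5)
    with pytest.raises(ValueError):
        mx.windowed_alpha(g, "X", window_bp=0)


# -------------------------------------------------------------- Hudson FST


def test_fst_identical_panels_near_zero():
    rng = np.random.default_rng(8)
    sizes = {"A": 20, "B": 20}
    g = random_geno(rng, n_sites=200, panel_sizes=sizes)
    g.dosage[:, g.panel_columns("B")] = g.dosage[:, g.panel_columns("A")]
    f = mx.hudson_fst(g, "A", "B", window_bp=10_000)
    assert abs(f["fst"].iloc[0]) < 0.05


def test_fst_fixed_differences_is_one():
    g = make_geno(
        [{"A": 1.0, "B": 0.0} for _ in range(20)], {"A": 3, "B": 3}
    )
    f = mx.hudson_fst(g, "A", "B", window_bp=100)
    assert f["fst"].iloc[0] == pytest.approx(1.0, abs=1e-12)


def hudson_oracle(counts_a, counts_b):
    """Brute-force per-site Hudson estimator from (alt, total) allele counts."""
    nums, dens = [], []
    for (xa, na), (xb, nb) in zip(counts_a, counts_b):
        p1, p2 = xa / na, xb / nb
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (na - 1) - p2 * (1 - p2) / (nb - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        nums.append(num)
        dens.append(den)
    return sum(nums) / sum(dens)


def test_fst_three_site_toy_counts_match_oracle():
    # A: 3 diploids, B: 2 diploids; printed dosage rows
    rows_a = [[0, 1, 2], [2, 2, 1], [0, 0, 1]]
    rows_b = [[2, 2], [0, 1], [1, 1]]
    dosage = np.hstack([np.array(rows_a), np.array(rows_b)]).astype(np.int8)
    g = GenotypeMatrix(
        chrom=np.full(3, "chr1", dtype=object),
        pos=np.array([1, 2, 3]),
        dosage=dosage,
        samples=["a0", "a1", "a2", "b0", "b1"],
        panels=pd.Series(
            {"a0": "A", "a1": "A", "a2": "A", "b0": "B", "b1": "B"}
        ),
    )
    expected = hudson_oracle(
        [(3, 6), (5, 6), (1, 6)], [(4, 4), (1, 4), (2, 4)]
    )
    f = mx.hudson_fst(g, "A", "B", window_bp=100)
    assert f["fst"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_fst_invariant_to_site_order_within_window():
    rng = np.random.default_rng(12)
    g = random_geno(rng, n_sites=50, panel_sizes={"A": 6, "B": 6})
    f1 = mx.hudson_fst(g, "A", "B", window_bp=1000)
    perm = rng.permutation(50)
    g2 = GenotypeMatrix(
        chrom=g.chrom, pos=g.pos, dosage=g.dosage[perm], samples=g.samples,
        panels=g.panels,
    )
    f2 = mx.hudson_fst(g2, "A", "B", window_bp=1000)
    assert f1["fst"].iloc[0] == pytest.approx(f2["fst"].iloc[0], abs=1e-12)


def test_fst_empty_window_is_nan_not_zero():
    g = random_geno(np.random.default_rng(13), n_sites=10,
                    panel_sizes={"A": 4, "B": 4})
    f = mx.hudson_fst(g, "A", "B", window_bp=5, chrom_lengths={"chr1": 20})
    assert np.isnan(f.loc[f["n_snvs"] == 0, "fst"]).all()


# --------------------------------------------------------------- LD prune


def ld_prune_oracle(dosage, window, step, r2_max):
    """Independent re-implementation of the greedy pruning rule."""
    n = dosage.shape[0]
    removed = set()

    def r2(i, j):
        x, y = dosage[i].astype(float), dosage[j].astype(float)
        ok = (x != MISSING) & (y != MISSING)
        if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
            return 0.0
        return float(np.corrcoef(x[ok], y[ok])[0, 1] ** 2)

    start = 0
    while True:
        win = list(range(start, min(start + window, n)))
        for ai in range(len(win)):
            if win[ai] in removed:
                continue
            for bi in range(ai + 1, len(win)):
                if win[bi] in removed:
                    continue
                if r2(win[ai], win[bi]) > r2_max:
                    removed.add(win[bi])
        if start + window >= n:
            break
        start += step
    return np.array([i not in removed for i in range(n)])


def test_ld_prune_trivials():
    g = random_geno(np.random.default_rng(14), n_sites=1,
                    panel_sizes={"A": 5})
    assert mx.ld_prune(g).tolist() == [True]

    rng = np.random.default_rng(15)
    g2 = random_geno(rng, n_sites=2, panel_sizes={"A": 10})
    g2.dosage[1] = g2.dosage[0]  # identical columns, r^2 = 1
    keep = mx.ld_prune(g2)
    assert keep.tolist() == [True, False]


def test_ld_prune_matches_exhaustive_oracle():
    rng = np.random.default_rng(16)
    g = random_geno(rng, n_sites=200, panel_sizes={"A": 20}, missing_rate=0.05)
    # add correlated structure so pruning actually triggers
    for i in range(0, 200, 7):
        if i + 1 < 200:
            g.dosage[i + 1] = g.dosage[i]
    keep = mx.ld_prune(g, window_snvs=50, step_snvs=5, r2_max=0.5)
    expected = ld_prune_oracle(g.dosage, 50, 5, 0.5)
    np.testing.assert_array_equal(keep, expected)


def test_ld_prune_no_kept_pair_exceeds_threshold():
    rng = np.random.default_rng(17)
    g = random_geno(rng, n_sites=60, panel_sizes={"A": 15})
    for i in range(0, 60, 5):
        if i + 2 < 60:
            g.dosage[i + 2] = g.dosage[i]
    keep = mx.ld_prune(g, window_snvs=20, step_snvs=2, r2_max=0.5)
    kept = np.flatnonzero(keep)
    # within any evaluation window of 20 consecutive original sites
    for a in range(kept.size):
        for b in range(a + 1, kept.size):
            i, j = kept[a], kept[b]
            if j - i < 20:
                assert pg._pairwise_r2(g.dosage, i, j) <= 0.5
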