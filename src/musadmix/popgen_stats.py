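"""Admixture and differentiation statistics on genotype matrices.

Implements the four-population f4 statistic, the f4-ratio estimator of the
musculus ancestry proportion alpha, windowed alpha scans with the standard
filters (minimum SNV count, nonpositive f4 terms, capping at 1), the Hudson
FST estimator aggregated as a ratio of sums per window, and PLINK-style
greedy LD pruning.

The f4-ratio setup follows the four-panel design used for East Asian house
mice: with KAZ (Kazakh musculus), SPR (M. spretus outgroup), KOR (Korean
musculus) and IND (Indian castaneus) reference panels, the musculus ancestry
fraction of a focal sample or population X is

    alpha = f4(KAZ, SPR; X, IND) / f4(KAZ, SPR; KOR, IND)

where f4(A,B;C,D) is the mean over usable sites of
(p_A - p_B)(p_C - p_D).  Values above 1 arise from statistical fluctuation
and are capped at 1.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, infer_chrom_lengths, window_grid

DEFAULT_QUARTET = ("KAZ", "SPR", "KOR", "IND")

STATUS_PASS = "pass"
STATUS_TOO_FEW = "too_few_snvs"
STATUS_NONPOS = "nonpositive_term"


# --------------------------------------------------------------------------
# allele frequencies


def allele_frequency(geno: GenotypeMatrix, panel: str) -> np.ndarray:
    """Per-site alternate-allele frequency in one panel.

    Missing calls are excluded per site; sites where the whole panel is
    missing are returned as NaN (undefined), never as 0.
    """
    cols = geno.resolve_group(panel)
    return _freq_from_dosage(geno.dosage[:, cols])


def _freq_from_dosage(d: np.ndarray) -> np.ndarray:
    ok = d != MISSING
    n_alleles = 2 * ok.sum(axis=1)
    alt = np.where(ok, d, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return freq


def _allele_counts(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, total allele count) per site with missing removed."""
    ok = d != MISSING
    n = 2 * ok.sum(axis=1)
    alt = np.where(ok, d, 0).sum(axis=1)
    return alt.astype(float), n.astype(float)


# --------------------------------------------------------------------------
# f4 and the f4-ratio


def patterson_f4(
    geno: GenotypeMatrix,
    quartet: Sequence[str],
    sites: np.ndarray | None = None,
) -> tuple[float, int]:
    """f4(A,B;C,D): mean over sites of (p_A - p_B)(p_C - p_D).

    A site contributes only when all four panel frequencies are defined
    (pairwise-complete deletion).  Returns (value, number of sites used).
    """
    a, b, c, d = quartet
    if len({a, b, c, d}) != 4:
        raise ValueError("quartet labels must be distinct")
    freqs = [allele_frequency(geno, lab) for lab in (a, b, c, d)]
    mask = ~np.any([np.isnan(f) for f in freqs], axis=0)
    if sites is not None:
        mask &= np.asarray(sites, dtype=bool)
    n_used = int(mask.sum())
    if n_used == 0:
        raise ValueError("no usable sites: all four panels undefined everywhere")
    pa, pb, pc, pd_ = (f[mask] for f in freqs)
    return float(np.mean((pa - pb) * (pc - pd_))), n_used


def f4_ratio_alpha(
    geno: GenotypeMatrix,
    X: str,
    quartet: Sequence[str] = DEFAULT_QUARTET,
    sites: np.ndarray | None = None,
    cap: bool = True,
) -> float:
    """Genome-wide musculus ancestry of X by the f4-ratio.

    X may be a panel label or a single sample id (treated as a one-member
    panel with frequencies in {0, 0.5, 1}).  Raises if the denominator
    f4(A,B;C,D) is not positive, which indicates a mis-specified quartet
    rather than a filterable window.
    """
    kaz, spr, kor, ind = quartet
    num, _ = patterson_f4(geno, (kaz, spr, X, ind), sites)
    den, _ = patterson_f4(geno, (kaz, spr, kor, ind), sites)
    if den <= 0:
        raise ValueError(
            f"genome-wide f4 denominator is non-positive ({den:.3g}); "
            "check quartet orientation (expected f4(A,B;C,D) > 0)"
        )
    alpha = num / den
    if cap and alpha > 1.0:
        alpha = 1.0
    return float(alpha)


def windowed_alpha(
    geno: GenotypeMatrix,
    X: str,
    window_bp: int = 20_000,
    min_snvs: int = 100,
    quartet: Sequence[str] = DEFAULT_QUARTET,
    chrom_lengths: dict[str, int] | None = None,
    global_denominator: bool = False,
) -> pd.DataFrame:
    """Per-window f4-ratio alpha with filter flags.

    Windows are non-overlapping, anchored at position 0 of each chromosome,
    0-based half-open and ``window_bp`` long (the last partial window is
    kept).  A window passes only if it has at least ``min_snvs`` usable SNVs
    and both f4 terms are strictly positive; passing alpha values are capped
    at 1.  Failing windows are flagged, never dropped.

    Returns a DataFrame with columns chrom, start, end, n_snvs, f4_num,
    f4_den, alpha, status.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    kaz, spr, kor, ind = quartet
    freq = {lab: allele_frequency(geno, lab) for lab in (kaz, spr, kor, ind)}
    freq_x = allele_frequency(geno, X)
    usable = ~(
        np.isnan(freq[kaz])
        | np.isnan(freq[spr])
        | np.isnan(freq[kor])
        | np.isnan(freq[ind])
        | np.isnan(freq_x)
    )
    num_site = (freq[kaz] - freq[spr]) * (freq_x - freq[ind])
    den_site = (freq[kaz] - freq[spr]) * (freq[kor] - freq[ind])

    if chrom_lengths is None:
        chrom_lengths = infer_chrom_lengths(geno)
    grid = window_grid(chrom_lengths, window_bp)

    if global_denominator:
        if not usable.any():
            raise ValueError("no usable sites for the global denominator")
        global_den = float(np.mean(den_site[usable]))

    chrom_idx = {c: np.flatnonzero(geno.chrom == c) for c in geno.chromosomes()}
    rows = []
    for chrom, start, end in grid.itertuples(index=False):
        idx = chrom_idx.get(chrom, np.empty(0, dtype=int))
        pos_c = geno.pos[idx]
        lo, hi = np.searchsorted(pos_c, [start + 1, end + 1])
        w = idx[lo:hi][usable[idx[lo:hi]]]
        n = int(w.size)
        if n < min_snvs:
            rows.append((chrom, start, end, n, np.nan, np.nan, np.nan, STATUS_TOO_FEW))
            continue
        num = float(np.mean(num_site[w]))
        den = global_den if global_denominator else float(np.mean(den_site[w]))
        if num <= 0 or den <= 0:
            rows.append((chrom, start, end, n, num, den, np.nan, STATUS_NONPOS))
            continue
        alpha = min(num / den, 1.0)
        rows.append((chrom, start, end, n, num, den, alpha, STATUS_PASS))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "n_snvs",
            "f4_num",
            "f4_den",
            "alpha",
            "status",
        ],
    )


# --------------------------------------------------------------------------
# Hudson FST


def hudson_fst_site(geno: GenotypeMatrix, panel_a: str, panel_b: str):
    """Per-site Hudson numerator/denominator between two panels.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    with n the allele (chromosome) counts.  Sites with fewer than 2 alleles
    sampled in either panel are undefined (NaN).
    """
    alt1, n1 = _allele_counts(geno.dosage[:, geno.resolve_group(panel_a)])
    alt2, n2 = _allele_counts(geno.dosage[:, geno.resolve_group(panel_b)])
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(ok, alt1 / np.maximum(n1, 1), np.nan)
        p2 = np.where(ok, alt2 / np.maximum(n2, 1), np.nan)
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
            - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num[~ok] = np.nan
    den[~ok] = np.nan
    return num, den


def hudson_fst(
    geno: GenotypeMatrix,
    panel_a: str,
    panel_b: str,
    window_bp: int = 20_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed Hudson FST as a ratio of sums.

    Window value = sum(site numerators) / sum(site denominators) over
    defined sites; windows with no usable site or zero denominator get NaN.
    """
    num, den = hudson_fst_site(geno, panel_a, panel_b)
    usable = ~np.isnan(num) & ~np.isnan(den)
    if chrom_lengths is None:
        chrom_lengths = infer_chrom_lengths(geno)
    grid = window_grid(chrom_lengths, window_bp)
    chrom_idx = {c: np.flatnonzero(geno.chrom == c) for c in geno.chromosomes()}
    rows = []
    for chrom, start, end in grid.itertuples(index=False):
        idx = chrom_idx.get(chrom, np.empty(0, dtype=int))
        pos_c = geno.pos[idx]
        lo, hi = np.searchsorted(pos_c, [start + 1, end + 1])
        w = idx[lo:hi][usable[idx[lo:hi]]]
        n = int(w.size)
        if n == 0:
            rows.append((chrom, start, end, 0, np.nan))
            continue
        s_den = float(den[w].sum())
        fst = float(num[w].sum() / s_den) if s_den != 0 else np.nan
        rows.append((chrom, start, end, n, fst))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snvs", "fst"])


# --------------------------------------------------------------------------
# LD pruning


def _pairwise_r2(d: np.ndarray, i: int, j: int) -> float:
    """Squared dosage correlation, pairwise-complete over samples."""
    x, y = d[i].astype(float), d[j].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    geno: GenotypeMatrix,
    window_snvs: int = 50,
    step_snvs: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Greedy sliding-window LD pruning (PLINK --indep-pairwise style).

    Within each window of ``window_snvs`` consecutive SNVs, every ordered
    pair of still-kept sites is examined and the later site of any pair with
    r^2 > ``r2_max`` is removed; the window then slides by ``step_snvs``.
    A site removed in any window stays removed.  Windows never span
    chromosomes.  Returns a boolean keep-mask over sites.
    """
    keep = np.ones(geno.n_sites, dtype=bool)
    for chrom in geno.chromosomes():
        idx = np.flatnonzero(geno.chrom == chrom)
        n = idx.size
        start = 0
        while True:
            win = idx[start : start + window_snvs]
            for ii in range(win.size):
                i = win[ii]
                if not keep[i]:
                    continue
                for jj in range(ii + 1, win.size):
                    j = win[jj]
                    if not keep[j]:
                        continue
                    if _pairwise_r2(geno.dosage, i, j) > r2_max:
                        keep[j] = False
            if start + window_snvs >= n:
                break
            start += step_snvs
    return keep
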