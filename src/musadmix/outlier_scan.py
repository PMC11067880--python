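"""Neutral null distribution of windowed alpha and outlier-window calling.

The observed per-window musculus ancestry proportion (alpha) is compared
with a null distribution obtained by simulating many independent neutral
20-kb windows under the cohort's demography (no selection), computing alpha
with the identical estimator and filters, and taking the empirical 5%
quantile.  Windows whose observed alpha falls below that threshold are
ancestry-enriched outliers (castaneus-enriched, in the house-mouse
application).  Outliers are then annotated against gene intervals and
contrasted with the genomic background for gene density (chi-square) and
recombination rate (Mann–Whitney U).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from . import popgen_stats
from .genotypes import GenotypeMatrix
from .synthetic_data import DemographicSpec, simulate_window


@dataclasses.dataclass
class NullAlphaDistribution:
    """Simulated neutral window alpha values and the derived threshold."""

    values: np.ndarray
    n_requested: int
    n_failed: int
    quantile: float
    threshold: float
    spec: DemographicSpec
    seed: int

    def percentile_of(self, alpha: float) -> float:
        """Fraction of the null at or below ``alpha``."""
        return float(np.mean(self.values <= alpha))


def _window_alpha(
    geno: GenotypeMatrix,
    focal: str,
    min_snvs: int,
    quartet: Sequence[str],
) -> float | None:
    """Alpha of one simulated window under the standard filters.

    Returns None when the window fails the SNV-count or positivity filter.
    """
    freq = {lab: popgen_stats.allele_frequency(geno, lab) for lab in quartet}
    freq_x = popgen_stats.allele_frequency(geno, focal)
    kaz, spr, kor, ind = quartet
    usable = ~(
        np.isnan(freq[kaz])
        | np.isnan(freq[spr])
        | np.isnan(freq[kor])
        | np.isnan(freq[ind])
        | np.isnan(freq_x)
    )
    if int(usable.sum()) < min_snvs:
        return None
    pa, pb = freq[kaz][usable], freq[spr][usable]
    pc, pd_ = freq[kor][usable], freq[ind][usable]
    px = freq_x[usable]
    num = float(np.mean((pa - pb) * (px - pd_)))
    den = float(np.mean((pa - pb) * (pc - pd_)))
    if num <= 0 or den <= 0:
        return None
    return min(num / den, 1.0)


def build_null(
    spec: DemographicSpec,
    n_sims: int,
    quantile: float = 0.05,
    min_snvs: int = 100,
    focal: str = "FOCAL",
    quartet: Sequence[str] = popgen_stats.DEFAULT_QUARTET,
    seed: int | None = None,
) -> NullAlphaDistribution:
    """Simulate ``n_sims`` independent neutral windows and take the
    empirical ``quantile`` of their alpha values.

    Windows failing the SNV-count or positivity filters are logged as
    failures; more than 50% failures aborts with a diagnostic.
    """
    if n_sims < 100:
        raise ValueError(f"n_sims must be >= 100 (got {n_sims})")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    master = spec.seed if seed is None else seed
    rng = np.random.default_rng([master, 0x6E756C6C])
    values = []
    n_failed = 0
    for _ in range(n_sims):
        geno = simulate_window(spec, rng)
        alpha = _window_alpha(geno, focal, min_snvs, quartet)
        if alpha is None:
            n_failed += 1
        else:
            values.append(alpha)
    if n_failed > 0.5 * n_sims:
        raise RuntimeError(
            f"{n_failed}/{n_sims} null windows failed the filters; the "
            "demographic spec is incompatible with the estimator settings "
            "(check snv_density * window_bp >= min_snvs and the quartet "
            "orientation)"
        )
    arr = np.asarray(values)
    return NullAlphaDistribution(
        values=arr,
        n_requested=n_sims,
        n_failed=n_failed,
        quantile=quantile,
        threshold=float(np.quantile(arr, quantile)),
        spec=spec,
        seed=master,
    )


def call_outliers(
    windows: pd.DataFrame,
    null: NullAlphaDistribution,
    direction: str = "low",
) -> pd.DataFrame:
    """Flag pass windows beyond the null threshold.

    ``direction='low'`` (default) scans for castaneus-enriched windows:
    pass windows with alpha strictly below the 5% null threshold.
    ``direction='high'`` uses the symmetric upper quantile instead.
    Returns the window table with added ``null_percentile`` and ``outlier``
    columns; non-pass windows are never outliers.
    """
    if null.values.size == 0:
        raise ValueError("null distribution is empty")
    if direction not in {"low", "high"}:
        raise ValueError("direction must be 'low' or 'high'")
    out = windows.copy()
    is_pass = out["status"] == popgen_stats.STATUS_PASS
    out["null_percentile"] = [
        null.percentile_of(a) if ok else np.nan
        for a, ok in zip(out["alpha"], is_pass)
    ]
    if direction == "low":
        thr = null.threshold
        out["outlier"] = is_pass & (out["alpha"] < thr)
    else:
        thr = float(np.quantile(null.values, 1.0 - null.quantile))
        out["outlier"] = is_pass & (out["alpha"] > thr)
    return out


# --------------------------------------------------------------------------
# annotation


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED file (chrom, start, end[, name]); 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {line!r}") from exc
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _gene_trees(genes: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.groupby("chrom", sort=False):
        t = IntervalTree()
        for _, g in grp.iterrows():
            if g["end"] > g["start"]:
                t.addi(int(g["start"]), int(g["end"]), g["name"])
        trees[chrom] = t
    return trees


def annotate_outliers(
    calls: pd.DataFrame, genes: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Attach overlapping gene ids to each window (any-bp overlap,
    half-open intervals) and return the deduplicated gene list over
    outlier windows.
    """
    trees = _gene_trees(genes)
    gene_lists = []
    for _, w in calls.iterrows():
        t = trees.get(w["chrom"])
        hits = sorted({iv.data for iv in t.overlap(w["start"], w["end"])}) if t else []
        gene_lists.append(hits)
    out = calls.copy()
    out["genes"] = gene_lists
    flags = (
        out["outlier"].tolist()
        if "outlier" in out.columns
        else [False] * len(out)
    )
    outlier_genes = sorted(
        {g for gl, flag in zip(gene_lists, flags) if flag for g in gl}
    )
    return out, outlier_genes


def window_recombination_rate(
    windows: pd.DataFrame, recomb: pd.DataFrame
) -> np.ndarray:
    """Length-weighted mean recombination rate (cM/Mb) per window.

    ``recomb`` holds chrom, start, end, rate segments (0-based half-open).
    Windows with no overlapping segment get NaN.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in recomb.groupby("chrom", sort=False):
        t = IntervalTree()
        for _, r in grp.iterrows():
            if r["end"] > r["start"]:
                t.addi(int(r["start"]), int(r["end"]), float(r["rate"]))
        trees[chrom] = t
    rates = np.full(len(windows), np.nan)
    for i, (_, w) in enumerate(windows.iterrows()):
        t = trees.get(w["chrom"])
        if t is None:
            continue
        total = 0.0
        weighted = 0.0
        for iv in t.overlap(w["start"], w["end"]):
            ov = min(iv.end, w["end"]) - max(iv.begin, w["start"])
            if ov > 0:
                total += ov
                weighted += ov * iv.data
        if total > 0:
            rates[i] = weighted / total
    return rates


def contrast_annotations(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    recomb: pd.DataFrame | None = None,
) -> dict:
    """Gene-density and recombination-rate contrasts of outliers vs rest.

    Gene density: 2x2 chi-square (outlier x gene-containing, no continuity
    correction).  Recombination: two-sided Mann–Whitney U on window rates.
    Only pass windows enter either contrast.  Degenerate tables are
    reported as untestable rather than raising.
    """
    annotated, _ = annotate_outliers(calls, genes)
    is_pass = annotated["status"] == popgen_stats.STATUS_PASS
    df = annotated[is_pass].copy()
    df["has_gene"] = df["genes"].map(bool)
    report: dict = {"n_windows": int(len(df)), "n_outliers": int(df["outlier"].sum())}

    table = np.array(
        [
            [
                int((df["outlier"] & df["has_gene"]).sum()),
                int((df["outlier"] & ~df["has_gene"]).sum()),
            ],
            [
                int((~df["outlier"] & df["has_gene"]).sum()),
                int((~df["outlier"] & ~df["has_gene"]).sum()),
            ],
        ]
    )
    report["gene_density_table"] = table.tolist()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        report["gene_density"] = {"testable": False}
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        report["gene_density"] = {
            "testable": True,
            "chi2": float(chi2),
            "p_value": float(p),
        }

    if recomb is not None:
        rates = window_recombination_rate(df, recomb)
        ok = ~np.isnan(rates)
        r_out = rates[ok & df["outlier"].to_numpy()]
        r_bg = rates[ok & ~df["outlier"].to_numpy()]
        if r_out.size == 0 or r_bg.size == 0:
            report["recombination"] = {"testable": False}
        else:
            u, p = stats.mannwhitneyu(r_out, r_bg, alternative="two-sided")
            report["recombination"] = {
                "testable": True,
                "u_statistic": float(u),
                "p_value": float(p),
                "median_outlier": float(np.median(r_out)),
                "median_background": float(np.median(r_bg)),
            }
    return report
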