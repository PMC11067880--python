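"""Synthetic cohorts, ancestry truth tracks and amplicon depth profiles.

The generator emulates the statistical structure of the East Asian house
mouse study design: four reference panels (Kazakh musculus, M. spretus
outgroup, Korean musculus, Indian castaneus) plus admixed focal samples
whose genomes are castaneus/musculus mosaics, and Poisson read-depth
profiles at cluster-diagnostic sites of a multi-copy gene family.

Backend
-------
Allele frequencies evolve by a hierarchical Balding–Nichols drift model
along the population tree

    root ── SPR (outgroup)
      └──┬── musculus ancestor ──┬── KAZ
         │                      └── KOR
         └── castaneus ancestor ──── IND

with per-branch inbreeding coefficient F = 1 - exp(-t / 2N) derived from
the branch length t (generations) and diploid size N.  Panel genotypes are
Binomial(2, p_pop) draws; focal haplotypes are two-state ancestry mosaics
(musculus vs castaneus) sampling alleles from p_KOR or p_IND.  Mosaics are
piecewise constant with switch events at rate ``switch_rate`` per bp, the
state being redrawn Bernoulli(a) at every event, so the marginal musculus
fraction equals the configured admixture proportion a and the mean ancestry
block length is 1/(switch_rate * (1 - a)).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MISSING, window_grid, write_panel

MUS = 1  # musculus-like ancestry state
CAS = 0

DEFAULT_PANEL_SIZES = {"KAZ": 5, "SPR": 7, "KOR": 9, "IND": 2, "FOCAL": 10}


@dataclasses.dataclass
class PlantedBlock:
    """A genomic interval whose focal ancestry is forced to a set fraction."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    musculus_fraction: float


@dataclasses.dataclass
class DemographicSpec:
    """Demography + genome layout for cohort simulation.

    Sizes are diploids, times are generations before present and must be
    ordered oldest -> youngest along each lineage.  The admixture pulse
    mixes the KOR-like (musculus) and IND-like (castaneus) sources with
    musculus proportion ``admixture_proportion``.
    """

    ne_ancestral: int = 25_000
    ne_subspecies: int = 25_000
    ne_panel: int = 25_000
    t_outgroup_split: int = 50_000
    t_subspecies_split: int = 18_000
    t_panel_split: int = 5_000
    admixture_time: int = 200
    admixture_proportion: float = 0.878
    panel_sizes: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PANEL_SIZES)
    )
    n_chromosomes: int = 3
    chrom_length: int = 10_000_000
    snv_density: float = 0.05
    window_bp: int = 20_000
    switch_rate: float = 5e-6  # per bp; mean musculus block ~ 1/(r*(1-a))
    missing_rate: float = 0.0
    planted_blocks: tuple[PlantedBlock, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        a = self.admixture_proportion
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"admixture proportion {a} outside [0, 1]")
        times = (
            self.t_outgroup_split,
            self.t_subspecies_split,
            self.t_panel_split,
            self.admixture_time,
        )
        if any(t <= 0 for t in times):
            raise ValueError("all times must be strictly positive")
        if not (
            self.t_outgroup_split
            > self.t_subspecies_split
            > self.t_panel_split
            > self.admixture_time
        ):
            raise ValueError(
                "times must be ordered oldest->youngest: outgroup split > "
                "subspecies split > panel split > admixture pulse (an "
                "admixture pulse older than its source split is invalid)"
            )
        for ne in (self.ne_ancestral, self.ne_subspecies, self.ne_panel):
            if ne < 1:
                raise ValueError("effective sizes must be >= 1")
        for pop, n in self.panel_sizes.items():
            if n < 1:
                raise ValueError(f"panel size for {pop} must be >= 1")
        if self.snv_density <= 0 or self.chrom_length <= 0 or self.n_chromosomes < 1:
            raise ValueError("invalid genome layout")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for b in self.planted_blocks:
            if not 0.0 <= b.musculus_fraction <= 1.0:
                raise ValueError("planted block fraction outside [0, 1]")

    # branch-wise Balding–Nichols F values
    def branch_f(self) -> dict[str, float]:
        """Per-branch F = 1 - exp(-t/2N) along the population tree.

        'ingroup' is the branch from the outgroup split down to the
        castaneus/musculus split; it is shared by all ingroup panels, so it
        cancels from within-ingroup differentiation and from f4 but still
        shapes the ingroup frequency spectrum.
        """

        def f(t: float, ne: float) -> float:
            return float(1.0 - np.exp(-t / (2.0 * ne)))

        return {
            "SPR": f(self.t_outgroup_split, self.ne_ancestral),
            "ingroup": f(
                self.t_outgroup_split - self.t_subspecies_split, self.ne_ancestral
            ),
            "mus_anc": f(
                self.t_subspecies_split - self.t_panel_split, self.ne_subspecies
            ),
            "cas_anc": f(
                self.t_subspecies_split - self.t_panel_split, self.ne_subspecies
            ),
            "KAZ": f(self.t_panel_split, self.ne_panel),
            "KOR": f(self.t_panel_split, self.ne_panel),
            "IND": f(self.t_panel_split, self.ne_panel),
        }


@dataclasses.dataclass
class SimulatedCohort:
    """Genotypes plus the ancestry truth the generator knows."""

    geno: GenotypeMatrix
    truth_sample: pd.DataFrame  # sample, ancestry (genome-wide musculus fraction)
    truth_window: pd.DataFrame  # chrom, start, end, sample, ancestry
    spec: DemographicSpec

    def to_files(self, outdir: str, prefix: str = "cohort") -> dict[str, str]:
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "vcf": os.path.join(outdir, f"{prefix}.vcf"),
            "panel": os.path.join(outdir, f"{prefix}.panel.tsv"),
            "truth_sample": os.path.join(outdir, f"{prefix}.truth_sample.tsv"),
            "truth_window": os.path.join(outdir, f"{prefix}.truth_window.tsv"),
            "windows_bed": os.path.join(outdir, f"{prefix}.windows.bed"),
        }
        self.geno.to_vcf(paths["vcf"], extra_header=[f"musadmix_seed={self.spec.seed}"])
        write_panel(self.geno.panels, paths["panel"])
        self.truth_sample.to_csv(paths["truth_sample"], sep="\t", index=False)
        self.truth_window.to_csv(paths["truth_window"], sep="\t", index=False)
        grid = window_grid(
            {c: self.spec.chrom_length for c in self.geno.chromosomes()},
            self.spec.window_bp,
        )
        grid.to_csv(paths["windows_bed"], sep="\t", index=False, header=False)
        return paths


# --------------------------------------------------------------------------
# frequency model


def _bn_drift(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols drift: p' ~ Beta(p(1-F)/F, (1-p)(1-F)/F).

    Frequencies already fixed at 0 or 1 stay fixed.
    """
    if f <= 0:
        return p.copy()
    lam = (1.0 - f) / f
    out = p.copy()
    seg = (p > 0) & (p < 1)
    out[seg] = rng.beta(p[seg] * lam, (1.0 - p[seg]) * lam)
    return out


def _population_frequencies(
    spec: DemographicSpec, n_sites: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    F = spec.branch_f()
    p_anc = rng.uniform(0.05, 0.95, n_sites)
    p_spr = _bn_drift(p_anc, F["SPR"], rng)
    p_in = _bn_drift(p_anc, F["ingroup"], rng)  # shared by all ingroup panels
    p_mus = _bn_drift(p_in, F["mus_anc"], rng)
    p_cas = _bn_drift(p_in, F["cas_anc"], rng)
    return {
        "SPR": p_spr,
        "KAZ": _bn_drift(p_mus, F["KAZ"], rng),
        "KOR": _bn_drift(p_mus, F["KOR"], rng),
        "IND": _bn_drift(p_cas, F["IND"], rng),
    }


# --------------------------------------------------------------------------
# ancestry mosaics


def _mosaic_track(
    length: int, a: float, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One haplotype's ancestry track along [0, length).

    Returns (breakpoints, states): ``states[k]`` holds on
    [breakpoints[k], breakpoints[k+1]) with an implicit final breakpoint at
    ``length``.  Switch events are Poisson(rate per bp); the state is
    redrawn Bernoulli(a) at each event (so consecutive states may repeat,
    which leaves the marginal law exactly Bernoulli(a)).
    """
    breaks = [0]
    pos = 0.0
    if rate > 0:
        while True:
            pos += rng.exponential(1.0 / rate)
            if pos >= length:
                break
            breaks.append(int(pos))
    states = (rng.random(len(breaks)) < a).astype(np.int8)
    return np.asarray(breaks, dtype=np.int64), states


def _apply_planted_blocks(
    breaks: np.ndarray,
    states: np.ndarray,
    length: int,
    blocks: Sequence[PlantedBlock],
    chrom: str,
    hap_rank: int,
    n_haplotypes: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Force ancestry inside planted blocks to the block fraction.

    Each haplotype carries a single constant state across the whole block,
    assigned deterministically by haplotype rank so that exactly
    round(fraction * n_haplotypes) focal haplotypes are musculus there and
    the cohort's mean block ancestry equals the planted fraction.
    """
    for b in blocks:
        if b.chrom != chrom:
            continue
        n_mus = int(round(b.musculus_fraction * n_haplotypes))
        state_in = MUS if hap_rank < n_mus else CAS
        # rebuild the piecewise track with the block overridden
        grid = [0] + [int(x) for x in breaks[1:]] + [length]
        new_breaks: list[int] = []
        new_states: list[int] = []
        for k in range(len(grid) - 1):
            s, e = grid[k], grid[k + 1]
            st = int(states[k])
            for ss, ee, stt in _split_segment(s, e, b.start, b.end, st, state_in):
                if ee > ss:
                    new_breaks.append(ss)
                    new_states.append(stt)
        breaks = np.asarray(new_breaks, dtype=np.int64)
        states = np.asarray(new_states, dtype=np.int8)
    return breaks, states


def _split_segment(s, e, bs, be, outside_state, inside_state):
    """Split [s,e) by block [bs,be), tagging inside/outside states."""
    parts = []
    if e <= bs or s >= be:
        parts.append((s, e, outside_state))
        return parts
    if s < bs:
        parts.append((s, bs, outside_state))
    parts.append((max(s, bs), min(e, be), inside_state))
    if e > be:
        parts.append((be, e, outside_state))
    return parts


def _states_at(breaks: np.ndarray, states: np.ndarray, pos0: np.ndarray) -> np.ndarray:
    """Ancestry state at 0-based positions."""
    idx = np.searchsorted(breaks, pos0, side="right") - 1
    return states[idx]


def _window_fractions(
    breaks: np.ndarray, states: np.ndarray, length: int, window_bp: int
) -> np.ndarray:
    """Fraction of bp in the musculus state per window along one track."""
    edges = np.append(breaks, length).astype(float)
    n_win = int(np.ceil(length / window_bp))
    out = np.zeros(n_win)
    for k in range(len(states)):
        if states[k] != MUS:
            continue
        s, e = edges[k], edges[k + 1]
        if e <= s:
            continue
        w0 = int(s // window_bp)
        w1 = min(int((e - 1) // window_bp), n_win - 1)
        for w in range(w0, w1 + 1):
            ws, we = w * window_bp, min((w + 1) * window_bp, length)
            out[w] += max(0.0, min(e, we) - max(s, ws))
    widths = np.array(
        [min((w + 1) * window_bp, length) - w * window_bp for w in range(n_win)],
        dtype=float,
    )
    return out / widths


# --------------------------------------------------------------------------
# cohort simulation


def _site_positions(length: int, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """``n_sites`` distinct, sorted 1-based positions in [1, length]."""
    if n_sites > length:
        raise ValueError("more sites requested than positions available")
    pos = rng.choice(length, size=n_sites, replace=False, shuffle=False)
    pos.sort()
    return pos.astype(np.int64) + 1


def simulate_cohort(spec: DemographicSpec) -> SimulatedCohort:
    """Simulate reference panels plus admixed focal samples with truth.

    Returns genotypes for all panels, the genome-wide musculus fraction of
    each focal sample and the per-window musculus fraction truth table.
    Fixed seed => bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    a = spec.admixture_proportion

    panel_names = [p for p in spec.panel_sizes if p != "FOCAL"]
    n_focal = spec.panel_sizes.get("FOCAL", 0)
    samples: list[str] = []
    panels: list[str] = []
    for p in panel_names:
        for i in range(spec.panel_sizes[p]):
            samples.append(f"{p}_{i}")
            panels.append(p)
    for i in range(n_focal):
        samples.append(f"FOCAL_{i}")
        panels.append("FOCAL")

    chroms_all: list[np.ndarray] = []
    pos_all: list[np.ndarray] = []
    dos_all: list[np.ndarray] = []
    truth_win_rows = []
    mus_bp = np.zeros(n_focal)  # musculus bp summed over both haplotypes
    total_bp = 2 * spec.n_chromosomes * spec.chrom_length

    n_sites_chrom = int(round(spec.snv_density * spec.chrom_length))
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = _site_positions(spec.chrom_length, n_sites_chrom, rng)
        freqs = _population_frequencies(spec, pos.size, rng)

        dosage = np.empty((pos.size, len(samples)), dtype=np.int8)
        col = 0
        for p in panel_names:
            n = spec.panel_sizes[p]
            dosage[:, col : col + n] = rng.binomial(
                2, freqs[p][:, None], size=(pos.size, n)
            )
            col += n

        win_frac = np.zeros((n_focal, int(np.ceil(spec.chrom_length / spec.window_bp))))
        for s in range(n_focal):
            hap_sum = np.zeros(pos.size, dtype=np.int8)
            for _hap in range(2):
                breaks, states = _mosaic_track(
                    spec.chrom_length, a, spec.switch_rate, rng
                )
                breaks, states = _apply_planted_blocks(
                    breaks,
                    states,
                    spec.chrom_length,
                    spec.planted_blocks,
                    chrom,
                    hap_rank=2 * s + _hap,
                    n_haplotypes=2 * n_focal,
                )
                st = _states_at(breaks, states, pos - 1)
                p_hap = np.where(st == MUS, freqs["KOR"], freqs["IND"])
                hap_sum += (rng.random(pos.size) < p_hap).astype(np.int8)
                frac = _window_fractions(
                    breaks, states, spec.chrom_length, spec.window_bp
                )
                win_frac[s] += frac / 2.0
                edges = np.append(breaks, spec.chrom_length).astype(float)
                seg_len = np.diff(edges)
                mus_bp[s] += seg_len[states == MUS].sum()
            dosage[:, col + s] = hap_sum

        if spec.missing_rate > 0:
            miss = rng.random(dosage.shape) < spec.missing_rate
            dosage[miss] = MISSING

        chroms_all.append(np.full(pos.size, chrom, dtype=object))
        pos_all.append(pos)
        dos_all.append(dosage)

        n_win = win_frac.shape[1]
        for w in range(n_win):
            ws = w * spec.window_bp
            we = min(ws + spec.window_bp, spec.chrom_length)
            for s in range(n_focal):
                truth_win_rows.append((chrom, ws, we, f"FOCAL_{s}", win_frac[s, w]))

    geno = GenotypeMatrix(
        chrom=np.concatenate(chroms_all),
        pos=np.concatenate(pos_all),
        dosage=np.vstack(dos_all),
        samples=samples,
        panels=pd.Series(panels, index=samples),
    )
    truth_sample = pd.DataFrame(
        {
            "sample": [f"FOCAL_{i}" for i in range(n_focal)],
            "ancestry": mus_bp / total_bp,
        }
    )
    truth_window = pd.DataFrame(
        truth_win_rows, columns=["chrom", "start", "end", "sample", "ancestry"]
    )
    return SimulatedCohort(geno, truth_sample, truth_window, spec)


def simulate_window(
    spec: DemographicSpec,
    rng: np.random.Generator,
    chrom: str = "null",
) -> GenotypeMatrix:
    """One independent neutral window (panels + focal) for null building.

    The window is ``spec.window_bp`` long with the expected SNV density;
    each focal haplotype follows the same mosaic process restricted to the
    window, so window-scale ancestry variance (the dominant term in the
    neutral alpha distribution) is preserved.
    """
    L = spec.window_bp
    n_sites = max(1, int(round(spec.snv_density * L)))
    pos = _site_positions(L, n_sites, rng)
    freqs = _population_frequencies(spec, n_sites, rng)

    panel_names = [p for p in spec.panel_sizes if p != "FOCAL"]
    n_focal = spec.panel_sizes.get("FOCAL", 0)
    samples, panels = [], []
    for p in panel_names:
        samples += [f"{p}_{i}" for i in range(spec.panel_sizes[p])]
        panels += [p] * spec.panel_sizes[p]
    samples += [f"FOCAL_{i}" for i in range(n_focal)]
    panels += ["FOCAL"] * n_focal

    dosage = np.empty((n_sites, len(samples)), dtype=np.int8)
    col = 0
    for p in panel_names:
        n = spec.panel_sizes[p]
        dosage[:, col : col + n] = rng.binomial(2, freqs[p][:, None], size=(n_sites, n))
        col += n
    a = spec.admixture_proportion
    for s in range(n_focal):
        hap_sum = np.zeros(n_sites, dtype=np.int8)
        for _hap in range(2):
            breaks, states = _mosaic_track(L, a, spec.switch_rate, rng)
            st = _states_at(breaks, states, pos - 1)
            p_hap = np.where(st == MUS, freqs["KOR"], freqs["IND"])
            hap_sum += (rng.random(n_sites) < p_hap).astype(np.int8)
        dosage[:, col + s] = hap_sum

    return GenotypeMatrix(
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=pos,
        dosage=dosage,
        samples=samples,
        panels=pd.Series(panels, index=samples),
    )


# --------------------------------------------------------------------------
# amplicon depth profiles


@dataclasses.dataclass
class DepthProfileSpec:
    """Poisson depth profile at tag sites of a multi-copy gene family.

    ``copy_number`` maps cluster id -> true haploid copy number.  A fraction
    of sites are injected as depth outliers (multiplied by
    ``outlier_multiplier``) and a fraction carry a sub-1 mappability score,
    emulating the artifacts the downstream filters are meant to remove.
    """

    copy_number: dict[str, float]
    coverage: float = 30.0  # haploid reference coverage (x)
    n_sites: int = 200
    outlier_fraction: float = 0.0
    outlier_multiplier: float = 10.0
    low_mappability_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(cn < 0 for cn in self.copy_number.values()):
            raise ValueError("copy numbers must be >= 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for fr in (self.outlier_fraction, self.low_mappability_fraction):
            if not 0.0 <= fr < 1.0:
                raise ValueError("fractions must be in [0, 1)")


def simulate_amplicon_depths(
    spec: DepthProfileSpec, genome_mean_depth: float | None = None
) -> pd.DataFrame:
    """Per-site diagnostic-allele depths for each cluster.

    depth ~ Poisson(copy_number * genome_mean_depth / 2) per tag site.
    Returns a SiteDepthTable DataFrame with columns cluster, coord,
    allele_depth, total_depth, mappability.
    """
    depth = spec.coverage if genome_mean_depth is None else genome_mean_depth
    if depth <= 0:
        raise ValueError("genome_mean_depth must be > 0")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cluster, cn in spec.copy_number.items():
        lam = cn * depth / 2.0
        d = rng.poisson(lam, spec.n_sites).astype(np.int64)
        mappability = np.ones(spec.n_sites)
        n_low = int(round(spec.low_mappability_fraction * spec.n_sites))
        if n_low:
            mappability[rng.choice(spec.n_sites, n_low, replace=False)] = 0.9
        n_out = int(round(spec.outlier_fraction * spec.n_sites))
        if n_out:
            out_idx = rng.choice(spec.n_sites, n_out, replace=False)
            d[out_idx] = np.round(d[out_idx] * spec.outlier_multiplier).astype(np.int64)
        background = rng.poisson(0.05 * depth, spec.n_sites)
        for i in range(spec.n_sites):
            rows.append(
                (
                    cluster,
                    i + 1,
                    int(d[i]),
                    int(d[i] + background[i]),
                    float(mappability[i]),
                )
            )
    return pd.DataFrame(
        rows, columns=["cluster", "coord", "allele_depth", "total_depth", "mappability"]
    )
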