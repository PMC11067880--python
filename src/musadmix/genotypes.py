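"""Genotype container and VCF / panel-file I/O.

The in-memory representation is a sites x samples matrix of alternate-allele
dosages (0, 1, 2, or -1 for missing) plus per-sample panel labels, which is
what every downstream statistic (f4, f4-ratio, Hudson FST, LD pruning)
consumes.  VCF coordinates are 1-based; window/BED coordinates elsewhere in
the package are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

_ALLOWED_DOSAGES = frozenset({-1, 0, 1, 2})


@dataclasses.dataclass
class GenotypeMatrix:
    """Biallelic SNV dosages for a cohort with panel labels.

    Parameters
    ----------
    chrom : array of str, one per site
    pos : array of int, 1-based positions, strictly increasing within chromosome
    dosage : (n_sites, n_samples) int array; -1 encodes a missing call
    samples : sample identifiers, one per dosage column
    panels : mapping sample id -> population/panel label
    """

    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    samples: list[str]
    panels: pd.Series

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.samples = list(self.samples)
        self.panels = pd.Series(self.panels).reindex(self.samples)
        if self.dosage.shape != (self.pos.size, len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{self.pos.size} sites x {len(self.samples)} samples"
            )
        bad = set(np.unique(self.dosage)) - _ALLOWED_DOSAGES
        if bad:
            raise ValueError(f"dosages outside {{-1,0,1,2}}: {sorted(bad)}")
        if self.pos.size > 1:
            same_chrom = self.chrom[1:] == self.chrom[:-1]
            if np.any(same_chrom & (np.diff(self.pos) <= 0)):
                raise ValueError("positions not strictly increasing within chromosome")
            # each chromosome must form one contiguous run of rows
            runs = [self.chrom[0]] + list(self.chrom[1:][~same_chrom])
            if len(set(runs)) != len(runs):
                raise ValueError("chromosome rows must be contiguous")
        if self.panels.isna().any():
            missing = self.panels.index[self.panels.isna()].tolist()
            raise ValueError(f"samples without panel label: {missing}")

    @property
    def n_sites(self) -> int:
        return self.pos.size

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def panel_labels(self) -> list[str]:
        return sorted(self.panels.unique())

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def panel_columns(self, label: str) -> np.ndarray:
        """Column indices of all samples in panel `label`."""
        cols = np.flatnonzero((self.panels == label).to_numpy())
        if cols.size == 0:
            raise KeyError(f"unknown or empty panel {label!r}")
        return cols

    def resolve_group(self, name: str) -> np.ndarray:
        """Columns for either a panel label or a single sample id."""
        if (self.panels == name).any():
            return self.panel_columns(name)
        if name in self.samples:
            return np.array([self.sample_index(name)])
        raise KeyError(f"{name!r} is neither a panel label nor a sample id")

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    # ------------------------------------------------------------------ I/O

    def to_vcf(self, path: str, extra_header: Sequence[str] = ()) -> None:
        """Write a minimal VCF v4.2 with GT calls.

        Synthetic sites carry fixed REF=A / ALT=G alleles.  No timestamp is
        written so identical matrices produce byte-identical files.
        """
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=musadmix\n")
            for line in extra_header:
                fh.write(f"##{line}\n")
            for c in self.chromosomes():
                length = int(self.pos[self.chrom == c].max())
                fh.write(f"##contig=<ID={c},length={length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for i in range(self.n_sites):
                calls = "\t".join(gt_codes[int(d)] for d in self.dosage[i])
                fh.write(
                    f"{self.chrom[i]}\t{self.pos[i]}\t.\tA\tG\t.\tPASS\t.\tGT\t{calls}\n"
                )

    @classmethod
    def from_vcf(cls, vcf_path: str, panel_path: str) -> "GenotypeMatrix":
        """Load biallelic SNVs from a VCF plus a sample->population TSV."""
        from cyvcf2 import VCF

        vcf = VCF(vcf_path, gts012=True)
        samples = list(vcf.samples)
        chroms: list[str] = []
        poss: list[int] = []
        rows: list[np.ndarray] = []
        for v in vcf:
            if len(v.ALT) != 1:
                continue
            # gts012: 0/1/2 = dosage, 3 = unknown
            g = np.asarray(v.gt_types, dtype=np.int8)
            g[g == 3] = MISSING
            chroms.append(v.CHROM)
            poss.append(v.POS)
            rows.append(g)
        vcf.close()
        panels = read_panel(panel_path)
        dosage = (
            np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
        )
        return cls(
            chrom=np.array(chroms, dtype=object),
            pos=np.array(poss, dtype=np.int64),
            dosage=dosage,
            samples=samples,
            panels=panels,
        )


def read_panel(path: str) -> pd.Series:
    """Read a two-column TSV (sample_id, population) into a Series."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["sample", "population"]
    )
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in panel file: {dups}")
    return pd.Series(df["population"].values, index=df["sample"].values)


def write_panel(panels: pd.Series, path: str) -> None:
    with open(path, "w") as fh:
        for sample, pop in panels.items():
            fh.write(f"{sample}\t{pop}\n")


def window_grid(chrom_lengths: dict[str, int], window_bp: int) -> pd.DataFrame:
    """Non-overlapping windows anchored at 0, 0-based half-open.

    The final partial window of each chromosome is retained.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, window_bp)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + window_bp, length))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def infer_chrom_lengths(geno: GenotypeMatrix) -> dict[str, int]:
    """Chromosome extents from the highest observed position."""
    return {
        c: int(geno.pos[geno.chrom == c].max()) for c in geno.chromosomes()
    }
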