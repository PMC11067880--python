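"""Copy-number estimation for high-identity multi-copy gene families.

Paralogs of an ampliconic family (e.g. the X-linked Slx/Slxl1 and Y-linked
Sly clusters) are too similar for per-copy mapping, but a multiple
alignment of the paralogous sequences exposes *tag SNVs*: alignment columns
where one cluster carries a diagnostic allele absent from every other
cluster.  Counting short-read depth of the diagnostic allele at those sites
and dividing the mean by half the genome-wide depth yields the per-cluster
copy number:

    CN = mean(diagnostic-allele depth over filtered tag sites)
         / (genome mean depth / 2)

Filters: only sites with mappability exactly 1 are trusted, and sites whose
diagnostic depth falls outside [median/3, 3*median] (median per cluster,
computed after the mappability filter; bounds inclusive) are excluded.
"""

from __future__ import annotations

import dataclasses
import re
from collections import Counter
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO


@dataclasses.dataclass
class TagSNV:
    """A cluster-diagnostic alignment column mapped to reference coords."""

    coord: int  # 1-based position on the designated reference sequence
    cluster: str
    allele: str
    mappability: float = 1.0


@dataclasses.dataclass
class ParalogAlignment:
    """Aligned paralog sequences with cluster labels.

    ``sequences`` maps sequence id -> aligned (gapped) sequence; every
    sequence must have the same aligned length.  ``clusters`` maps sequence
    id -> cluster id (e.g. X1, X2, Y1..Y6).  ``reference`` names the
    sequence whose ungapped coordinates tag sites are reported in.
    """

    sequences: dict[str, str]
    clusters: dict[str, str]
    reference: str

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"aligned lengths differ: {sorted(lengths)}")
        if len(set(self.clusters.values())) < 2:
            raise ValueError("need at least 2 clusters")
        missing = set(self.sequences) - set(self.clusters)
        if missing:
            raise ValueError(f"sequences without cluster label: {sorted(missing)}")
        for cl in set(self.clusters.values()):
            if not any(c == cl for c in self.clusters.values()):
                raise ValueError(f"cluster {cl} has zero sequences")
        if self.reference not in self.sequences:
            raise ValueError(f"reference {self.reference!r} not in alignment")

    @classmethod
    def from_files(
        cls, fasta_path: str, clusters_path: str, reference: str | None = None
    ) -> "ParalogAlignment":
        seqs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")
        }
        df = pd.read_csv(
            clusters_path, sep="\t", header=None, names=["seq", "cluster"], comment="#"
        )
        clusters = dict(zip(df["seq"], df["cluster"].astype(str)))
        if reference is None:
            reference = next(iter(seqs))
        return cls(sequences=seqs, clusters=clusters, reference=reference)


def find_tag_snvs(aln: ParalogAlignment) -> list[TagSNV]:
    """All cluster-diagnostic columns of the alignment.

    A column is a tag for cluster c if every member of c carries the same
    allele there and no member of any other cluster carries it.  Columns
    containing a gap in any sequence are skipped.  Coordinates are 1-based
    on the reference sequence (which, in a gap-free column, always has a
    base).
    """
    ids = list(aln.sequences)
    seqs = [aln.sequences[i] for i in ids]
    clusters = [aln.clusters[i] for i in ids]
    ref_seq = aln.sequences[aln.reference]
    length = len(ref_seq)
    tags: list[TagSNV] = []
    ref_coord = 0
    for col in range(length):
        if ref_seq[col] != "-":
            ref_coord += 1
        column = [s[col] for s in seqs]
        if "-" in column:
            continue
        by_cluster: dict[str, set[str]] = {}
        for allele, cl in zip(column, clusters):
            by_cluster.setdefault(cl, set()).add(allele)
        for cl, alleles in by_cluster.items():
            if len(alleles) != 1:
                continue
            allele = next(iter(alleles))
            others = {
                a for c2, al in by_cluster.items() if c2 != cl for a in al
            }
            if allele not in others:
                tags.append(TagSNV(coord=ref_coord, cluster=cl, allele=allele))
    return _drop_ambiguous(tags)


def _drop_ambiguous(tags: list[TagSNV]) -> list[TagSNV]:
    """Drop tags whose (coordinate, allele) pair is claimed by more than
    one cluster: such a diagnostic allele is ambiguous on the reference."""
    counts = Counter((t.coord, t.allele) for t in tags)
    return [t for t in tags if counts[(t.coord, t.allele)] == 1]


# --------------------------------------------------------------------------
# depth filtering and estimation


class EmptyDepthTable(ValueError):
    """All sites were removed by filtering; no estimate is possible."""


def filter_sites(
    depths: pd.DataFrame,
    depth_column: str = "allele_depth",
) -> pd.DataFrame:
    """Apply the mappability and median-depth filters per cluster.

    Keeps sites with mappability exactly 1 whose ``depth_column`` lies in
    [median/3, 3*median] inclusive, the median being taken per cluster over
    mappability-passing sites.  ``depth_column`` defaults to the diagnostic
    allele depth; pass "total_depth" to filter on total site depth instead.
    """
    if depths.empty:
        raise ValueError("depth table is empty")
    kept = []
    for cluster, grp in depths.groupby("cluster", sort=False):
        mappable = grp[grp["mappability"] == 1.0]
        if mappable.empty:
            continue
        med = float(mappable[depth_column].median())
        lo, hi = med / 3.0, 3.0 * med
        ok = mappable[(mappable[depth_column] >= lo) & (mappable[depth_column] <= hi)]
        kept.append(ok)
    if not kept:
        raise EmptyDepthTable("no sites survive the mappability/depth filters")
    return pd.concat(kept, ignore_index=True)


def estimate_copy_number(
    depths_filtered: pd.DataFrame,
    genome_mean_depth: float,
    sample: str = "sample",
    n_filtered: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-cluster copy number from filtered diagnostic-allele depths.

    CN = mean(allele depth) / (genome_mean_depth / 2).  Returns a DataFrame
    with columns sample, cluster, copy_number, n_sites_used, n_filtered.
    """
    if genome_mean_depth <= 0:
        raise ValueError("genome_mean_depth must be > 0")
    if depths_filtered.empty:
        raise EmptyDepthTable("no usable sites for copy-number estimation")
    rows = []
    for cluster, grp in depths_filtered.groupby("cluster", sort=False):
        cn = float(grp["allele_depth"].mean() / (genome_mean_depth / 2.0))
        nf = (n_filtered or {}).get(cluster, 0)
        rows.append((sample, cluster, cn, len(grp), nf))
    return pd.DataFrame(
        rows, columns=["sample", "cluster", "copy_number", "n_sites_used", "n_filtered"]
    )


def estimate_from_depths(
    depths: pd.DataFrame,
    genome_mean_depth: float,
    sample: str = "sample",
    depth_column: str = "allele_depth",
) -> pd.DataFrame:
    """Convenience: filter then estimate, tracking per-cluster filter counts."""
    filtered = filter_sites(depths, depth_column=depth_column)
    n_before = depths.groupby("cluster", sort=False).size()
    n_after = filtered.groupby("cluster", sort=False).size()
    n_filtered = {
        cl: int(n_before.get(cl, 0) - n_after.get(cl, 0)) for cl in n_before.index
    }
    return estimate_copy_number(
        filtered, genome_mean_depth, sample=sample, n_filtered=n_filtered
    )


# --------------------------------------------------------------------------
# pileup parsing

_INDEL_RE = re.compile(r"[+-](\d+)")


def parse_pileup_bases(bases: str, ref: str) -> Counter:
    """Count base calls in one samtools-mpileup base string.

    Handles read starts (^ + mapq char), read ends ($), indels (+n/-n
    followed by n bases, which belong to the next position), deletions (*)
    and the ./,, ref shorthand.
    """
    counts: Counter = Counter()
    i = 0
    ref = ref.upper()
    while i < len(bases):
        c = bases[i]
        if c == "^":
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = _INDEL_RE.match(bases, i)
            n = int(m.group(1))
            i = m.end() + n
            continue
        if c in ".,":
            counts[ref] += 1
        elif c == "*":
            counts["*"] += 1
        else:
            counts[c.upper()] += 1
        i += 1
    return counts


def depth_table_from_pileup(
    pileup_path: str,
    tags: Iterable[TagSNV],
    mappability: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Build a SiteDepthTable from an mpileup file and a tag-SNV set.

    ``mappability`` maps 1-based coordinate -> score; unlisted coordinates
    default to 1.0.
    """
    by_coord: dict[int, list[TagSNV]] = {}
    for t in tags:
        by_coord.setdefault(t.coord, []).append(t)
    rows = []
    with open(pileup_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            pos = int(parts[1])
            if pos not in by_coord:
                continue
            ref, depth, bases = parts[2], int(parts[3]), parts[4]
            counts = parse_pileup_bases(bases, ref)
            for t in by_coord[pos]:
                score = (mappability or {}).get(pos, 1.0)
                rows.append(
                    (t.cluster, pos, int(counts.get(t.allele.upper(), 0)), depth, score)
                )
    return pd.DataFrame(
        rows, columns=["cluster", "coord", "allele_depth", "total_depth", "mappability"]
    )
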