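"""Gap-sites: the inner borders of gapped (spliced) read alignments.

All reads covering the same splicing event share the two inner coordinates
of their alignment gap, so a gap-site — identified by
``(chrom, left_end, right_start)`` — is a surrogate for a splice junction,
and the number of reads on a gap-site estimates how often the junction is
used.  Coordinates are 1-based inclusive (SAM convention): ``left_end`` is
the last aligned base before the gap, ``right_start`` the first aligned
base after it.  BED export converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# CIGAR operation codes (SAM spec); ops that consume reference positions.
_CIGAR_N = 3
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X


@dataclass(frozen=True, order=True)
class GapSite:
    """One splicing event's coordinates.

    Identity (equality, hashing, ordering) is by ``(chrom, left_end,
    right_start)`` only; strand is carried along when known but does not
    distinguish gap-sites.
    """

    chrom: str
    left_end: int
    right_start: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.right_start > self.left_end + 1:
            raise ValueError(
                f"gap-site must span a gap of >= 1 base: "
                f"left_end={self.left_end}, right_start={self.right_start}")

    @property
    def key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.left_end, self.right_start)

    @property
    def feature_id(self) -> str:
        return f"{self.chrom}:{self.left_end}-{self.right_start}"


@dataclass
class GeneModel:
    """A gene as an ordered set of disjoint exons on one chromosome.

    Every intron (the interval between two adjacent exons) defines exactly
    one annotated gap-site.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]  # 1-based closed intervals, sorted

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs >= 1 exon")
        ex = sorted(tuple(e) for e in self.exons)
        for (a, b) in ex:
            if b < a:
                raise ValueError(f"gene {self.gene_id}: exon end < start")
        for (_, b0), (a1, _) in zip(ex, ex[1:]):
            if a1 <= b0:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        self.exons = ex

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    @property
    def exonic_length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    def introns(self) -> List[Tuple[int, int]]:
        """1-based closed intronic intervals between adjacent exons."""
        return [(b0 + 1, a1 - 1) for (_, b0), (a1, _)
                in zip(self.exons, self.exons[1:])]

    def annotated_gap_sites(self) -> List[GapSite]:
        """One gap-site per intron: (last exon base, first next-exon base)."""
        return [GapSite(self.chrom, b0, a1, self.strand)
                for (_, b0), (a1, _) in zip(self.exons, self.exons[1:])]


class CountMatrix:
    """Features x samples non-negative integer counts plus sample metadata.

    ``counts`` is a DataFrame indexed by feature id with one column per
    sample; ``samples`` is a DataFrame indexed by sample id carrying the
    design factors (age_group, gender, location, donor, ...);
    ``feature_genes`` maps feature ids to gene ids (may be absent for
    gene-level matrices whose feature ids are the gene ids).
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame,
                 feature_genes: pd.Series | None = None):
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if counts.index.duplicated().any():
            raise ValueError("duplicate feature ids in count matrix")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = [s for s in counts.columns if s not in samples.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        self.counts = counts.rename_axis(index="feature_id")
        self.samples = samples.loc[counts.columns]
        self.feature_genes = feature_genes

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        if self.feature_genes is not None:
            out.insert(0, "gene_id", self.feature_genes)
        out.to_csv(path, sep="\t", index_label="feature_id",
                   lineterminator="\n")

    @classmethod
    def from_tsv(cls, path, samples: pd.DataFrame) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        genes = None
        if "gene_id" in df.columns:
            genes = df.pop("gene_id")
        return cls(df, samples, feature_genes=genes)


# ---------------------------------------------------------------------------
# extraction from gapped alignments


def extract_gap_sites(alignments: Iterable,
                      min_mapq: int | None = None) -> Dict[GapSite, int]:
    """Count reads on gap-sites from gapped alignment records.

    ``alignments`` yields pysam ``AlignedSegment``-like records (attributes
    ``reference_name``, ``reference_start`` 0-based, ``cigartuples``).  Each
    N operation of each record contributes 1 to its gap-site; a read with
    several gaps counts once per gap.  Records without reference
    coordinates are skipped (their number is logged).
    """
    counts: Counter = Counter()
    skipped = 0
    for rec in alignments:
        if getattr(rec, "is_unmapped", False):
            skipped += 1
            continue
        ref = getattr(rec, "reference_name", None)
        start = getattr(rec, "reference_start", None)
        cig = getattr(rec, "cigartuples", None)
        if ref is None or start is None or not cig:
            skipped += 1
            continue
        if min_mapq is not None and getattr(rec, "mapping_quality", 0) < min_mapq:
            skipped += 1
            continue
        strand = "-" if getattr(rec, "is_reverse", False) else "+"
        pos = start  # 0-based cursor == 1-based last consumed base
        for op, length in cig:
            if op == _CIGAR_N:
                counts[GapSite(ref, pos, pos + length + 1, strand)] += 1
            if op in _REF_CONSUMING:
                pos += length
    if skipped:
        logger.info("extract_gap_sites: skipped %d records without usable "
                    "coordinates", skipped)
    return dict(counts)


def read_alignments(path, mode: str = "r"):
    """Open a SAM/BAM file with pysam and yield its records."""
    import pysam

    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        yield from fh


def filter_ubiquitous(per_sample: Mapping[str, Mapping[GapSite, int]],
                      samples: Sequence[str] | None = None) -> Set[GapSite]:
    """Gap-sites supported by >= 1 read in *every* sample."""
    if samples is None:
        samples = list(per_sample)
    if not samples:
        raise ValueError("need at least one sample")
    it = iter(samples)
    first = next(it)
    kept = {s for s, c in per_sample[first].items() if c >= 1}
    for sid in it:
        m = per_sample[sid]
        kept = {s for s in kept if m.get(s, 0) >= 1}
        if not kept:
            break
    return kept


def match_annotation(sites: Iterable[GapSite],
                     genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Match gap-sites to annotated introns by exact boundary equality.

    Returns one row per (site, gene) assignment with columns
    ``feature_id, chrom, left_end, right_start, gene_id, ambiguous``.
    A site is annotated iff its coordinates exactly equal an intron's
    boundaries; a site matching introns of several genes is assigned to
    all of them and flagged ambiguous.
    """
    genes = list(genes)
    sites = list(sites)
    intron_index: Dict[Tuple[str, int, int], List[str]] = {}
    for g in genes:
        for s in g.annotated_gap_sites():
            intron_index.setdefault(s.key, []).append(g.gene_id)
    gene_chroms = {g.chrom for g in genes}
    site_chroms = {s.chrom for s in sites}
    if sites and gene_chroms and not (site_chroms & gene_chroms):
        raise ValueError(
            f"no gap-site chromosome matches the annotation "
            f"(sites: {sorted(site_chroms)}, annotation: "
            f"{sorted(gene_chroms)}); check naming conventions")
    rows = []
    for s in sorted(sites):
        hits = intron_index.get(s.key)
        if not hits:
            continue
        ambiguous = len(hits) > 1
        for gid in sorted(hits):
            rows.append((s.feature_id, s.chrom, s.left_end, s.right_start,
                         gid, ambiguous))
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "left_end",
                                       "right_start", "gene_id", "ambiguous"])


def assemble_count_matrix(per_sample: Mapping[str, Mapping[GapSite, int]],
                          annotated: pd.DataFrame,
                          sample_table: pd.DataFrame) -> CountMatrix:
    """Build the gap-site x sample CountMatrix over annotated sites."""
    if sample_table.index.duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    feats = annotated.drop_duplicates("feature_id")
    keys = list(zip(feats["chrom"], feats["left_end"], feats["right_start"]))
    sample_ids = list(sample_table.index)
    mat = np.zeros((len(keys), len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        m = {s.key: c for s, c in per_sample[sid].items()}
        for i, key in enumerate(keys):
            mat[i, j] = m.get(key, 0)
    counts = pd.DataFrame(mat, index=list(feats["feature_id"]),
                          columns=sample_ids)
    gene_map = (annotated.sort_values(["feature_id", "gene_id"])
                .drop_duplicates("feature_id").set_index("feature_id")["gene_id"])
    return CountMatrix(counts, sample_table,
                       feature_genes=gene_map.reindex(counts.index))


def write_bed(sites: Iterable[GapSite], path) -> None:
    """Write gap-site intron intervals as BED (0-based half-open)."""
    with open(path, "w", newline="\n") as fh:
        for s in sorted(set(sites)):
            # intron bases 1-based closed: [left_end+1, right_start-1]
            fh.write(f"{s.chrom}\t{s.left_end}\t{s.right_start - 1}\t"
                     f"{s.feature_id}\t0\t{s.strand}\n")


def read_bed(path) -> List[GapSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "."
            sites.append(GapSite(f[0], int(f[1]), int(f[2]) + 1, strand))
    return sites
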