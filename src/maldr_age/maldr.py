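"""The MALDR filter: monotone alignment-depth ratios across age groups.

A gene passes when, over more than 99% of its *restricted genetic region*
(gene positions left after cutting introns and low-coverage stretches),
the loess-smoothed group-mean alignment depth satisfies a strict
adjacent-group ratio > 1.2 in one consistent direction,
Young < Middle < Old or Old < Middle < Young.  The filter is sensitive to
ordering, not to effect size or baseline expression, and — deliberately —
also to a few strongly deviating donors inflating one group's mean, the
caveat exemplified by the ID1 expression pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from maldr_age.gapsites import GapSite, GeneModel
from maldr_age.params import MaldrParameters
from maldr_age.smoothing import loess_smooth

logger = logging.getLogger(__name__)

AGE_GROUP_ORDER = ("Young", "Middle", "Old")
_EPS = 1e-9  # pseudo-depth guarding ratio denominators


@dataclass
class DepthProfile:
    """Per-base alignment depth over one gene region for one sample."""

    gene_id: str
    sample_id: str
    positions: np.ndarray  # 1-based genomic coordinates, strictly increasing
    depth: np.ndarray      # non-negative integers, one per position

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth)
        if self.positions.shape != self.depth.shape:
            raise ValueError("positions and depth must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative")


class GeneDepth:
    """Depth profiles of all samples for one gene on a common grid."""

    def __init__(self, gene_id: str, positions, depth: np.ndarray,
                 sample_ids: Sequence[str], chrom: str | None = None):
        self.gene_id = gene_id
        self.positions = np.asarray(positions, dtype=np.int64)
        self.depth = np.asarray(depth)
        self.sample_ids = list(sample_ids)
        self.chrom = chrom
        if self.depth.shape != (len(self.sample_ids), self.positions.size):
            raise ValueError("depth must be (n_samples, n_positions)")

    def profile(self, sample_id: str) -> DepthProfile:
        i = self.sample_ids.index(sample_id)
        return DepthProfile(self.gene_id, sample_id,
                            self.positions, self.depth[i])

    @classmethod
    def from_profiles(cls, profiles: Iterable[DepthProfile],
                      chrom: str | None = None) -> "GeneDepth":
        profiles = list(profiles)
        if not profiles:
            raise ValueError("no profiles")
        gid = profiles[0].gene_id
        pos = profiles[0].positions
        for p in profiles[1:]:
            if p.gene_id != gid or not np.array_equal(p.positions, pos):
                raise ValueError("profiles must share gene and position grid")
        depth = np.stack([p.depth for p in profiles])
        return cls(gid, pos, depth, [p.sample_id for p in profiles], chrom)


@dataclass
class RestrictedRegion:
    """Positions kept after the intron cut and the low-coverage cut.

    Removal reasons are mutually exclusive; the intron cut is applied
    first, so a position inside a gap-site is never additionally counted
    as low-coverage.
    """

    gene_id: str
    kept_positions: np.ndarray
    removed_intronic: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=np.int64))
    removed_low_coverage: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=np.int64))


@dataclass
class SmoothedGroupCurves:
    """One smoothed mean-depth curve per age group on a shared grid."""

    gene_id: str
    groups: Tuple[str, ...]
    positions: np.ndarray
    curves: np.ndarray  # (n_groups, n_positions), non-negative

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.shape != (len(self.groups), self.positions.size):
            raise ValueError("curves must be (n_groups, n_positions)")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.curves.T, columns=list(self.groups))
        df.insert(0, "position", self.positions)
        df.insert(0, "gene_id", self.gene_id)
        return df


@dataclass
class MaldrResult:
    """Per-gene outcome of the monotone-ratio filter."""

    gene_id: str
    direction: str            # "increasing" | "decreasing" | "none"
    monotone_fraction: float  # fraction of kept positions, dominant direction
    passes: bool
    n_positions: int = 0


# ---------------------------------------------------------------------------
# pipeline stages


def restrict_introns(positions, gene_id: str,
                     gap_sites: Iterable[GapSite]) -> RestrictedRegion:
    """Stage-1 cut: drop positions strictly inside observed gap-sites.

    A position p is intronic when ``left_end < p < right_start`` for any
    of the gene's gap-sites; overlapping gap-sites are unioned.  With no
    gap-sites the region is returned unchanged.
    """
    pos = np.asarray(positions, dtype=np.int64)
    intronic = np.zeros(pos.size, dtype=bool)
    for s in gap_sites:
        intronic |= (pos > s.left_end) & (pos < s.right_start)
    return RestrictedRegion(gene_id, kept_positions=pos[~intronic],
                            removed_intronic=pos[intronic])


def group_mean_depth(gene_depth: GeneDepth, sample_table: pd.DataFrame,
                     group_col: str = "age_group",
                     group_order: Sequence[str] = AGE_GROUP_ORDER,
                     positions=None) -> pd.DataFrame:
    """Arithmetic mean of raw depth per group per position.

    Returns a (group x position) frame with rows in ``group_order``.
    Depth is averaged in absolute numbers — no library-size scaling.
    """
    pos = gene_depth.positions if positions is None \
        else np.asarray(positions, dtype=np.int64)
    col_idx = np.searchsorted(gene_depth.positions, pos)
    if np.any(col_idx >= gene_depth.positions.size) or \
            not np.array_equal(gene_depth.positions[col_idx], pos):
        raise ValueError("requested positions missing from the depth grid")
    groups = sample_table.loc[gene_depth.sample_ids, group_col]
    rows = []
    for g in group_order:
        members = np.asarray(groups == g)
        if not members.any():
            raise ValueError(f"group {g!r} has no samples")
        rows.append(gene_depth.depth[members][:, col_idx].mean(axis=0))
    return pd.DataFrame(rows, index=list(group_order), columns=pos)


def smooth_group_curves(group_means: pd.DataFrame, gene_id: str,
                        span: float = 0.3) -> SmoothedGroupCurves:
    """Loess-smooth each group's mean-depth curve independently."""
    pos = group_means.columns.to_numpy(dtype=np.int64)
    curves = np.stack([loess_smooth(pos, group_means.loc[g].to_numpy(), span)
                       for g in group_means.index])
    return SmoothedGroupCurves(gene_id, tuple(group_means.index), pos, curves)


def restrict_low_coverage(curves: SmoothedGroupCurves,
                          params: MaldrParameters | None = None,
                          region: RestrictedRegion | None = None,
                          ) -> Tuple[SmoothedGroupCurves, RestrictedRegion]:
    """Stage-2 cut: drop positions where every group is below the cut.

    The cut is ``low_coverage_frac`` (default 2%) of the maximal smoothed
    depth over all groups and positions of the gene; a position survives
    if *any* group reaches the cut.  If nothing survives the returned
    region is empty and the caller must treat the gene as unevaluable.
    """
    if params is None:
        params = MaldrParameters()
    m = curves.curves.max() if curves.curves.size else 0.0
    if m <= 0.0:  # no coverage anywhere: nothing survives the cut
        keep = np.zeros(curves.positions.size, dtype=bool)
    else:
        keep = (curves.curves >= params.low_coverage_frac * m).any(axis=0)
    removed = curves.positions[~keep]
    kept = curves.positions[keep]
    if region is None:
        region = RestrictedRegion(curves.gene_id, kept_positions=kept,
                                  removed_low_coverage=removed)
    else:
        region = RestrictedRegion(curves.gene_id, kept_positions=kept,
                                  removed_intronic=region.removed_intronic,
                                  removed_low_coverage=removed)
    if kept.size == 0:
        logger.info("gene %s: all positions below the coverage cut; "
                    "unevaluable", curves.gene_id)
    out = SmoothedGroupCurves(curves.gene_id, curves.groups, kept,
                              curves.curves[:, keep])
    return out, region


def monotone_fraction(curves: SmoothedGroupCurves,
                      params: MaldrParameters | None = None) -> MaldrResult:
    """Fraction of kept positions with a strict monotone adjacent ratio.

    A position is increasing-monotone iff Middle/Young > ratio_threshold
    AND Old/Middle > ratio_threshold; decreasing-monotone with the
    reciprocal ratios.  The reported fraction is that of the dominant
    direction; the gene passes iff it strictly exceeds
    ``fraction_threshold``.  Zero denominators are guarded by a
    pseudo-depth of 1e-9.
    """
    if params is None:
        params = MaldrParameters()
    if len(curves.groups) != 3:
        raise ValueError("monotone_fraction needs exactly 3 ordered groups")
    if curves.positions.size < 1:
        raise ValueError("no kept positions")
    t = params.ratio_threshold
    y, m, o = curves.curves

    def _ratio(num, den):
        return num / np.where(den <= 0.0, _EPS, den)

    inc = (_ratio(m, y) > t) & (_ratio(o, m) > t)
    dec = (_ratio(y, m) > t) & (_ratio(m, o) > t)
    frac_inc = float(inc.mean())
    frac_dec = float(dec.mean())
    if frac_inc > frac_dec:
        direction, frac = "increasing", frac_inc
    elif frac_dec > frac_inc:
        direction, frac = "decreasing", frac_dec
    else:
        direction, frac = "none", frac_inc
    return MaldrResult(curves.gene_id, direction, frac,
                       passes=frac > params.fraction_threshold,
                       n_positions=int(curves.positions.size))


def run_maldr(gene_ids: Iterable[str],
              depths: Mapping[str, GeneDepth],
              gene_gap_sites: Mapping[str, List[GapSite]],
              sample_table: pd.DataFrame,
              params: MaldrParameters | None = None,
              group_col: str = "age_group",
              group_order: Sequence[str] = AGE_GROUP_ORDER,
              cut_on_raw: bool = False,
              return_curves: bool = False):
    """Full MALDR stage for the pre-filtered gene set.

    Per gene: intron cut -> group means -> loess smoothing -> low-coverage
    cut -> monotone-ratio fraction.  With ``cut_on_raw=True`` the coverage
    cut is applied to the raw group means before smoothing instead.
    Genes without profiles, or whose region empties out, are skipped with
    a log entry.  Deterministic for fixed inputs.
    """
    if params is None:
        params = MaldrParameters()
    results: List[MaldrResult] = []
    curve_store: Dict[str, SmoothedGroupCurves] = {}
    for gid in sorted(set(gene_ids)):
        gd = depths.get(gid)
        if gd is None:
            logger.info("gene %s: no depth profiles; skipped", gid)
            continue
        region = restrict_introns(gd.positions, gid,
                                  gene_gap_sites.get(gid, ()))
        if region.kept_positions.size == 0:
            logger.info("gene %s: entirely intronic; skipped", gid)
            continue
        means = group_mean_depth(gd, sample_table, group_col, group_order,
                                 positions=region.kept_positions)
        if cut_on_raw:
            raw = SmoothedGroupCurves(gid, tuple(group_order),
                                      region.kept_positions,
                                      means.to_numpy(dtype=float))
            raw, region = restrict_low_coverage(raw, params, region)
            if raw.positions.size == 0:
                continue
            means = means[raw.positions]
            curves = smooth_group_curves(means, gid, params.loess_span)
        else:
            curves = smooth_group_curves(means, gid, params.loess_span)
            curves, region = restrict_low_coverage(curves, params, region)
            if curves.positions.size == 0:
                continue
        results.append(monotone_fraction(curves, params))
        if return_curves:
            curve_store[gid] = curves
    df = pd.DataFrame(
        [(r.gene_id, r.direction, r.monotone_fraction, r.passes,
          r.n_positions) for r in results],
        columns=["gene_id", "direction", "monotone_fraction", "passes",
                 "n_positions"]).set_index("gene_id")
    if return_curves:
        return df, curve_store
    return df


# ---------------------------------------------------------------------------
# text I/O


def write_depth_bedgraph(profile: DepthProfile, chrom: str, path) -> None:
    """Write one sample's depth as bedGraph (0-based half-open, rle)."""
    pos = profile.positions
    dep = profile.depth
    with open(path, "w", newline="\n") as fh:
        if pos.size == 0:
            return
        run_start = 0
        for i in range(1, pos.size + 1):
            last = i == pos.size
            if last or pos[i] != pos[i - 1] + 1 or dep[i] != dep[run_start]:
                fh.write(f"{chrom}\t{pos[run_start] - 1}\t"
                         f"{pos[i - 1]}\t{int(dep[run_start])}\n")
                run_start = i


def read_depth_bedgraph(path, gene_id: str, sample_id: str) -> DepthProfile:
    pos: List[int] = []
    dep: List[int] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            _, start, end, value = line.split("\t")
            for p in range(int(start) + 1, int(end) + 1):
                pos.append(p)
                dep.append(int(float(value)))
    return DepthProfile(gene_id, sample_id, np.array(pos), np.array(dep))


def write_curves_tsv(curves: Mapping[str, SmoothedGroupCurves], path) -> None:
    frames = [curves[g].to_frame() for g in sorted(curves)]
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["gene_id", "position"]))
    out.to_csv(path, sep="\t", index=False, float_format="%.6g",
               lineterminator="\n")
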