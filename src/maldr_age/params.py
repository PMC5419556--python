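"""Numeric thresholds of the MALDR method, collected in one place."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass
class MaldrParameters:
    """All tunable thresholds of the screening method.

    Attributes
    ----------
    prefilter_fdr
        BH-adjusted p-value cut for the gap-site pre-filter; a gene enters
        the depth analysis when at least one of its gap-sites falls strictly
        below this FDR.
    low_coverage_frac
        Positions where every group's smoothed depth is below this fraction
        of the gene's maximal smoothed depth are removed.
    ratio_threshold
        Adjacent-group depth ratio that must be strictly exceeded at a
        position for it to count as monotone.
    fraction_threshold
        Fraction of the restricted region that must be monotone (strictly
        exceeded) for the gene to pass.
    correlation_threshold
        Pairwise CPM correlation defining the co-expressed gene set.
    loess_span
        Fraction of positions in each local regression window.
    """

    prefilter_fdr: float = 0.1
    low_coverage_frac: float = 0.02
    ratio_threshold: float = 1.2
    fraction_threshold: float = 0.99
    correlation_threshold: float = 0.8
    loess_span: float = 0.3

    def __post_init__(self) -> None:
        for name in ("prefilter_fdr", "low_coverage_frac",
                     "fraction_threshold", "correlation_threshold",
                     "loess_span"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0 and not (name == "loess_span" and v == 1.0):
                raise ValueError(f"{name} must lie in (0, 1); got {v!r}")
        if not self.ratio_threshold > 1.0:
            raise ValueError(
                f"ratio_threshold must exceed 1; got {self.ratio_threshold!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MaldrParameters":
        return cls(**d)
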