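"""Curated gene sets for the dermal-fibroblast ageing cohort.

The original fibroblast ageing cohort that this pipeline models reported
42 age-MAR genes (genes passing the monotone alignment-depth-ratio
filter across age groups).  Among them, the literature assigns a
TGF-beta signalling role to twelve: eight genes directly regulated by
TGF-beta, the pathway's negative-feedback regulator SMAD7, two
SMAD-interacting genes (FAM83G, SERTAD1), and the lncRNA MEG3 which
regulates TGF-beta pathway genes.  These sets back the membership
summaries in :func:`tgfb_related_fraction`.
"""

from __future__ import annotations

from typing import FrozenSet

#: Age-MAR genes directly regulated by TGF-beta.
TGFB_REGULATED: FrozenSet[str] = frozenset(
    {"ATOH8", "SNAI1", "ID3", "SPHK1", "ID1", "CNN1", "PRRX2", "ROBO1"})

#: Further age-MAR genes tied to TGF-beta signalling: SMAD7 (negative
#: feedback), FAM83G and SERTAD1 (SMAD interactors), MEG3 (lncRNA
#: regulator of pathway genes).
TGFB_PATHWAY_LINKED: FrozenSet[str] = frozenset(
    {"SMAD7", "FAM83G", "SERTAD1", "MEG3"})

#: All TGF-beta signalling related age-MAR genes.
TGFB_RELATED: FrozenSet[str] = TGFB_REGULATED | TGFB_PATHWAY_LINKED

#: Number of age-MAR genes reported for the cohort.
N_AGE_MAR_GENES: int = 42

#: The nine age-MAR genes whose pairwise CPM correlations all exceed 0.8
#: in the cohort.
CORRELATED_NINE: FrozenSet[str] = frozenset(
    {"ATOH8", "SNAI1", "ID3", "SPHK1", "ID1", "PRRX2", "SMAD7", "FAM83G",
     "SERTAD1"})


def tgfb_related_fraction(n_age_mar: int = N_AGE_MAR_GENES) -> float:
    """Percentage of age-MAR genes with a TGF-beta signalling link."""
    if n_age_mar <= 0:
        raise ValueError("n_age_mar must be positive")
    return 100.0 * len(TGFB_RELATED) / n_age_mar
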