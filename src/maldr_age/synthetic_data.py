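"""Synthetic annotation, cohort, gap-site counts and depth profiles.

The generator emulates the statistical structure of the fibroblast ageing
cohort that the analysis assumes: 27 donors in three ordered age groups
(Young 18-25, Middle 35-49, Old 60-67), one sun-exposed and one
sun-protected sample per donor (54 samples, 18 per age group, 13 female /
14 male donors), negative-binomially dispersed gap-site counts with a
donor-level random effect shared between a donor's two samples,
exon/intron depth structure with a small intronic leakage, and injectable
effects: monotone age trends, a few strongly over-expressing donors (the
ID1-like pattern), gender or location bias.

Counts and depth are coupled through a common latent expression surface:
calling :func:`simulate_counts` and :func:`simulate_depth_profiles` with
the same genes, samples, effects and seed draws the gene weights and
donor effects from identical streams, so gap-site counts and exonic depth
agree up to sampling noise.  Depth is simulated directly per base (not
via simulated reads); a read-level FASTQ emitter exists only for QC
fixtures.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from maldr_age.gapsites import GapSite, GeneModel, CountMatrix
from maldr_age.maldr import GeneDepth

EFFECT_KINDS = ("monotone_up", "monotone_down", "outlier_donors",
                "gender_biased", "location_biased", "null")

DEFAULT_READ_LEN = 101   # sequencing reads of the emulated platform
DEFAULT_DISPERSION = 0.1  # typical bulk RNA-seq NB dispersion
DEFAULT_DONOR_SIGMA = 0.3  # log-normal sd of the donor random effect
DEFAULT_LEAKAGE = 0.01   # intronic depth as a fraction of exonic depth


@dataclass
class SyntheticGenomeSpec:
    """Layout of the synthetic chromosome and its gene models."""

    n_genes: int = 20
    exons_per_gene: Tuple[int, int] = (2, 4)
    exon_len: Tuple[int, int] = (120, 240)
    intron_len: Tuple[int, int] = (60, 150)
    chrom_name: str = "chrS"
    chrom_len: int | None = None          # None: sized to fit
    intergenic_len: Tuple[int, int] = (200, 500)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.exons_per_gene[0] < 1:
            raise ValueError("every gene needs >= 1 exon")
        for name in ("exons_per_gene", "exon_len", "intron_len",
                     "intergenic_len"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range invalid: ({lo}, {hi})")


@dataclass
class AgeGroupSpec:
    name: str
    age_min: int
    age_max: int
    n_donors: int
    n_female: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_female <= self.n_donors:
            raise ValueError(f"group {self.name}: invalid gender counts")
        if self.age_max < self.age_min:
            raise ValueError(f"group {self.name}: invalid age range")


def _default_age_groups() -> List[AgeGroupSpec]:
    return [AgeGroupSpec("Young", 18, 25, 9, 4),
            AgeGroupSpec("Middle", 35, 49, 9, 5),
            AgeGroupSpec("Old", 60, 67, 9, 4)]


@dataclass
class CohortSpec:
    """Donor cohort layout: one sample per donor per location."""

    n_donors: int = 27
    age_groups: List[AgeGroupSpec] = field(default_factory=_default_age_groups)
    genders: Tuple[str, str] = ("female", "male")
    locations: Tuple[str, str] = ("sun_exposed", "sun_protected")
    lib_size: Tuple[int, int] = (200_000, 300_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(g.n_donors for g in self.age_groups) != self.n_donors:
            raise ValueError("age-group donor counts must sum to n_donors")
        if self.lib_size[0] < 1 or self.lib_size[1] < self.lib_size[0]:
            raise ValueError("invalid lib_size range")

    @property
    def group_order(self) -> Tuple[str, ...]:
        return tuple(g.name for g in self.age_groups)


@dataclass
class EffectSpec:
    """A per-gene expression effect injected into the simulation."""

    gene_id: str
    effect_kind: str
    ratio: float = 1.0              # fold-change per adjacent group step
    outlier_donor_ids: Tuple[str, ...] = ()
    outlier_fold: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect_kind {self.effect_kind!r}")
        if self.ratio < 1.0:
            raise ValueError("ratio must be >= 1")
        if self.effect_kind != "outlier_donors" and (
                self.outlier_donor_ids or self.outlier_fold != 1.0):
            raise ValueError("outlier fields only valid for outlier_donors")


# ---------------------------------------------------------------------------
# gene models


def generate_gene_models(spec: SyntheticGenomeSpec,
                         seed: int) -> List[GeneModel]:
    """Lay out non-overlapping gene models on the synthetic chromosome.

    Every intron defines exactly one annotated gap-site.  Raises when the
    declared chromosome length cannot hold the drawn genes.
    """
    rng = np.random.default_rng([int(seed), 11])
    genes: List[GeneModel] = []
    cursor = 1
    width = len(str(spec.n_genes))
    for i in range(spec.n_genes):
        cursor += int(rng.integers(spec.intergenic_len[0],
                                   spec.intergenic_len[1] + 1))
        n_ex = int(rng.integers(spec.exons_per_gene[0],
                                spec.exons_per_gene[1] + 1))
        exons = []
        pos = cursor
        for j in range(n_ex):
            elen = int(rng.integers(spec.exon_len[0], spec.exon_len[1] + 1))
            exons.append((pos, pos + elen - 1))
            pos += elen
            if j < n_ex - 1:
                pos += int(rng.integers(spec.intron_len[0],
                                        spec.intron_len[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"G{i + 1:0{width}d}", spec.chrom_name,
                               strand, exons))
        cursor = exons[-1][1] + 1
    if spec.chrom_len is not None and cursor - 1 > spec.chrom_len:
        raise ValueError(
            f"genes need {cursor - 1} bp but chrom_len is {spec.chrom_len}")
    return genes


def write_gtf(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as GTF (1-based closed, deterministic text)."""
    with open(path, "w", newline="\n") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.chrom}\tmaldr_sim\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for k, (a, b) in enumerate(g.exons, start=1):
                fh.write(f"{g.chrom}\tmaldr_sim\texon\t{a}\t{b}\t.\t"
                         f"{g.strand}\t.\t{attrs} exon_number \"{k}\";\n")


def read_gtf(path) -> List[GeneModel]:
    """Read gene models from GTF exon lines (as written by write_gtf)."""
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str]] = {}
    order: List[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            gid = f[8].split('gene_id "')[1].split('"')[0]
            if gid not in exons:
                exons[gid] = []
                meta[gid] = (f[0], f[6])
                order.append(gid)
            exons[gid].append((int(f[3]), int(f[4])))
    return [GeneModel(g, meta[g][0], meta[g][1], exons[g]) for g in order]


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """One row per sample: donor, age, age group, gender, location, library.

    The default spec yields 54 samples — 18 per age group — from 27
    donors, 13 female and 14 male.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng([int(spec.seed), 21])
    rows = []
    donor_no = 0
    for grp in spec.age_groups:
        genders = ([spec.genders[0]] * grp.n_female
                   + [spec.genders[1]] * (grp.n_donors - grp.n_female))
        rng.shuffle(genders)
        ages = rng.integers(grp.age_min, grp.age_max + 1, size=grp.n_donors)
        for k in range(grp.n_donors):
            donor_no += 1
            donor = f"D{donor_no:02d}"
            for loc in spec.locations:
                lib = int(rng.integers(spec.lib_size[0],
                                       spec.lib_size[1] + 1))
                rows.append((f"{donor}_{loc}", donor, int(ages[k]),
                             grp.name, genders[k], loc, lib))
    df = pd.DataFrame(rows, columns=["sample_id", "donor", "age",
                                     "age_group", "gender", "location",
                                     "lib_size"])
    return df.set_index("sample_id")


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id",
                   lineterminator="\n")


def read_sample_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# ---------------------------------------------------------------------------
# latent expression shared by counts and depth


def _gene_weights(genes: Sequence[GeneModel], seed: int,
                  overrides: Mapping[str, float] | None) -> np.ndarray:
    rng = np.random.default_rng([int(seed), 31])
    w = rng.lognormal(mean=0.0, sigma=0.5, size=len(genes))
    if overrides:
        ids = {g.gene_id: i for i, g in enumerate(genes)}
        for gid, val in overrides.items():
            if gid not in ids:
                raise KeyError(f"unknown gene_id in weight override: {gid}")
            w[ids[gid]] = val
    total = w.sum()
    if total <= 0:
        raise ValueError("all gene weights are zero")
    return w / total


def _donor_effects(genes: Sequence[GeneModel], samples: pd.DataFrame,
                   sigma: float, seed: int) -> np.ndarray:
    """(n_genes, n_samples) multiplicative donor effects, mean 1.

    Drawn per donor x gene and shared between the donor's two samples.
    """
    donors = sorted(samples["donor"].unique())
    rng = np.random.default_rng([int(seed), 32])
    if sigma <= 0:
        return np.ones((len(genes), len(samples)))
    d = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma,
                      size=(len(genes), len(donors)))
    col = pd.Categorical(samples["donor"], categories=donors).codes
    return d[:, col]


def _effect_multipliers(genes: Sequence[GeneModel], samples: pd.DataFrame,
                        effects: Iterable[EffectSpec],
                        group_order: Sequence[str]) -> np.ndarray:
    ids = {g.gene_id: i for i, g in enumerate(genes)}
    mult = np.ones((len(genes), len(samples)))
    gidx = pd.Categorical(samples["age_group"],
                          categories=list(group_order)).codes
    if (gidx < 0).any():
        raise ValueError("sample age_group outside the declared group order")
    for eff in effects:
        if eff.gene_id not in ids:
            raise KeyError(f"effect references unknown gene {eff.gene_id!r}")
        row = ids[eff.gene_id]
        if eff.effect_kind == "monotone_up":
            mult[row] *= eff.ratio ** gidx
        elif eff.effect_kind == "monotone_down":
            mult[row] *= eff.ratio ** (-gidx.astype(float))
        elif eff.effect_kind == "outlier_donors":
            hit = samples["donor"].isin(eff.outlier_donor_ids).to_numpy()
            mult[row, hit] *= eff.outlier_fold
        elif eff.effect_kind == "gender_biased":
            hit = (samples["gender"] == "male").to_numpy()
            mult[row, hit] *= eff.ratio
        elif eff.effect_kind == "location_biased":
            hit = (samples["location"] == "sun_exposed").to_numpy()
            mult[row, hit] *= eff.ratio
        # "null": no modification
    return mult


def _expected_reads(genes: Sequence[GeneModel], samples: pd.DataFrame,
                    effects: Iterable[EffectSpec], seed: int,
                    donor_sigma: float,
                    gene_weights: Mapping[str, float] | None,
                    group_order: Sequence[str]) -> np.ndarray:
    """Expected reads per gene (rows) and sample (columns)."""
    w = _gene_weights(genes, seed, gene_weights)
    d = _donor_effects(genes, samples, donor_sigma, seed)
    e = _effect_multipliers(genes, samples, effects, group_order)
    lib = samples["lib_size"].to_numpy(dtype=float)
    return w[:, None] * lib[None, :] * e * d


# ---------------------------------------------------------------------------
# counts


def simulate_counts(genes: Sequence[GeneModel], samples: pd.DataFrame,
                    effects: Iterable[EffectSpec] = (),
                    nb_dispersion: float = DEFAULT_DISPERSION,
                    seed: int = 0,
                    read_len: int = DEFAULT_READ_LEN,
                    donor_sigma: float = DEFAULT_DONOR_SIGMA,
                    gene_weights: Mapping[str, float] | None = None,
                    group_order: Sequence[str] | None = None) -> CountMatrix:
    """NB-distributed gap-site counts for every annotated junction.

    The expected count at each of a gene's gap-sites is the gene's
    expected read number times the chance that a read of ``read_len``
    crosses a given junction, ``(read_len - 1) / exonic_length``.  Counts
    are NB(mean, dispersion = ``nb_dispersion``) via gamma-Poisson mixing
    (Poisson in the limit dispersion -> 0).
    """
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    if group_order is None:
        group_order = _order_from_samples(samples)
    effects = list(effects)
    reads = _expected_reads(genes, samples, effects, seed, donor_sigma,
                            gene_weights, group_order)
    rng = np.random.default_rng([int(seed), 41])
    rows = []
    feature_ids: List[str] = []
    gene_ids: List[str] = []
    for i, g in enumerate(genes):
        sites = g.annotated_gap_sites()
        if not sites:
            continue
        jfrac = (read_len - 1) / g.exonic_length
        mu = np.tile(reads[i] * jfrac, (len(sites), 1))
        if nb_dispersion > 0:
            lam = rng.gamma(shape=1.0 / nb_dispersion,
                            scale=nb_dispersion * mu)
        else:
            lam = mu
        rows.append(rng.poisson(lam))
        feature_ids.extend(s.feature_id for s in sites)
        gene_ids.extend([g.gene_id] * len(sites))
    counts = pd.DataFrame(np.vstack(rows) if rows else
                          np.zeros((0, len(samples)), dtype=np.int64),
                          index=feature_ids, columns=samples.index)
    return CountMatrix(counts, samples,
                       feature_genes=pd.Series(gene_ids, index=feature_ids))


def _order_from_samples(samples: pd.DataFrame) -> Tuple[str, ...]:
    canonical = [g for g in ("Young", "Middle", "Old")
                 if g in set(samples["age_group"])]
    if canonical:
        extra = sorted(set(samples["age_group"]) - set(canonical))
        return tuple(canonical + extra)
    return tuple(sorted(set(samples["age_group"])))


# ---------------------------------------------------------------------------
# depth profiles


def simulate_depth_profiles(genes: Sequence[GeneModel],
                            samples: pd.DataFrame,
                            effects: Iterable[EffectSpec] = (),
                            read_len: int = DEFAULT_READ_LEN,
                            seed: int = 0,
                            donor_sigma: float = DEFAULT_DONOR_SIGMA,
                            leakage: float = DEFAULT_LEAKAGE,
                            gene_weights: Mapping[str, float] | None = None,
                            group_order: Sequence[str] | None = None,
                            ) -> Dict[str, GeneDepth]:
    """Per-base Poisson depth over each gene's full genomic span.

    Exonic mean depth is ``expected_reads * read_len / exonic_length``
    (the same expected reads that drive the gap-site counts when called
    with the same seed); intronic mean depth is ``leakage`` times that.
    """
    if not 0 <= leakage < 1:
        raise ValueError("leakage must lie in [0, 1)")
    if group_order is None:
        group_order = _order_from_samples(samples)
    effects = list(effects)
    reads = _expected_reads(genes, samples, effects, seed, donor_sigma,
                            gene_weights, group_order)
    rng = np.random.default_rng([int(seed), 42])
    out: Dict[str, GeneDepth] = {}
    for i, g in enumerate(genes):
        pos = np.arange(g.start, g.end + 1, dtype=np.int64)
        exonic = np.zeros(pos.size, dtype=bool)
        for a, b in g.exons:
            exonic[(pos >= a) & (pos <= b)] = True
        base = reads[i] * read_len / g.exonic_length  # per sample
        mu = base[:, None] * np.where(exonic, 1.0, leakage)[None, :]
        depth = rng.poisson(mu)
        out[g.gene_id] = GeneDepth(g.gene_id, pos, depth,
                                   list(samples.index), chrom=g.chrom)
    return out


# ---------------------------------------------------------------------------
# FASTQ emitter (QC fixtures only)


def simulate_fastq_reads(n_reads: int, read_len: int = DEFAULT_READ_LEN,
                         gc: float = 0.5, seed: int = 0) -> List[str]:
    """Random reads with a given GC content, for k-mer QC fixtures."""
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng([int(seed), 51])
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    draws = rng.choice(4, size=(n_reads, read_len), p=p)
    return ["".join(alphabet[row]) for row in draws]


def write_fastq(reads: Sequence[str], path, sample_id: str = "S") -> None:
    """Write reads as FASTQ (gzip when the path ends in .gz)."""
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "wt", newline="\n") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@{sample_id}:{i}\n{r}\n+\n{'I' * len(r)}\n")
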