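"""DNA 6-mer spectrum screening of samples before analysis.

Sequencing samples with serious disturbances (contamination, adapter
artefacts, strong compositional bias) stand out in their k-mer frequency
spectra.  Each sample's reads are reduced to the relative frequencies of
all 4^k forward-strand k-mers; samples whose spectra sit unusually far
from the cohort (robust MAD rule on median pairwise distances) are
flagged for exclusion.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


@dataclass
class KmerSpectrum:
    """Relative k-mer frequencies of one sample's reads."""

    sample_id: str
    k: int
    freq: np.ndarray      # length 4^k, sums to 1
    n_kmers: int = 0      # number of counted (valid) k-mers

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.size != 4 ** self.k:
            raise ValueError(f"spectrum length must be 4^{self.k}")
        if np.any(self.freq < 0):
            raise ValueError("frequencies must be >= 0")
        if abs(self.freq.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


def kmer_counts(reads: Iterable[str], k: int) -> np.ndarray:
    """Raw k-mer counts over all reads, forward strand only.

    K-mers containing any non-ACGT symbol are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros(4 ** k, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    n_reads = 0
    any_window = False
    for read in reads:
        n_reads += 1
        if len(read) < k:
            continue
        any_window = True
        codes = _CODE[np.frombuffer(read.encode("ascii"), dtype=np.uint8)]
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (win >= 0).all(axis=1)
        if valid.any():
            ids = win[valid] @ powers
            counts += np.bincount(ids, minlength=4 ** k)
    if n_reads == 0:
        raise ValueError("no reads given")
    if not any_window:
        raise ValueError(f"k={k} longer than every read")
    return counts


def kmer_spectrum(reads: Iterable[str], k: int = 6,
                  sample_id: str = "sample") -> KmerSpectrum:
    """Normalised k-mer spectrum of one sample (default 6-mers)."""
    counts = kmer_counts(reads, k)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid k-mers (all contain non-ACGT symbols)")
    return KmerSpectrum(sample_id, k, counts / total, n_kmers=int(total))


def spectrum_distance_matrix(spectra: Sequence[KmerSpectrum]) -> pd.DataFrame:
    """Pairwise 1 - Pearson correlation of log-transformed spectra.

    A pseudo-frequency of 1 / (4^k * 10) is added before the log so that
    absent k-mers stay finite.
    """
    if not spectra:
        raise ValueError("no spectra")
    k = spectra[0].k
    if any(s.k != k for s in spectra):
        raise ValueError("all spectra must share k")
    pseudo = 1.0 / (4 ** k * 10)
    logf = np.log(np.stack([s.freq for s in spectra]) + pseudo)
    corr = np.corrcoef(logf)
    dist = 1.0 - corr
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    ids = [s.sample_id for s in spectra]
    return pd.DataFrame(dist, index=ids, columns=ids)


def flag_outlier_samples(distances: pd.DataFrame,
                         threshold_mad: float = 3.5) -> List[str]:
    """Samples whose median distance to all others is unusually large.

    A sample is flagged when its median distance exceeds the cohort
    median of those medians plus ``threshold_mad`` times their MAD.
    """
    n = distances.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    d = distances.to_numpy(dtype=float)
    med_dist = np.array([np.median(np.delete(d[i], i)) for i in range(n)])
    centre = np.median(med_dist)
    mad = np.median(np.abs(med_dist - centre))
    cut = centre + threshold_mad * mad
    with np.errstate(invalid="ignore"):
        flags = med_dist > cut
    return [s for s, f in zip(distances.index, flags) if f]


def read_fastq(path) -> List[str]:
    """Read sequences from a FASTQ file (plain or gzip)."""
    from Bio import SeqIO

    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "rt") as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]


def write_spectra_tsv(spectra: Sequence[KmerSpectrum], path) -> None:
    df = pd.DataFrame({s.sample_id: s.freq for s in spectra})
    df.to_csv(path, sep="\t", index_label="kmer_index",
              float_format="%.6g", lineterminator="\n")
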