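"""Fragment-length histograms and normalized profiles.

Plasma cfDNA fragment sizes carry a nucleosomal footprint: a dominant
mono-nucleosome mode near 166 bp, a di-nucleosome mode near 332 bp, and a
~10 bp oscillation on the sub-nucleosomal side. This module holds the raw
per-sample length histogram, its validated I/O, and the conversion to a
normalized log-proportion profile that the feature extractors consume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam

logger = logging.getLogger(__name__)

#: length window (inclusive, bp) that the feature pipeline requires
FEATURE_SUPPORT = (81, 336)


class HistogramParseError(ValueError):
    """Raised when a histogram file violates the two-column TSV contract."""


@dataclass(frozen=True)
class LengthHistogram:
    """Fragment counts per integer fragment length (bp).

    Parameters
    ----------
    sample_id : str
        Sample identifier carried through the pipeline.
    counts : dict[int, int]
        Mapping length (bp) -> non-negative fragment count.
    support : tuple[int, int]
        Inclusive length range ``[lo, hi]``; inferred from the counts if
        not given explicitly.
    """

    sample_id: str
    counts: dict[int, int]
    support: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("histogram has no bins")
        lengths = np.fromiter(self.counts.keys(), dtype=np.int64)
        values = np.fromiter(self.counts.values(), dtype=np.int64)
        if (values < 0).any():
            bad = lengths[values < 0][0]
            raise ValueError(f"negative count at length {bad}")
        if values.sum() <= 0:
            warnings.warn(
                f"{self.sample_id}: histogram has zero total count",
                stacklevel=2,
            )
        if self.support is None:
            object.__setattr__(
                self, "support", (int(lengths.min()), int(lengths.max()))
            )
        lo, hi = self.support
        if lo > hi:
            raise ValueError(f"invalid support [{lo}, {hi}]")
        if lengths.min() < lo or lengths.max() > hi:
            raise ValueError("histogram contains lengths outside its support")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def count_vector(self) -> np.ndarray:
        """Counts on the dense inclusive support grid (zeros filled in)."""
        lo, hi = self.support
        out = np.zeros(hi - lo + 1, dtype=np.int64)
        for length, count in self.counts.items():
            out[length - lo] = count
        return out


@dataclass(frozen=True)
class FragmentProfile:
    """Normalized fragment-length proportions p_j and their natural logs.

    ``p[j - support[0]]`` is the proportion of fragments of length j after
    adding ``pseudocount`` to every bin of the dense support grid.
    """

    sample_id: str
    support: tuple[int, int]
    p: np.ndarray
    logp: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1")
        if not np.all(self.p > 0):
            raise ValueError("all proportions must be strictly positive")

    @property
    def lengths(self) -> np.ndarray:
        lo, hi = self.support
        return np.arange(lo, hi + 1)

    def window(self, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (lengths, logp) restricted to the inclusive window [lo, hi]."""
        s_lo, s_hi = self.support
        if lo < s_lo or hi > s_hi:
            raise ValueError(
                f"window [{lo}, {hi}] not contained in support [{s_lo}, {s_hi}]"
            )
        sl = slice(lo - s_lo, hi - s_lo + 1)
        return self.lengths[sl], self.logp[sl]


def read_histogram(path: str, sample_id: str) -> LengthHistogram:
    """Read a two-column ``length<TAB>count`` TSV into a LengthHistogram.

    Lines starting with ``#`` are ignored. Lengths must be unique integers
    and counts non-negative integers; violations raise
    :class:`HistogramParseError` naming the offending line.
    """
    counts: dict[int, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise HistogramParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            try:
                length, count = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise HistogramParseError(
                    f"{path}:{lineno}: non-integer field"
                ) from exc
            if length in counts:
                raise HistogramParseError(
                    f"{path}:{lineno}: duplicate length {length}"
                )
            if count < 0:
                raise HistogramParseError(
                    f"{path}:{lineno}: negative count {count}"
                )
            counts[length] = count
    if not counts:
        raise HistogramParseError(f"{path}: empty histogram file")
    return LengthHistogram(sample_id=sample_id, counts=counts)


def write_histogram(hist: LengthHistogram, path: str) -> None:
    """Write a histogram as ``length<TAB>count`` over its dense support."""
    lo, _ = hist.support
    vec = hist.count_vector()
    with open(path, "w") as fh:
        fh.write("#length\tcount\n")
        for offset, count in enumerate(vec):
            fh.write(f"{lo + offset}\t{int(count)}\n")


def histogram_from_alignments(
    path: str,
    sample_id: str,
    min_mapq: int = 30,
    support: tuple[int, int] = (50, 400),
) -> LengthHistogram:
    """Count absolute template lengths from a coordinate-sorted BAM/SAM/CRAM.

    Retains first-in-pair, properly-paired, primary, non-duplicate,
    non-supplementary records with mapping quality >= ``min_mapq``.
    Template lengths outside ``support`` are dropped and their number logged.
    """
    lo, hi = support
    counts: dict[int, int] = {}
    dropped = 0
    with pysam.AlignmentFile(path) as af:
        for read in af.fetch(until_eof=True):
            if (
                not read.is_paired
                or not read.is_proper_pair
                or not read.is_read1
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.is_unmapped
                or read.mapping_quality < min_mapq
            ):
                continue
            tlen = abs(read.template_length)
            if lo <= tlen <= hi:
                counts[tlen] = counts.get(tlen, 0) + 1
            else:
                dropped += 1
    if dropped:
        logger.info("%s: dropped %d pairs outside support [%d, %d]",
                    sample_id, dropped, lo, hi)
    if not counts:
        warnings.warn(
            f"{sample_id}: no read pairs passed the template-length filters",
            stacklevel=2,
        )
        counts = {lo: 0}
    return LengthHistogram(sample_id=sample_id, counts=counts, support=support)


def normalize(hist: LengthHistogram, pseudocount: float = 0.5) -> FragmentProfile:
    """Convert counts to proportions p_j over the full dense support.

    ``p_j = (count_j + pseudocount) / sum_i (count_i + pseudocount)``.
    A positive pseudocount keeps every bin strictly positive so that the
    log-profile used downstream is finite.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    vec = hist.count_vector().astype(float)
    if pseudocount == 0 and (vec == 0).any():
        raise ValueError(
            "log undefined: zero count in support with zero pseudocount"
        )
    vec = vec + pseudocount
    p = vec / vec.sum()
    return FragmentProfile(
        sample_id=hist.sample_id,
        support=hist.support,
        p=p,
        logp=np.log(p),
        pseudocount=float(pseudocount),
    )
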