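"""Shared genomic primitives and statistical utilities.

Every downstream stage works with the same small set of objects:
:class:`GenomicInterval` (BED-convention, 0-based half-open coordinates),
:class:`SignalTrack` (fixed-width binned coverage per chromosome),
:class:`GeneAnnotation` (interval plus strand-consistent TSS/TTS), and a
handful of statistics used throughout the analyses (two-sided binomial
enrichment test, BH/Bonferroni adjustment, per-row z-scoring).

Coordinates are 0-based half-open everywhere internally; any 1-based input
is converted at the reader boundary.  Chromosome names are matched by exact
string comparison; an optional ``normalize_chrom`` flag on the readers adds
or strips a ``chr`` prefix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats

STRANDS = ("+", "-", ".")

#: fixed float formatting for all text writers (6 significant digits)
FLOAT_FMT = "%.6g"


class BedParseError(ValueError):
    """Raised for malformed BED/bedGraph records; message names the line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic region in 0-based half-open (BED) convention."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap length in bp (0 if disjoint or on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with strand-consistent TSS/TTS.

    For a + gene the TSS is ``interval.start`` and the TTS ``interval.end``;
    for a - gene the two are swapped.
    """

    gene_id: str
    interval: GenomicInterval
    tss: int
    tts: int

    def __post_init__(self) -> None:
        iv = self.interval
        if iv.strand == "-":
            expect = (iv.end, iv.start)
        else:
            expect = (iv.start, iv.end)
        if (self.tss, self.tts) != expect:
            raise ValueError(
                f"TSS/TTS ({self.tss},{self.tts}) inconsistent with strand "
                f"{iv.strand} of {iv}"
            )

    @classmethod
    def from_interval(cls, gene_id: str, interval: GenomicInterval) -> "GeneAnnotation":
        if interval.strand == "-":
            return cls(gene_id, interval, interval.end, interval.start)
        return cls(gene_id, interval, interval.start, interval.end)


@dataclass(frozen=True)
class MultipleTestResult:
    """A raw p-value with its multiplicity-adjusted companion."""

    raw_p: float
    adj_p: float
    method: str

    def __post_init__(self) -> None:
        if self.method not in ("BH", "bonferroni"):
            raise ValueError(f"unknown method {self.method!r}")
        if not (0.0 <= self.raw_p <= min(self.adj_p, 1.0) + 1e-15):
            raise ValueError("need 0 <= raw_p <= min(adj_p, 1)")


# ---------------------------------------------------------------------------
# BED / interval algebra
# ---------------------------------------------------------------------------


def _normalize_chrom(chrom: str, mode: str | None) -> str:
    if mode == "add" and not chrom.startswith("chr"):
        return "chr" + chrom
    if mode == "strip" and chrom.startswith("chr"):
        return chrom[3:]
    return chrom


def read_bed(path, normalize_chrom: str | None = None) -> list[GenomicInterval]:
    """Read BED3/BED6 records in file order.

    Track definition lines, browser lines, comments and blank lines are
    skipped.  Malformed records raise :class:`BedParseError` naming the line
    number.  ``normalize_chrom`` may be ``"add"`` or ``"strip"`` to opt in to
    ``chr``-prefix normalization.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = _normalize_chrom(fields[0], normalize_chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(
                    GenomicInterval(chrom, start, end, strand, name=name, score=score)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    """Write BED6 with deterministic column order and fixed float format."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = FLOAT_FMT % iv.score if iv.score is not None else "0"
            name = iv.name if iv.name is not None else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals into a minimal cover."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def intersect(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap_bp: int = 1,
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All (a_i, b_j, overlap_bp) pairs with same-chromosome overlap.

    A sorted sweep per chromosome; output is sorted by (chrom, a.start,
    b.start).  Symmetric in content: swapping the inputs swaps the pair
    members but selects the same overlaps.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom_b.values():
        ivs.sort(key=lambda x: (x.start, x.end))
    pairs: list[tuple[GenomicInterval, GenomicInterval, int]] = []
    for ai in sorted(a, key=lambda x: (x.chrom, x.start, x.end)):
        cands = by_chrom_b.get(ai.chrom, ())
        # linear scan is fine at the region-set sizes this pipeline handles
        for bj in cands:
            if bj.start >= ai.end:
                break
            ov = min(ai.end, bj.end) - max(ai.start, bj.start)
            if ov >= min_overlap_bp:
                pairs.append((ai, bj, ov))
    return pairs


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def binomial_enrichment(observed: int, n: int, p0: float) -> float:
    """Two-sided exact binomial test, minimum-likelihood convention.

    p = sum of Binomial(k; n, p0) over all k whose point probability does not
    exceed that of ``observed``.  This is the convention scipy's ``binomtest``
    implements; the mode therefore always yields p = 1.
    """
    if not (0 <= observed <= n):
        raise ValueError("need 0 <= observed <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly inside (0, 1)")
    return float(stats.binomtest(int(observed), int(n), p0).pvalue)


def adjust_pvalues(
    p: Sequence[float], method: str = "BH", m: int | None = None
) -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment, optionally with a larger
    family size ``m`` than the number of supplied p-values.

    Output order matches input order; values are capped at 1.  BH uses the
    standard step-up with monotonicity enforcement.
    """
    parr = np.asarray(p, dtype=float)
    if parr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if parr.size and (np.nanmin(parr) < 0 or np.nanmax(parr) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    k = parr.size
    if m is None:
        m = k
    if m < k:
        raise ValueError("family size m must be >= len(p)")
    if k == 0:
        return parr.copy()
    if method == "bonferroni":
        return np.minimum(1.0, parr * m)
    if method != "BH":
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(parr, kind="stable")
    ranked = parr[order] * m / np.arange(1, k + 1)
    # enforce monotone non-decreasing adjusted values from the largest rank
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(k)
    out[order] = np.minimum(1.0, adj)
    return out


def zscore_matrix(x: np.ndarray) -> np.ndarray:
    """Per-row z-scores with the sample (n-1) standard deviation.

    Constant rows map to all-zero rows with a warning rather than NaN.
    Requires at least 2 columns.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples per gene")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant row(s) mapped to zeros", RuntimeWarning
        )
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd
    z[flat, :] = 0.0
    return z


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

NORMALIZATION_STATES = ("raw", "background_equalized", "rpgc_1x")


@dataclass
class SignalTrack:
    """Fixed-width binned coverage: one non-negative vector per chromosome.

    ``normalization_state`` is one-way: once a track leaves ``raw`` it cannot
    return.  ``rpgc_1x`` means the genome-wide mean bin value is 1 (reads per
    genomic content, i.e. "1x genome coverage").
    """

    bin_size: int
    data: dict[str, np.ndarray]
    library_size: int | None = None
    normalization_state: str = "raw"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.normalization_state not in NORMALIZATION_STATES:
            raise ValueError(f"unknown state {self.normalization_state!r}")
        clean: dict[str, np.ndarray] = {}
        for chrom, vec in self.data.items():
            arr = np.asarray(vec, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"{chrom}: track vector must be 1-D")
            if arr.size and arr.min() < 0:
                raise ValueError(f"{chrom}: negative track values")
            clean[chrom] = arr
        self.data = clean
        self._cummass: dict[str, np.ndarray] = {}

    # -- basic queries ------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def n_bins(self) -> int:
        return int(sum(v.size for v in self.data.values()))

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def chrom_length(self, chrom: str) -> int:
        return int(self.data[chrom].size * self.bin_size)

    # -- normalization ------------------------------------------------------

    def to_rpgc(self) -> "SignalTrack":
        """Scale so the genome-wide mean bin value is 1 (1x coverage)."""
        mean = self.total() / max(self.n_bins(), 1)
        if mean <= 0:
            raise ValueError("cannot normalize an empty track")
        return SignalTrack(
            self.bin_size,
            {c: v / mean for c, v in self.data.items()},
            library_size=self.library_size,
            normalization_state="rpgc_1x",
        )

    def scaled(self, factor: float, state: str = "background_equalized") -> "SignalTrack":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return SignalTrack(
            self.bin_size,
            {c: v * factor for c, v in self.data.items()},
            library_size=self.library_size,
            normalization_state=state,
        )

    # -- resampling ---------------------------------------------------------

    def window_counts(self, window_bp: int) -> dict[str, np.ndarray]:
        """Re-bin by summation into windows of ``window_bp`` (a multiple of
        ``bin_size``); a trailing partial window is dropped."""
        if window_bp % self.bin_size != 0:
            raise ValueError(
                f"window {window_bp} is not a multiple of bin size {self.bin_size}"
            )
        k = window_bp // self.bin_size
        out = {}
        for chrom, vec in self.data.items():
            nwin = vec.size // k
            out[chrom] = vec[: nwin * k].reshape(nwin, k).sum(axis=1)
        return out

    def mean_coverage(self, chrom: str, start: int, end: int) -> float:
        """Exact mean of the piecewise-constant track over [start, end).

        Positions outside the chromosome contribute zero coverage.
        """
        if end <= start:
            raise ValueError("end must exceed start")
        if chrom not in self._cummass:
            vec = self.data[chrom]
            self._cummass[chrom] = np.concatenate(
                ([0.0], np.cumsum(vec) * self.bin_size)
            )
        cum = self._cummass[chrom]
        length = self.chrom_length(chrom)

        def mass_at(pos: float) -> float:
            pos = min(max(pos, 0), length)
            i = int(pos // self.bin_size)
            frac = pos - i * self.bin_size
            return cum[i] + self.data[chrom][i] * frac if frac else cum[i]

        return (mass_at(end) - mass_at(start)) / (end - start)

    # -- I/O ----------------------------------------------------------------

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.data:
                vec = self.data[chrom]
                for i, v in enumerate(vec):
                    fh.write(
                        f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t"
                        + (FLOAT_FMT % v)
                        + "\n"
                    )

    @classmethod
    def from_bedgraph(
        cls,
        path,
        bin_size: int,
        chrom_sizes: dict[str, int] | None = None,
        normalize_chrom: str | None = None,
    ) -> "SignalTrack":
        """Read a bedGraph whose records align with a fixed ``bin_size`` grid.

        Records must not straddle bin boundaries; a record spanning several
        bins assigns its value to each of them.  Vector lengths come from
        ``chrom_sizes`` when given, else from the largest end seen.
        """
        values: dict[str, dict[int, float]] = {}
        maxend: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("track", "#", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise BedParseError(f"{path}:{lineno}: need 4 columns")
                chrom = _normalize_chrom(f[0], normalize_chrom)
                try:
                    start, end, val = int(f[1]), int(f[2]), float(f[3])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad record") from exc
                if start % bin_size or end % bin_size or end <= start:
                    raise BedParseError(
                        f"{path}:{lineno}: record not aligned to {bin_size}-bp bins"
                    )
                d = values.setdefault(chrom, {})
                for b in range(start // bin_size, end // bin_size):
                    d[b] = val
                maxend[chrom] = max(maxend.get(chrom, 0), end)
        data = {}
        for chrom, d in values.items():
            if chrom_sizes is not None:
                n = -(-chrom_sizes[chrom] // bin_size)
            else:
                n = maxend[chrom] // bin_size
            vec = np.zeros(n)
            for b, v in d.items():
                vec[b] = v
            data[chrom] = vec
        return cls(bin_size, data)


def read_gene_annotation(path, normalize_chrom: str | None = None) -> list[GeneAnnotation]:
    """Read a BED6-like gene table (chrom, start, end, gene_id, score, strand)."""
    genes = []
    seen: set[str] = set()
    for iv in read_bed(path, normalize_chrom=normalize_chrom):
        gid = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        if gid in seen:
            raise ValueError(f"duplicate gene_id {gid!r}")
        seen.add(gid)
        genes.append(GeneAnnotation.from_interval(gid, iv))
    return genes


def write_gene_annotation(path, genes: Iterable[GeneAnnotation]) -> None:
    write_bed(
        path,
        (replace(g.interval, name=g.gene_id) for g in genes),
    )
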