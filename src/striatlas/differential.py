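"""Count-based differential enrichment over a unified region set.

One engine serves every contrast in the pipeline: a negative-binomial Wald
test with method-of-moments dispersion shrunk toward a mean-dependent trend.
With ``dispersion=0`` the engine degenerates to the exact conditional
Poisson test (a binomial test on the group totals conditioned on the region
total), the classical no-overdispersion model of window-count callers.  The
study thresholds are preserved as defaults at the call sites: genotype
contrasts at BH-adjusted p < 1e-5, the NeuN+ vs NeuN- cell-type contrast at
raw p < 1e-15, and the concordance filter at p < 0.05.

Normalization equalizes background regions: per-sample size factors are the
median across background regions of the ratio of that sample's count to the
region's geometric-mean count (median-of-ratios), rescaled to geometric mean
one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GenomicInterval,
    SignalTrack,
    adjust_pvalues,
    binomial_enrichment,
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class RegionCountMatrix:
    """Integer read counts for a region set across samples.

    ``samples`` is a DataFrame indexed by sample name whose columns carry the
    modelled covariates (genotype, age, fraction, replicate, ...).
    """

    regions: list[GenomicInterval]
    counts: np.ndarray
    samples: pd.DataFrame
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"(regions={len(self.regions)}, samples={len(self.samples)})"
            )
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if self.size_factors.shape != (len(self.samples),):
                raise ValueError("one size factor per sample required")
            if (self.size_factors <= 0).any():
                raise ValueError("size factors must be strictly positive")

    def normalized(self) -> np.ndarray:
        if self.size_factors is None:
            raise ValueError("size factors not set")
        return self.counts / self.size_factors

    def subset_samples(self, mask: np.ndarray) -> "RegionCountMatrix":
        return RegionCountMatrix(
            self.regions,
            self.counts[:, mask],
            self.samples.loc[mask],
            None if self.size_factors is None else self.size_factors[mask],
        )


@dataclass
class DifferentialRegion:
    """One region's differential result (condition2 over condition1)."""

    interval: GenomicInterval
    log2fc: float
    raw_p: float
    adj_p: float
    base_mean: float = float("nan")
    mean1: float = float("nan")
    mean2: float = float("nan")

    @property
    def direction(self) -> str:
        return "up" if self.log2fc >= 0 else "down"


def differential_table(regions: Sequence[DifferentialRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in regions],
            "start": [r.interval.start for r in regions],
            "end": [r.interval.end for r in regions],
            "log2fc": [r.log2fc for r in regions],
            "raw_p": [r.raw_p for r in regions],
            "adj_p": [r.adj_p for r in regions],
            "direction": [r.direction for r in regions],
        }
    )


@dataclass
class EnhancerCatalogue:
    """Cell-type-specific enhancer intervals: neuronal vs glial.

    The two label sets are disjoint by construction (each region gets the
    label of the fraction with the higher normalized signal).
    """

    neuronal: list[GenomicInterval] = field(default_factory=list)
    glial: list[GenomicInterval] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dup = set(self.neuronal) & set(self.glial)
        if dup:
            raise ValueError(f"{len(dup)} region(s) carry both labels")

    def __len__(self) -> int:
        return len(self.neuronal) + len(self.glial)

    def to_bed(self, path) -> None:
        from dataclasses import replace

        from .core import write_bed

        ivs = [replace(iv, name="neuronal") for iv in self.neuronal]
        ivs += [replace(iv, name="glial") for iv in self.glial]
        ivs.sort(key=lambda x: (x.chrom, x.start))
        write_bed(path, ivs)

    @classmethod
    def from_bed(cls, path) -> "EnhancerCatalogue":
        from .core import read_bed

        cat = cls()
        for iv in read_bed(path):
            if iv.name == "neuronal":
                cat.neuronal.append(iv)
            elif iv.name == "glial":
                cat.glial.append(iv)
            else:
                raise ValueError(f"unknown catalogue label {iv.name!r}")
        return cat


# ---------------------------------------------------------------------------
# counting and normalization
# ---------------------------------------------------------------------------


def count_matrix_from_tracks(
    regions: Sequence[GenomicInterval],
    tracks: dict[str, SignalTrack],
    samples: pd.DataFrame,
) -> RegionCountMatrix:
    """Region x sample counts by summing raw per-bin track counts over each
    region (track values are reads per bin, so the region total is the mean
    bin value times the number of bins spanned)."""
    names = list(samples.index)
    counts = np.zeros((len(regions), len(names)))
    for j, name in enumerate(names):
        track = tracks[name]
        for i, iv in enumerate(regions):
            mean_per_bin = track.mean_coverage(iv.chrom, iv.start, iv.end)
            counts[i, j] = round(mean_per_bin * iv.length / track.bin_size)
    return RegionCountMatrix(list(regions), counts, samples)


def compute_size_factors(
    rcm: RegionCountMatrix,
    background_regions: Sequence[GenomicInterval] | None = None,
) -> np.ndarray:
    """Median-of-ratios size factors over background regions.

    ``background_regions`` selects rows of the matrix by exact coordinates;
    when None, all regions are used.  Factors are rescaled to geometric mean
    one, so two identical samples get factors (1, 1) and doubling one
    sample's counts doubles its factor.
    """
    if background_regions is None:
        sub = rcm.counts
    else:
        wanted = {(iv.chrom, iv.start, iv.end) for iv in background_regions}
        rows = [
            i
            for i, iv in enumerate(rcm.regions)
            if (iv.chrom, iv.start, iv.end) in wanted
        ]
        if not rows:
            raise ValueError("no matrix rows match the background regions")
        sub = rcm.counts[rows]
    if (sub.sum(axis=0) == 0).any():
        raise ValueError("a sample has all-zero background counts")
    positive = (sub > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no background region has nonzero counts in all samples")
    pos = sub[positive]
    geomean = np.exp(np.log(pos).mean(axis=1, keepdims=True))
    factors = np.median(pos / geomean, axis=0)
    return factors / np.exp(np.mean(np.log(factors)))


def sample_background_regions(
    genome: Sequence[tuple[str, int]],
    exclude: Sequence[GenomicInterval],
    n: int = 200,
    width: int = 2000,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Random fixed-width regions avoiding an exclusion set (e.g. islands)."""
    rng = np.random.default_rng(seed)
    excl: dict[str, list[tuple[int, int]]] = {}
    for iv in exclude:
        excl.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    chroms = list(genome)
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        chrom, length = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, length - width))
        if any(s < start + width and start < e for s, e in excl.get(chrom, ())):
            continue
        out.append(GenomicInterval(chrom, start, start + width))
    if len(out) < n:
        warnings.warn(
            f"only {len(out)}/{n} background regions placed", RuntimeWarning
        )
    return out


# ---------------------------------------------------------------------------
# the test engine
# ---------------------------------------------------------------------------


def _variance_trend_coefs(mu: np.ndarray, s2: np.ndarray) -> tuple[float, float]:
    """Fit the NB-form mean-variance trend s2(mu) = b1*mu + b2*mu**2 by least
    squares over informative regions (coefficients clipped non-negative).

    Working on the variance of normalized counts (rather than a dispersion
    decomposition involving per-sample size factors) keeps every downstream
    statistic a function of normalized counts only, so rescaling a sample's
    counts together with its size factor leaves all p-values unchanged.
    """
    ok = (mu > 0) & np.isfinite(s2)
    if ok.sum() < 10:
        # too few regions for a trend: Poisson-like fallback
        ratio = float(np.median(s2[ok] / mu[ok])) if ok.any() else 1.0
        return max(ratio, 1e-8), 0.0
    m, y = mu[ok], s2[ok]
    # iteratively reweighted fit (weights ~ 1/trend^2) so high-mean regions,
    # whose sample variances have huge spread, do not dominate
    w = 1.0 / np.maximum(m, 1.0) ** 2
    b1, b2 = 1.0, 0.0
    for _ in range(3):
        sw = np.sqrt(w)
        X = np.column_stack((m, m**2)) * sw[:, None]
        coef, *_ = np.linalg.lstsq(X, y * sw, rcond=None)
        b1, b2 = max(float(coef[0]), 1e-8), max(float(coef[1]), 0.0)
        w = 1.0 / np.maximum(b1 * m + b2 * m**2, 1e-8) ** 2
    return b1, b2


def _trend(mu: np.ndarray, b1: float, b2: float) -> np.ndarray:
    return b1 * mu + b2 * mu**2


def differential_test(
    rcm: RegionCountMatrix,
    contrast: tuple[str, str],
    condition_col: str = "genotype",
    dispersion: float | str = "auto",
    pseudocount: float = 0.5,
    prior_df: float = 20.0,
) -> list[DifferentialRegion]:
    """Per-region differential test of condition2 over condition1.

    dispersion:
      * ``"auto"`` - method-of-moments per region, shrunk toward an a0+a1/mu
        trend with ``prior_df`` pseudo-degrees of freedom, then an NB Wald
        test on the log fold-change;
      * a float > 0 - fixed dispersion, NB Wald;
      * ``0`` - exact conditional Poisson test: group-2 total vs the region
        total with success probability given by the size-factor shares.

    The log2 fold-change always uses ``pseudocount`` on the normalized group
    means; BH adjustment is applied across regions.
    """
    cond = rcm.samples[condition_col].to_numpy()
    g1 = cond == contrast[0]
    g2 = cond == contrast[1]
    if not g1.any() or not g2.any():
        missing = [c for c, g in zip(contrast, (g1, g2)) if not g.any()]
        raise ValueError(f"group(s) absent from metadata: {missing}")
    if rcm.size_factors is None:
        rcm.size_factors = compute_size_factors(rcm)
    sf = rcm.size_factors
    norm = rcm.normalized()
    mu1 = norm[:, g1].mean(axis=1)
    mu2 = norm[:, g2].mean(axis=1)
    l2fc = np.log2((mu2 + pseudocount) / (mu1 + pseudocount))
    base_mean = norm.mean(axis=1)

    if dispersion == 0 or dispersion == 0.0:
        k2 = rcm.counts[:, g2].sum(axis=1)
        tot = rcm.counts[:, g1].sum(axis=1) + k2
        p0 = sf[g2].sum() / (sf[g1].sum() + sf[g2].sum())
        raw_p = np.array(
            [
                binomial_enrichment(int(k), int(t), p0) if t > 0 else 1.0
                for k, t in zip(k2, tot)
            ]
        )
    else:
        n1, n2 = int(g1.sum()), int(g2.sum())
        mu_bar = (mu1 * n1 + mu2 * n2) / (n1 + n2)
        if dispersion == "auto":
            if n1 < 2 or n2 < 2:
                raise ValueError(
                    "need >= 2 samples per group for dispersion estimation "
                    "(or supply a fixed dispersion)"
                )
            df = (n1 - 1) + (n2 - 1)
            ss = (norm[:, g1].var(axis=1, ddof=1) * (n1 - 1)
                  + norm[:, g2].var(axis=1, ddof=1) * (n2 - 1))
            s2 = ss / df  # pooled within-group variance, normalized scale
            b1, b2 = _variance_trend_coefs(mu_bar, s2)
            s2_trend = np.maximum(_trend(mu_bar, b1, b2), 1e-12)
            # per-region moderation: shrink the region's empirical variance
            # toward the trend and carry the ratio to group-level variances
            phi = (df * s2 + prior_df * s2_trend) / ((df + prior_df) * s2_trend)

            def group_var(mu: np.ndarray) -> np.ndarray:
                return phi * _trend(mu + pseudocount, b1, b2)

        else:
            alpha = float(dispersion)

            def group_var(mu: np.ndarray) -> np.ndarray:
                mu_pc = mu + pseudocount
                return mu_pc + alpha * mu_pc**2

        v = group_var(mu1) / (n1 * (mu1 + pseudocount) ** 2) + group_var(mu2) / (
            n2 * (mu2 + pseudocount) ** 2
        )
        z = np.log((mu2 + pseudocount) / (mu1 + pseudocount)) / np.sqrt(v)
        raw_p = 2.0 * stats.norm.sf(np.abs(z))

    adj_p = adjust_pvalues(raw_p, "BH")
    return [
        DifferentialRegion(
            iv,
            float(l2fc[i]),
            float(raw_p[i]),
            float(adj_p[i]),
            base_mean=float(base_mean[i]),
            mean1=float(mu1[i]),
            mean2=float(mu2[i]),
        )
        for i, iv in enumerate(rcm.regions)
    ]


def build_enhancer_catalogue(
    neun_pos: RegionCountMatrix,
    neun_neg: RegionCountMatrix,
    p_cutoff: float = 1e-15,
    use_adjusted: bool = False,
    dispersion: float | str = 0,
) -> EnhancerCatalogue:
    """Label regions neuronal or glial from the NeuN+ vs NeuN- contrast.

    Regions with p below ``p_cutoff`` (raw by default) and higher normalized
    signal in NeuN+ are neuronal; higher in NeuN- are glial; the rest are
    excluded.  The default engine mode is the exact conditional test
    (dispersion 0), the regime in which the stringent 1e-15 cutoff is
    meaningful; see docs/methods.md.
    """
    if [
        (iv.chrom, iv.start, iv.end) for iv in neun_pos.regions
    ] != [(iv.chrom, iv.start, iv.end) for iv in neun_neg.regions]:
        raise ValueError("NeuN+ and NeuN- matrices cover different region universes")
    counts = np.hstack([neun_pos.counts, neun_neg.counts])
    meta = pd.concat(
        [
            neun_pos.samples.assign(fraction="NeuN+"),
            neun_neg.samples.assign(fraction="NeuN-"),
        ]
    )
    meta.index = [f"s{i}" for i in range(len(meta))]
    merged = RegionCountMatrix(neun_pos.regions, counts, meta)
    merged.size_factors = compute_size_factors(merged)
    res = differential_test(
        merged, ("NeuN-", "NeuN+"), condition_col="fraction", dispersion=dispersion
    )
    cat = EnhancerCatalogue(
        provenance={
            "contrast": "NeuN+ vs NeuN-",
            "p_cutoff": p_cutoff,
            "use_adjusted": use_adjusted,
        }
    )
    for r in res:
        p = r.adj_p if use_adjusted else r.raw_p
        if p < p_cutoff:
            if r.log2fc > 0:
                cat.neuronal.append(r.interval)
            elif r.log2fc < 0:
                cat.glial.append(r.interval)
    return cat
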