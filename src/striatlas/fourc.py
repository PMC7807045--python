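"""4C-seq processing at restriction-fragment resolution.

A 4C experiment profiles the contacts of one fixed bait locus.  This module
covers the computational chain: building the restriction-fragment map from
genome sequence (first cutter DpnII/GATC delimits fragments, second cutter
Csp6I/GTAC classifies them), checking bait/primer design distance criteria,
cross-sample quantile normalization, running-mean smoothing over fragment
order, interaction-region calling against a monotone distance-decay
background, and differential interaction tests between conditions.

Fragment counts are the unit of analysis; read trimming and alignment happen
upstream and are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .core import GenomicInterval, adjust_pvalues

FIRST_SITE = "GATC"   # DpnII
SECOND_SITE = "GTAC"  # Csp6I


# ---------------------------------------------------------------------------
# fragment map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fragment:
    """A first-cutter restriction fragment.

    The 4-bp first-cutter site is assigned to the downstream fragment, i.e.
    each fragment starts at a site start (except the first fragment of a
    chromosome).  ``blind`` fragments contain no second-cutter site.
    """

    interval: GenomicInterval
    second_sites: tuple[int, ...]  # absolute start positions of GTAC within

    @property
    def blind(self) -> bool:
        return not self.second_sites

    @property
    def first_to_second_bp(self) -> int | None:
        """Distance from the fragment's first-cutter boundary to its first
        internal second-cutter site."""
        if self.blind:
            return None
        return self.second_sites[0] - self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class FragmentMap:
    """Ordered fragments per chromosome; fragments tile each chromosome."""

    fragments: dict[str, list[Fragment]]

    def __post_init__(self) -> None:
        for chrom, frags in self.fragments.items():
            pos = 0
            for f in frags:
                if f.interval.start != pos:
                    raise ValueError(f"{chrom}: fragments do not tile (gap at {pos})")
                pos = f.interval.end

    def n_fragments(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.fragments[chrom])
        return sum(len(v) for v in self.fragments.values())


def _find_sites(seq: str, site: str) -> list[int]:
    out, i = [], seq.find(site)
    while i != -1:
        out.append(i)
        i = seq.find(site, i + 1)
    return out


def build_fragment_map(
    genome: dict[str, str],
    first_site: str = FIRST_SITE,
    second_site: str = SECOND_SITE,
) -> FragmentMap:
    """Scan sequences for first-cutter sites and build the fragment map.

    A chromosome without any first-cutter site yields a single blind-or-not
    fragment spanning it.  Sequences are uppercased before matching.
    """
    if len(first_site) != 4 or len(second_site) != 4:
        raise ValueError("restriction sites must be 4-bp literals")
    frag_map: dict[str, list[Fragment]] = {}
    for chrom, seq in genome.items():
        seq = seq.upper()
        cuts = _find_sites(seq, first_site)
        second = _find_sites(seq, second_site)
        # a cut at position 0 would duplicate the leading boundary
        bounds = sorted({0, *cuts}) + [len(seq)]
        frags = []
        for start, end in zip(bounds[:-1], bounds[1:]):
            inside = tuple(p for p in second if start <= p and p + 4 <= end)
            frags.append(Fragment(GenomicInterval(chrom, start, end), inside))
        frag_map[chrom] = frags
    return FragmentMap(frag_map)


def check_bait_design(
    frag_map: FragmentMap,
    chrom: str,
    fragment_index: int,
    min_first_to_second: int = 350,
    min_fragment: int = 500,
    max_fragment: int = 1500,
) -> tuple[bool, list[str]]:
    """Apply the bait/primer design distance criteria to one fragment.

    Criteria (strict inequalities): the distance from the first-cutter site
    to the next second-cutter site must exceed ``min_first_to_second`` bp,
    and the fragment length (first cutter to the following first cutter,
    beyond the second cutter) must lie strictly between ``min_fragment`` and
    ``max_fragment`` bp.  A blind fragment fails outright.
    """
    frag = frag_map.fragments[chrom][fragment_index]
    reasons: list[str] = []
    if frag.blind:
        return False, ["blind fragment: no second-cutter site"]
    d1 = frag.first_to_second_bp
    if not (d1 > min_first_to_second):
        reasons.append(
            f"first-to-second cutter distance {d1} <= {min_first_to_second}"
        )
    if not (min_fragment < frag.length < max_fragment):
        reasons.append(
            f"fragment length {frag.length} outside ({min_fragment}, {max_fragment})"
        )
    return not reasons, reasons


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


@dataclass
class FourCProfile:
    """Per-fragment counts around one bait.

    ``excluded`` fragments (bait-proximal, self-ligation artefacts) carry no
    normalized score.  ``normalized`` preserves the within-sample rank order
    of the raw counts over scored fragments.
    """

    bait_fragment: int
    counts: np.ndarray
    normalized: np.ndarray | None = None
    excluded: frozenset[int] = frozenset()
    fragment_intervals: list[GenomicInterval] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a vector over fragments")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if not (0 <= self.bait_fragment < self.counts.size):
            raise ValueError("bait fragment index out of range")
        if not self.excluded:
            self.excluded = frozenset(
                i
                for i in range(self.bait_fragment - 2, self.bait_fragment + 3)
                if 0 <= i < self.counts.size
            )

    @property
    def n_fragments(self) -> int:
        return int(self.counts.size)

    def scored_indices(self) -> np.ndarray:
        return np.array(
            [i for i in range(self.n_fragments) if i not in self.excluded], dtype=int
        )

    def scores(self) -> np.ndarray:
        if self.normalized is None:
            raise ValueError("profile not normalized yet")
        return self.normalized

    def scored_from_counts(self) -> "FourCProfile":
        """A copy whose normalized scores are the raw counts (NaN at
        excluded fragments).  Quantile normalization needs >= 2 samples of
        the same bait; a lone profile is scored on its raw scale."""
        full = np.full(self.n_fragments, np.nan)
        idx = self.scored_indices()
        full[idx] = self.counts[idx]
        return FourCProfile(
            bait_fragment=self.bait_fragment,
            counts=self.counts,
            normalized=full,
            excluded=self.excluded,
            fragment_intervals=self.fragment_intervals,
            metadata=dict(self.metadata),
        )


def quantile_normalize(profiles: Sequence[FourCProfile]) -> list[FourCProfile]:
    """Standard quantile normalization across samples over scored fragments.

    Each sample's scored values are replaced by the cross-sample mean of the
    order statistics at their rank (ties get the average); afterwards every
    sample has an identical sorted score vector.  Excluded fragments get NaN.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles to quantile-normalize")
    idx0 = tuple(profiles[0].scored_indices())
    for p in profiles[1:]:
        if tuple(p.scored_indices()) != idx0 or p.n_fragments != profiles[0].n_fragments:
            raise ValueError("profiles cover different fragment universes")
    idx = np.asarray(idx0)
    mat = np.vstack([p.counts[idx] for p in profiles])
    n = idx.size
    ref = np.sort(mat, axis=1).mean(axis=0)
    out = []
    for p, row in zip(profiles, mat):
        ranks = stats.rankdata(row, method="average")
        normed = np.interp(ranks, np.arange(1, n + 1), ref)
        full = np.full(p.n_fragments, np.nan)
        full[idx] = normed
        out.append(
            FourCProfile(
                bait_fragment=p.bait_fragment,
                counts=p.counts,
                normalized=full,
                excluded=p.excluded,
                fragment_intervals=p.fragment_intervals,
                metadata=dict(p.metadata),
            )
        )
    return out


def smooth_profile(profile: FourCProfile, window_fragments: int = 21) -> np.ndarray:
    """Centred running mean over fragment order (default 21 fragments).

    Edges use shrunken symmetric windows; excluded (bait-proximal) fragments
    are skipped entirely, i.e. the mean runs over the scored subsequence.
    Returns a full-length vector with NaN at excluded fragments.
    """
    if window_fragments % 2 == 0:
        raise ValueError("window must be odd")
    idx = profile.scored_indices()
    if window_fragments > idx.size:
        raise ValueError("window exceeds the number of scored fragments")
    x = profile.scores()[idx]
    half = window_fragments // 2
    n = x.size
    out = np.empty(n)
    cum = np.concatenate(([0.0], np.cumsum(x)))
    for i in range(n):
        h = min(half, i, n - 1 - i)  # shrunken symmetric edge window
        out[i] = (cum[i + h + 1] - cum[i - h]) / (2 * h + 1)
    full = np.full(profile.n_fragments, np.nan)
    full[idx] = out
    return full


# ---------------------------------------------------------------------------
# interaction calling
# ---------------------------------------------------------------------------


@dataclass
class InteractionRegion:
    """A contiguous run of fragments interacting above background."""

    first_fragment: int
    last_fragment: int  # inclusive
    interval: GenomicInterval | None = None
    sample_means: dict[str, float] = field(default_factory=dict)
    t_stat: float = float("nan")
    raw_p: float = float("nan")
    adj_p: float = float("nan")

    @property
    def member_fragments(self) -> range:
        return range(self.first_fragment, self.last_fragment + 1)

    def overlaps(self, other: "InteractionRegion") -> bool:
        return (
            self.first_fragment <= other.last_fragment
            and other.first_fragment <= self.last_fragment
        )


def _fit_monotone_background(
    idx: np.ndarray, values: np.ndarray, bait: int
) -> np.ndarray:
    """Expected signal per scored fragment: non-increasing in distance from
    the bait, fitted separately upstream and downstream by isotonic
    regression."""
    bg = np.empty_like(values)
    up = idx < bait
    for mask in (up, ~up):
        if mask.sum() == 0:
            continue
        dist = np.abs(idx[mask] - bait).astype(float)
        iso = IsotonicRegression(increasing=False)
        bg[mask] = iso.fit_transform(dist, values[mask])
    return bg


def call_interactions(
    profiles: dict[str, FourCProfile],
    window_fragments: int = 21,
    seed_z: float = 3.5,
    extension_z: float = 1.5,
    merge_gap: int = 2,
    min_fragments: int = 5,
) -> tuple[dict[str, list[InteractionRegion]], list[InteractionRegion]]:
    """Call interacting regions per sample and keep those reproducible in
    every sample.

    Per sample: smooth, fit the monotone distance-decay background, and take
    log-ratio residuals (multiplicative 4C noise makes relative exceedance
    approximately homoscedastic along the chromosome, unlike absolute
    residuals which are dominated by bait-proximal variance).  The residual
    noise scale is estimated robustly (MAD, which planted contacts barely
    perturb); candidate regions grow by hysteresis: a region must contain at
    least one *seed* fragment above ``seed_z`` noise SDs and extends over
    contiguous fragments above ``extension_z`` SDs; runs within
    ``merge_gap`` merge and only runs of at least ``min_fragments`` survive.
    A profile exactly equal to a monotone decay has zero residuals
    everywhere, a zero noise scale, and yields no candidates.  Reproducible
    regions are the intersections of per-sample regions that overlap across
    all samples.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    per_sample: dict[str, list[InteractionRegion]] = {}
    for name, prof in profiles.items():
        idx = prof.scored_indices()
        smoothed = smooth_profile(prof, window_fragments)[idx]
        bg = _fit_monotone_background(idx, smoothed, prof.bait_fragment)
        delta = 1e-3 * float(np.mean(smoothed)) + 1e-12
        resid = np.log((smoothed + delta) / (bg + delta))
        # noise scale of the *smoothed* log profile, estimated from the raw
        # fragment scatter around the running mean (the isotonic fit itself
        # absorbs medium-scale noise, so its own residuals underestimate it)
        raw = prof.scores()[idx]
        raw_resid = np.log((raw + delta) / (smoothed + delta))
        mad = float(np.median(np.abs(raw_resid - np.median(raw_resid))))
        sigma = 1.4826 * mad / np.sqrt(window_fragments)
        thr_seed = seed_z * sigma
        thr_ext = extension_z * sigma
        seeds = (resid > thr_seed) & (resid > 0)
        ext = (resid > thr_ext) & (resid > 0)
        cand = idx[ext]
        is_seed = seeds[ext]
        regions: list[InteractionRegion] = []
        if cand.size:
            breaks = np.flatnonzero(np.diff(cand) > merge_gap + 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [cand.size - 1]))
            for s, e in zip(starts, ends):
                first, last = int(cand[s]), int(cand[e])
                if last - first + 1 >= min_fragments and is_seed[s : e + 1].any():
                    regions.append(InteractionRegion(first, last))
        per_sample[name] = regions

    names = list(per_sample)
    reproducible: list[InteractionRegion] = []
    for reg in per_sample[names[0]]:
        lo, hi = reg.first_fragment, reg.last_fragment
        ok = True
        for other_name in names[1:]:
            hits = [o for o in per_sample[other_name] if o.overlaps(reg)]
            if not hits:
                ok = False
                break
            lo = max(lo, min(o.first_fragment for o in hits))
            hi = min(hi, max(o.last_fragment for o in hits))
        if ok and lo <= hi:
            reproducible.append(InteractionRegion(lo, hi))
    return per_sample, reproducible


def differential_interaction(
    regions: Sequence[InteractionRegion],
    profiles_by_condition: dict[str, dict[str, FourCProfile]],
    paired: bool = False,
) -> list[InteractionRegion]:
    """Two-tailed t-tests on per-sample mean normalized scores per region.

    With ``paired=True`` samples are matched by their dict order across the
    two conditions (e.g. male/female replicates); a zero-variance paired
    difference falls back to the unpaired Welch test with a warning.  BH
    adjustment runs across regions.
    """
    conds = list(profiles_by_condition)
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    for c in conds:
        if len(profiles_by_condition[c]) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 samples")
    out: list[InteractionRegion] = []
    raw = []
    for reg in regions:
        frag = np.array(
            [i for i in reg.member_fragments], dtype=int
        )
        means = {}
        per_cond: list[np.ndarray] = []
        for c in conds:
            vals = []
            for name, prof in profiles_by_condition[c].items():
                scored = prof.scores()
                sel = frag[[f not in prof.excluded for f in frag]]
                with np.errstate(invalid="ignore"):
                    m = float(np.nanmean(scored[sel])) if sel.size else float("nan")
                means[f"{c}:{name}"] = m
                vals.append(m)
            per_cond.append(np.array(vals))
        a, b = per_cond
        if paired and a.size == b.size:
            diffs = a - b
            if np.allclose(diffs.std(ddof=1), 0.0):
                warnings.warn(
                    "zero-variance paired differences; falling back to the "
                    "unpaired Welch test",
                    RuntimeWarning,
                )
                t, p = stats.ttest_ind(a, b, equal_var=False)
            else:
                t, p = stats.ttest_rel(a, b)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        if np.isnan(p):  # zero variance in both groups, identical means
            t, p = 0.0, 1.0
        new = InteractionRegion(
            reg.first_fragment,
            reg.last_fragment,
            interval=reg.interval,
            sample_means=means,
            t_stat=float(t),
            raw_p=float(p),
        )
        raw.append(new.raw_p)
        out.append(new)
    adj = adjust_pvalues(raw, "BH")
    for r, ap in zip(out, adj):
        r.adj_p = float(ap)
    return out


def read_genome_fasta(path) -> dict[str, str]:
    """Load chromosome sequences from FASTA (Biopython-backed)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
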