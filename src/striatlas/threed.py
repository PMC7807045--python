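"""3D bead models from multi-bait 4C profiles, virtual Hi-C and insulation.

A modelled locus is discretized into beads, each representing a fixed number
of restriction fragments (default 25).  Per-bait 4C signal is converted to
bait-bead distance restraints through a monotone inverse-power transform,
and bead coordinates are obtained by multi-restart gradient minimization of
a restrained distance-geometry objective (restraint violations plus chain
connectivity walls and a soft excluded-volume term).  The all-pairs distance
matrix of a fitted model is the *virtual Hi-C*; a multi-scale insulation
score over its contact proxy locates TAD boundaries as local minima.

Distances are arbitrary model units: 4C signal fixes no physical scale, so
only relative geometry is meaningful, and model comparisons use
reflection-invariant quantities (distance matrices, Spearman correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, signal, stats
from scipy.spatial import distance_matrix as _pairwise_distances

from .fourc import FourCProfile


# ---------------------------------------------------------------------------
# chain and restraints
# ---------------------------------------------------------------------------


@dataclass
class BeadChain:
    """The bead discretization of a modelled locus."""

    n_beads: int
    fragments_per_bead: int = 25
    bp_per_bead: float | None = None  # genomic span represented by one bead
    bait_beads: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_beads < 10:
            raise ValueError("need >= 10 beads")
        if self.fragments_per_bead < 1:
            raise ValueError("fragments_per_bead must be >= 1")
        for b in self.bait_beads:
            if not (0 <= b < self.n_beads):
                raise ValueError(f"bait bead {b} out of range")

    @classmethod
    def for_fragments(
        cls,
        n_fragments: int,
        fragments_per_bead: int = 25,
        bait_fragments: Sequence[int] = (),
        bp_per_bead: float | None = None,
    ) -> "BeadChain":
        n_beads = n_fragments // fragments_per_bead
        baits = sorted({min(f // fragments_per_bead, n_beads - 1) for f in bait_fragments})
        return cls(n_beads, fragments_per_bead, bp_per_bead, baits)

    def bead_of_fragment(self, frag: int) -> int:
        return min(frag // self.fragments_per_bead, self.n_beads - 1)


@dataclass(frozen=True)
class Restraint:
    bait_bead: int
    target_bead: int
    distance: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("target distance must be > 0")


def signal_to_restraints(
    profiles: Sequence[FourCProfile],
    chain: BeadChain,
    alpha: float = 1.0,
    d_range: tuple[float, float] = (1.0, 10.0),
) -> list[Restraint]:
    """Convert normalized per-fragment 4C signal into distance restraints.

    Bead signal is the mean of its scored member fragments; the target
    distance is the inverse-power transform ``d ~ s**(-1/alpha)`` rescaled
    affinely per bait so the observed signal range maps onto ``d_range``.
    Beads with no scored fragments are skipped.
    """
    d_min, d_max = d_range
    if not (0 < d_min < d_max):
        raise ValueError("need 0 < d_min < d_max")
    restraints: list[Restraint] = []
    for prof in profiles:
        scores = prof.scores()
        bait_bead = chain.bead_of_fragment(prof.bait_fragment)
        bead_signal: dict[int, float] = {}
        for bead in range(chain.n_beads):
            f0 = bead * chain.fragments_per_bead
            f1 = min(f0 + chain.fragments_per_bead, prof.n_fragments)
            member = [
                f for f in range(f0, f1) if f not in prof.excluded
                and np.isfinite(scores[f])
            ]
            if not member:
                continue
            s = float(np.mean(scores[member]))
            if s > 0 and bead != bait_bead:
                bead_signal[bead] = s
        if len(bead_signal) < 2:
            continue
        s_arr = np.array(list(bead_signal.values()))
        raw = s_arr ** (-1.0 / alpha)
        lo, hi = raw.min(), raw.max()
        if hi > lo:
            scaled = d_min + (raw - lo) * (d_max - d_min) / (hi - lo)
        else:
            scaled = np.full_like(raw, 0.5 * (d_min + d_max))
        for bead, d in zip(bead_signal, scaled):
            restraints.append(Restraint(bait_bead, bead, float(d)))
    return restraints


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


@dataclass
class BeadModel:
    coords: np.ndarray  # (n_beads, 3)
    objective: float
    seed: int
    restart: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")


def _objective_and_grad(
    x: np.ndarray,
    n: int,
    pair_i: np.ndarray,
    pair_j: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
    conn_min: float,
    conn_max: float | None,
    k_conn: float,
    ev_radius: float,
    k_ev: float,
) -> tuple[float, np.ndarray]:
    X = x.reshape(n, 3)
    grad = np.zeros_like(X)
    eps = 1e-9

    # restraints
    diff = X[pair_i] - X[pair_j]
    d = np.sqrt((diff**2).sum(axis=1)) + eps
    res = d - targets
    obj = float(np.sum(weights * res**2))
    g = (2.0 * weights * res / d)[:, None] * diff
    np.add.at(grad, pair_i, g)
    np.add.at(grad, pair_j, -g)

    # chain connectivity walls on consecutive beads
    diff_c = X[1:] - X[:-1]
    dc = np.sqrt((diff_c**2).sum(axis=1)) + eps
    low = np.maximum(conn_min - dc, 0.0)
    obj += float(k_conn * np.sum(low**2))
    gl = (-2.0 * k_conn * low / dc)[:, None] * diff_c
    np.add.at(grad, np.arange(1, n), gl)
    np.add.at(grad, np.arange(0, n - 1), -gl)
    if conn_max is not None:
        high = np.maximum(dc - conn_max, 0.0)
        obj += float(k_conn * np.sum(high**2))
        gh = (2.0 * k_conn * high / dc)[:, None] * diff_c
        np.add.at(grad, np.arange(1, n), gh)
        np.add.at(grad, np.arange(0, n - 1), -gh)

    # soft excluded volume on all pairs (lower wall)
    if k_ev > 0:
        D = _pairwise_distances(X, X) + eps
        iu, ju = np.triu_indices(n, k=1)
        duv = D[iu, ju]
        viol = np.maximum(ev_radius - duv, 0.0)
        sel = viol > 0
        if sel.any():
            obj += float(k_ev * np.sum(viol[sel] ** 2))
            dvec = X[iu[sel]] - X[ju[sel]]
            gv = (-2.0 * k_ev * viol[sel] / duv[sel])[:, None] * dvec
            np.add.at(grad, iu[sel], gv)
            np.add.at(grad, ju[sel], -gv)
    return obj, grad.ravel()


def fit_bead_model(
    restraints: Sequence[Restraint],
    chain: BeadChain,
    seed: int = 0,
    n_restarts: int = 20,
    conn_min: float = 0.2,
    conn_max: float | None = None,
    k_conn: float = 10.0,
    ev_radius: float = 0.2,
    k_ev: float = 1.0,
    maxiter: int = 500,
) -> BeadModel:
    """Restrained distance-geometry optimization by multi-restart L-BFGS.

    Minimizes the weighted squared restraint violations plus harmonic walls
    on consecutive-bead distances and a soft excluded-volume lower wall on
    all pairs.  Restarts are seeded random-walk initializations; the lowest
    objective wins.  Deterministic under a fixed seed.
    """
    if not restraints:
        raise ValueError("no restraints supplied")
    baits = {r.bait_bead for r in restraints}
    if len(baits) < 4:
        raise ValueError("need restraints from >= 4 bait viewpoints")
    n = chain.n_beads
    pair_i = np.array([r.bait_bead for r in restraints])
    pair_j = np.array([r.target_bead for r in restraints])
    targets = np.array([r.distance for r in restraints])
    weights = np.array([r.weight for r in restraints])
    step = float(np.median(targets)) / max(np.sqrt(n), 1.0) * 2.0

    best: BeadModel | None = None
    ss = np.random.SeedSequence(seed)
    for restart, child in enumerate(ss.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        init = np.cumsum(rng.normal(scale=step, size=(n, 3)), axis=0)
        res = optimize.minimize(
            _objective_and_grad,
            init.ravel(),
            args=(
                n, pair_i, pair_j, targets, weights,
                conn_min, conn_max, k_conn, ev_radius, k_ev,
            ),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.objective:
            best = BeadModel(res.x.reshape(n, 3), float(res.fun), seed, restart)
    if best is None:
        raise RuntimeError("optimization failed to reach a finite objective")
    return best


# ---------------------------------------------------------------------------
# virtual Hi-C and insulation
# ---------------------------------------------------------------------------


def virtual_hic(model: BeadModel) -> np.ndarray:
    """All-pairs Euclidean bead distances (symmetric, zero diagonal)."""
    return _pairwise_distances(model.coords, model.coords)


@dataclass
class InsulationProfile:
    """Multi-scale insulation of a virtual Hi-C matrix.

    ``per_b`` is a (n_scales, n_beads) matrix (NaN where the window does not
    fit); ``aggregate`` averages the per-scale z-scores; ``boundaries`` are
    the local minima of the aggregate.
    """

    b_values: np.ndarray
    per_b: np.ndarray
    aggregate: np.ndarray
    boundaries: list[int]


def insulation_score(
    vhic: np.ndarray,
    b_min: int = 4,
    b_max: int = 30,
    prominence_fraction: float = 0.1,
) -> InsulationProfile:
    """Insulation from a distance matrix via the contact proxy 1/(d+eps).

    For scale ``b`` and position ``k`` the insulation is the mean contact
    over the b x b square crossing ``k`` (pairs i < k <= j with
    k-b <= i and j < k+b); it is defined only where the full window fits.
    Per-scale profiles are z-scored and averaged into the aggregate, whose
    local minima (with prominence at least ``prominence_fraction`` of the
    aggregate's range) are reported as TAD boundaries.  Low insulation
    means a boundary: few contacts cross it.
    """
    D = np.asarray(vhic, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("square matrix required")
    if not (1 <= b_min <= b_max):
        raise ValueError("need 1 <= b_min <= b_max")
    if b_max >= n / 2:
        raise ValueError(f"b_max {b_max} too large for {n} beads")
    off = D[~np.eye(n, dtype=bool)]
    eps = 1e-6 * float(np.median(off)) if off.size else 1e-6
    C = 1.0 / (D + eps)
    # summed-area table for O(1) rectangle sums
    S = np.zeros((n + 1, n + 1))
    S[1:, 1:] = np.cumsum(np.cumsum(C, axis=0), axis=1)

    def rect_sum(r0, r1, c0, c1):  # rows [r0,r1), cols [c0,c1)
        return S[r1, c1] - S[r0, c1] - S[r1, c0] + S[r0, c0]

    b_values = np.arange(b_min, b_max + 1)
    per_b = np.full((b_values.size, n), np.nan)
    for bi, b in enumerate(b_values):
        for k in range(b, n - b + 1):
            per_b[bi, k] = rect_sum(k - b, k, k, k + b) / (b * b)
    # z-score each scale over its defined positions
    zs = np.full_like(per_b, np.nan)
    for bi in range(b_values.size):
        row = per_b[bi]
        ok = np.isfinite(row)
        mean = row[ok].mean()
        sd = row[ok].std(ddof=1)
        # an (effectively) constant profile is flat, not noise to amplify
        if sd > 1e-9 * max(1.0, abs(mean)):
            zs[bi, ok] = (row[ok] - mean) / sd
        else:
            zs[bi, ok] = 0.0
    defined = np.isfinite(zs)
    counts = defined.sum(axis=0)
    sums = np.where(defined, zs, 0.0).sum(axis=0)
    aggregate = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    ok = np.isfinite(aggregate)
    boundaries: list[int] = []
    if ok.any():
        valid = np.flatnonzero(ok)
        agg = aggregate[valid]
        rng_val = float(agg.max() - agg.min())
        if rng_val > 0:
            peaks, _ = signal.find_peaks(
                -agg, prominence=prominence_fraction * rng_val
            )
            boundaries = [int(valid[p]) for p in peaks]
    return InsulationProfile(b_values, per_b, aggregate, boundaries)


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------


@dataclass
class BoundaryMatch:
    bead_a: int | None
    bead_b: int | None
    displacement_beads: int | None = None
    displacement_bp: float | None = None
    insulation_delta: float | None = None


def compare_boundaries(
    profile_a: InsulationProfile,
    profile_b: InsulationProfile,
    bp_per_bead: float | None = None,
    max_match_beads: int = 5,
) -> list[BoundaryMatch]:
    """Greedy proximity matching of boundary sets from two conditions.

    Matched pairs report the signed displacement (b relative to a) in beads
    and, when the chain's genomic span per bead is known, in bp, plus the
    difference in aggregate insulation at the two positions.  Unmatched
    boundaries are reported with the missing side as None.
    """
    if profile_a.aggregate.size != profile_b.aggregate.size:
        raise ValueError("profiles cover different chains")
    a_set = list(profile_a.boundaries)
    b_set = list(profile_b.boundaries)
    pairs = sorted(
        ((abs(a - b), a, b) for a in a_set for b in b_set),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[BoundaryMatch] = []
    for dist, a, b in pairs:
        if dist > max_match_beads or a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        disp = b - a
        matches.append(
            BoundaryMatch(
                a,
                b,
                displacement_beads=disp,
                displacement_bp=disp * bp_per_bead if bp_per_bead else None,
                insulation_delta=float(
                    profile_b.aggregate[b] - profile_a.aggregate[a]
                ),
            )
        )
    for a in a_set:
        if a not in used_a:
            matches.append(BoundaryMatch(a, None))
    for b in b_set:
        if b not in used_b:
            matches.append(BoundaryMatch(None, b))
    return matches


def model_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman correlation of the strictly-upper-triangle distances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("two equal-size square matrices required")
    iu = np.triu_indices(a.shape[0], k=1)
    rho, _ = stats.spearmanr(a[iu], b[iu])
    return float(rho)
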