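"""4C-seq stage: fragment maps, bait criteria, normalization, calling."""

import numpy as np
import pytest
from scipy import stats

from striatlas.fourc import (
    FourCProfile,
    build_fragment_map,
    call_interactions,
    check_bait_design,
    differential_interaction,
    InteractionRegion,
    quantile_normalize,
    smooth_profile,
)


def _oracle_fragments(seq, first="GATC"):
    """Independent sliding-window scan for fragment boundaries."""
    cuts = [i for i in range(len(seq) - 3) if seq[i : i + 4] == first]
    bounds = sorted({0, *cuts}) + [len(seq)]
    return list(zip(bounds[:-1], bounds[1:]))


def _revcomp(seq):
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return "".join(comp[c] for c in reversed(seq))


class TestFragmentMap:
    def test_hand_sequence(self):
        seq = "AAAGATCAAAGTACAAAGATCAAA"
        fm = build_fragment_map({"c": seq})
        frags = fm.fragments["c"]
        assert [(f.interval.start, f.interval.end) for f in frags] == [
            (0, 3),
            (3, 17),
            (17, 24),
        ]
        assert frags[0].blind and frags[2].blind
        assert frags[1].second_sites == (10,)

    def test_no_first_site_single_blind_fragment(self):
        fm = build_fragment_map({"c": "AAAACCCCTTTT"})
        frags = fm.fragments["c"]
        assert len(frags) == 1 and frags[0].blind
        assert frags[0].interval.length == 12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_string_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        fm = build_fragment_map({"c": seq})
        got = [(f.interval.start, f.interval.end) for f in fm.fragments["c"]]
        assert got == _oracle_fragments(seq)
        # second sites verified fragmentwise
        for f in fm.fragments["c"]:
            inside = [
                p
                for p in range(f.interval.start, f.interval.end - 3)
                if seq[p : p + 4] == "GTAC"
            ]
            assert list(f.second_sites) == inside

    def test_reverse_complement_mirrors_map(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        fwd = build_fragment_map({"c": seq}).fragments["c"]
        rev = build_fragment_map({"c": _revcomp(seq)}).fragments["c"]
        n = len(seq)
        # GATC is palindromic: cut sites mirror to n - (pos + 4)
        fwd_cuts = {f.interval.start for f in fwd} - {0}
        rev_cuts = {f.interval.start for f in rev} - {0}
        assert rev_cuts == {n - (p + 4) for p in fwd_cuts}

    def test_fragments_tile_chromosome(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=3_000))
        frags = build_fragment_map({"c": seq}).fragments["c"]
        pos = 0
        for f in frags:
            assert f.interval.start == pos
            pos = f.interval.end
        assert pos == len(seq)


class TestBaitDesign:
    def _map_with(self, first_to_second, frag_len):
        # fragment [0, frag_len) with GTAC at first_to_second
        seq = ["A"] * (frag_len + 50)
        seq[first_to_second : first_to_second + 4] = list("GTAC")
        seq[frag_len : frag_len + 4] = list("GATC")
        return build_fragment_map({"c": "".join(seq)})

    def test_passing_design(self):
        fm = self._map_with(351, 600)
        ok, reasons = check_bait_design(fm, "c", 0)
        assert ok and reasons == []

    def test_first_to_second_boundary_strict(self):
        fm = self._map_with(350, 600)
        ok, reasons = check_bait_design(fm, "c", 0)
        assert not ok and "350" in reasons[0]

    def test_fragment_length_upper_boundary_strict(self):
        fm = self._map_with(351, 1500)
        ok, _ = check_bait_design(fm, "c", 0)
        assert not ok

    def test_fragment_length_lower_boundary_strict(self):
        fm = self._map_with(351, 500)
        ok, _ = check_bait_design(fm, "c", 0)
        assert not ok

    def test_blind_fragment_fails(self):
        fm = build_fragment_map({"c": "A" * 700 + "GATC" + "A" * 100})
        ok, reasons = check_bait_design(fm, "c", 0)
        assert not ok and "blind" in reasons[0]


class TestQuantileNormalize:
    def _profiles(self, rows, bait=10):
        return [
            FourCProfile(bait_fragment=bait, counts=np.asarray(r, dtype=float))
            for r in rows
        ]

    def test_identical_profiles_unchanged(self):
        rng = np.random.default_rng(0)
        row = rng.poisson(20, size=50).astype(float)
        a, b = quantile_normalize(self._profiles([row, row]))
        idx = a.scored_indices()
        assert np.allclose(a.normalized[idx], row[idx])
        assert np.allclose(b.normalized[idx], row[idx])

    def test_hand_rank_arithmetic(self):
        # bait 5 excludes fragments 3..7, so fragments 0..2 are the scored set
        a, b = quantile_normalize(
            self._profiles(
                [[1, 2, 3, 0, 0, 0, 0, 0], [10, 20, 30, 0, 0, 0, 0, 0]], bait=5
            )
        )
        assert np.allclose(a.normalized[:3], [5.5, 11.0, 16.5])
        assert np.allclose(b.normalized[:3], [5.5, 11.0, 16.5])

    def test_sorted_vectors_identical_and_idempotent(self):
        # tie-free values: with ties the averaged ranks make the property
        # approximate by construction, so the exact check uses continuous data
        rng = np.random.default_rng(1)
        profs = self._profiles(rng.uniform(1, 100, size=(3, 80)))
        normed = quantile_normalize(profs)
        idx = normed[0].scored_indices()
        ref = np.sort(normed[0].normalized[idx])
        for p in normed[1:]:
            assert np.allclose(np.sort(p.normalized[idx]), ref)
        # idempotent: renormalizing the normalized values changes nothing
        again = quantile_normalize(
            [
                FourCProfile(bait_fragment=p.bait_fragment, counts=np.nan_to_num(p.normalized))
                for p in normed
            ]
        )
        for p, q in zip(normed, again):
            assert np.allclose(p.normalized[idx], q.normalized[idx])

    def test_rank_preserving_per_sample(self):
        rng = np.random.default_rng(2)
        profs = self._profiles(rng.uniform(0, 100, size=(2, 60)))
        normed = quantile_normalize(profs)
        for raw, p in zip(profs, normed):
            idx = p.scored_indices()
            assert np.array_equal(
                np.argsort(raw.counts[idx], kind="stable"),
                np.argsort(p.normalized[idx], kind="stable"),
            )

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(self._profiles([np.ones(30)]))

    def test_mismatched_universes_rejected(self):
        a = FourCProfile(bait_fragment=5, counts=np.ones(30))
        b = FourCProfile(bait_fragment=9, counts=np.ones(30))
        with pytest.raises(ValueError):
            quantile_normalize([a, b])


class TestSmoothing:
    def _profile(self, values, bait=0):
        p = FourCProfile(bait_fragment=bait, counts=np.asarray(values, dtype=float))
        return p.scored_from_counts()

    def test_constant_vector_unchanged(self):
        p = self._profile(np.full(60, 3.0))
        sm = smooth_profile(p, 21)
        idx = p.scored_indices()
        assert np.allclose(sm[idx], 3.0)

    def test_impulse_becomes_unit_plateau(self):
        vals = np.zeros(101)
        vals[50] = 21.0
        p = self._profile(vals)
        sm = smooth_profile(p, 21)
        # scored fragments exclude bait 0 +/- 2 -> impulse sits mid-sequence
        idx = p.scored_indices()
        inner = sm[idx]
        plateau = np.flatnonzero(np.isclose(inner, 1.0))
        assert plateau.size == 21

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(size=40)
        p = self._profile(vals)
        sm = smooth_profile(p, 1)
        idx = p.scored_indices()
        assert np.allclose(sm[idx], vals[idx])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(self._profile(np.ones(40)), 4)

    def test_window_larger_than_profile_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(self._profile(np.ones(10)), 21)


def _decay_profile(seed, bump=True, n=1000, bait=100, factor=3.0, sigma=0.2):
    rng = np.random.default_rng(seed)
    d = np.abs(np.arange(n) - bait) + 1.0
    mu = 1000.0 / d
    if bump:
        mu[600:610] *= factor
    return FourCProfile(
        bait_fragment=bait, counts=np.round(mu * rng.lognormal(0, sigma, size=n))
    )


class TestInteractionCalling:
    def test_exact_monotone_decay_no_candidates(self):
        prof = _decay_profile(0, bump=False, sigma=0.0).scored_from_counts()
        per, rep = call_interactions({"s": prof})
        assert per["s"] == [] and rep == []

    def test_planted_bump_recovered(self):
        profs = dict(
            zip(("a", "b"), quantile_normalize([_decay_profile(3 + i) for i in range(2)]))
        )
        _, rep = call_interactions(profs)
        assert any(r.first_fragment <= 609 and r.last_fragment >= 600 for r in rep)

    def test_disjoint_candidates_no_reproducible_regions(self):
        a = _decay_profile(1, bump=False, sigma=0.0).scored_from_counts()
        # plant bumps at different places in hand-built normalized profiles
        av = np.nan_to_num(a.normalized.copy())
        bv = av.copy()
        av[300:310] *= 5
        bv[700:710] *= 5
        pa = FourCProfile(bait_fragment=100, counts=av, normalized=None).scored_from_counts()
        pb = FourCProfile(bait_fragment=100, counts=bv, normalized=None).scored_from_counts()
        per, rep = call_interactions({"a": pa, "b": pb})
        assert per["a"] and per["b"]
        assert rep == []


class TestDifferentialInteraction:
    def _profiles(self, means, bait=0, n=40):
        out = {}
        for name, m in means.items():
            vals = np.full(n, float(m))
            out[name] = FourCProfile(bait_fragment=bait, counts=vals).scored_from_counts()
        return out

    def test_identical_condition_means_null(self):
        region = InteractionRegion(10, 20)
        conds = {
            "WT": self._profiles({"m": 5.0, "f": 5.0}),
            "HD": self._profiles({"m": 5.0, "f": 5.0}),
        }
        (res,) = differential_interaction([region], conds)
        assert res.t_stat == 0.0 and res.raw_p == 1.0

    def test_paired_t_closed_form(self):
        region = InteractionRegion(10, 20)
        conds = {
            "WT": self._profiles({"m": 1.0, "f": 2.1}),
            "HD": self._profiles({"m": 2.0, "f": 3.0}),
        }
        (res,) = differential_interaction([region], conds, paired=True)
        diffs = np.array([1.0 - 2.0, 2.1 - 3.0])
        t_expect = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(2))
        p_expect = 2 * stats.t.sf(abs(t_expect), df=1)
        assert res.t_stat == pytest.approx(t_expect)
        assert res.raw_p == pytest.approx(p_expect)

    def test_zero_variance_paired_falls_back_with_warning(self):
        region = InteractionRegion(10, 20)
        conds = {
            "WT": self._profiles({"m": 1.0, "f": 2.0}),
            "HD": self._profiles({"m": 2.0, "f": 3.0}),
        }
        with pytest.warns(RuntimeWarning, match="Welch"):
            (res,) = differential_interaction([region], conds, paired=True)
        assert 0.0 <= res.raw_p <= 1.0

    def test_null_regions_bh_controls_significance(self):
        rng = np.random.default_rng(0)
        hits = 0
        for trial in range(20):
            regions = [InteractionRegion(i * 2, i * 2 + 1) for i in range(20)]
            trng = np.random.default_rng(trial)
            conds = {}
            for cond in ("WT", "HD"):
                conds[cond] = {}
                for rep in ("m", "f", "x"):
                    vals = 10 + trng.normal(0, 1, size=40)
                    conds[cond][rep] = FourCProfile(
                        bait_fragment=0, counts=np.maximum(vals, 0)
                    ).scored_from_counts()
            res = differential_interaction(regions, conds)
            hits += any(r.adj_p < 0.05 for r in res)
        assert hits <= 1  # no significant regions in >= 95% of null runs

    def test_single_sample_condition_rejected(self):
        conds = {"WT": self._profiles({"m": 1.0}), "HD": self._profiles({"m": 2.0, "f": 2.0})}
        with pytest.raises(ValueError):
            differential_interaction([InteractionRegion(0, 5)], conds)
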