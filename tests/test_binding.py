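"""A-band census: assignment, topology, profiles, angles, distances."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sarcotomo import binding as B
from sarcotomo.errors import InputError, InsufficientDataError
from sarcotomo.specs import BindingSpec, LatticeSpec
from sarcotomo.synth import build_aband_model


class TestAssignHeads:
    def test_worked_occupancy_example(self):
        # the published census: 2,734 fitted of 3,315 theoretical heads
        assert B.occupancy_from_counts(2734, 3315) * 100 == pytest.approx(82.5, abs=0.05)

    def test_zero_heads_zero_occupancy(self):
        assert B.occupancy_from_counts(0, 3315) == 0.0

    def test_round_trip_assignment(self, aband30):
        heads, summary = B.assign_heads(aband30.heads, aband30)
        # generator heads sit 20 Å from their subunit: all assigned back
        assert summary["n_unassigned"] == 0
        assert (heads["subunit_id"].to_numpy()
                == aband30.heads["subunit_id"].to_numpy()).all()
        assert summary["n_assigned"] + summary["n_unassigned"] == summary["n_heads"]
        assert summary["occupancy"] == pytest.approx(0.825, abs=0.02)

    def test_far_heads_flagged_not_dropped(self, aband_model):
        far = aband_model.heads.head(3).copy()
        far[["x", "y", "z"]] += 50000.0
        out, summary = B.assign_heads(far, aband_model)
        assert summary["n_unassigned"] == 3
        assert (out["subunit_id"] == -1).all()
        assert len(out) == 3


class TestTopology:
    def test_split_worked_example(self):
        # 10 split pairs of 3,315 theoretical heads = 0.6% of all heads
        assert 2 * 10 / 3315 * 100 == pytest.approx(0.6, abs=0.05)

    def test_all_unpaired_is_all_single(self, aband_model):
        heads = aband_model.heads.copy()
        heads["myosin_id"] = np.arange(len(heads))  # break all pairs
        topo = B.classify_head_topology(heads, aband_model)
        assert topo["frac"]["single"] == 1.0

    def test_classification_matches_generator(self, aband30):
        topo = B.classify_head_topology(aband30.heads, aband30)
        gen = aband30.heads["klass"].value_counts()
        assert topo["n_split"] == gen.get("split", 0)
        assert topo["n_single"] == gen.get("single", 0)
        assert topo["n_double"] == gen.get("double", 0)
        assert topo["n_heads"] == len(aband30.heads)

    def test_three_heads_rejected(self, aband_model):
        heads = aband_model.heads.head(3).copy()
        heads["myosin_id"] = 0
        with pytest.raises(InputError):
            B.classify_head_topology(heads, aband_model)


class TestProfiles:
    def test_no_heads_all_e(self, aband_model):
        import copy
        model = copy.copy(aband_model)
        model.heads = model.heads.iloc[0:0]
        for prof in B.encode_profiles(model, model.thin_ids()[0]):
            assert set(prof.sequence) == {"E"}

    def test_single_head_position(self, aband_model):
        import copy
        model = copy.copy(aband_model)
        thin0 = model.thin_ids()[0]
        subs = model.subunits[model.subunits["filament_id"] == thin0]
        # strand-1 (even k) subunit with k=4 -> strand ordinal 2
        sid = subs[subs["k"] == 4].index[0]
        nbrs = sorted(model.neighbors_of(thin0))
        model.heads = pd.DataFrame([dict(
            myosin_id=0, head_slot="a", origin_thick_id=nbrs[0],
            subunit_id=sid, klass="single", x=0.0, y=0.0, z=0.0)])
        p1, p2 = B.encode_profiles(model, thin0)
        assert p1.sequence[2] == "R"
        assert set(p1.sequence[:2] + p1.sequence[3:]) <= {"E"}
        assert set(p2.sequence) <= {"E"}

    def test_letter_runs_cluster_at_half_repeat(self, aband30):
        # one colour's hotspots recur every ~13-14 strand-1 ordinals: the
        # strand-1 azimuth advances 26.8 deg per ordinal, so the gate
        # window toward one thick filament repeats every 360/26.8 = 13.4
        # positions (~37 nm of filament)
        acs = []
        for thin_id in aband30.thin_ids()[:6]:
            p1, _ = B.encode_profiles(aband30, thin_id)
            arr = np.array([c == "R" for c in p1.sequence], dtype=float)
            arr = arr - arr.mean()
            ac = np.correlate(arr, arr, mode="full")[len(arr) - 1:]
            acs.append(ac[:20] / ac[0])
        mean_ac = np.mean(acs, axis=0)
        period = int(np.argmax(mean_ac[8:20])) + 8
        assert 12 <= period <= 15


def brute_force_align(a, b, w):
    """Exhaustive optimum over all global alignments with affine gaps."""
    best = -np.inf

    def score(cols):
        s = 0.0
        prev = None
        for ca, cb in cols:
            if ca == "-" or cb == "-":
                gap = "a" if ca == "-" else "b"
                s += w.gap_extend if prev == gap else w.gap_open
                prev = gap
            else:
                s += w.score(ca, cb)
                prev = None
        return s

    def rec(i, j, cols):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score(cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best


class TestAlignment:
    def test_identical_sequences_gap_free(self):
        w = B.ProfileWeights()
        a1, a2, s = B.pairwise_align("RGEBE", "RGEBE", w)
        assert a1 == a2 == "RGEBE"
        assert s == w.match * 3 + w.e_match * 2

    def test_example_pair_matches_brute_force(self):
        w = B.ProfileWeights()
        _, _, s = B.pairwise_align("RGE", "REE", w)
        assert s == brute_force_align("RGE", "REE", w)

    def test_pairwise_equals_brute_force_short_random(self):
        # oracle equivalence on random sequences of length <= 6
        rng = np.random.default_rng(0)
        w = B.ProfileWeights()
        letters = "RGBE"
        for _ in range(25):
            a = "".join(rng.choice(list(letters), rng.integers(1, 7)))
            b = "".join(rng.choice(list(letters), rng.integers(1, 7)))
            _, ga, s = B.pairwise_align(a, b, w)
            assert s == pytest.approx(brute_force_align(a, b, w)), (a, b)

    def test_traceback_consistent_with_score(self):
        rng = np.random.default_rng(1)
        w = B.ProfileWeights()
        for _ in range(10):
            a = "".join(rng.choice(list("RGBE"), 8))
            b = "".join(rng.choice(list("RGBE"), 6))
            ga, gb, s = B.pairwise_align(a, b, w)
            assert ga.replace("-", "") == a
            assert gb.replace("-", "") == b
            assert len(ga) == len(gb)
            assert s == pytest.approx(brute_force_align(a, b, w))

    def test_alphabet_enforced(self):
        with pytest.raises(InputError):
            B.pairwise_align("RGX", "REE")

    def test_msa_counts_and_width(self):
        seqs = ["ERGE", "ERGE", "ERG"]
        res = B.align_profiles(seqs)
        width = len(res["msa"][0])
        assert all(len(r) == width for r in res["msa"])
        counts = res["counts"]
        assert (counts.sum(axis=1) == len(seqs)).all()

    def test_hotspot_tracks_in_synthetic_msa(self, aband30):
        # strand-1 profiles of a gated model align into interleaved
        # R/G/B occurrence tracks
        seqs = []
        for thin_id in aband30.thin_ids()[:12]:
            p1, _ = B.encode_profiles(aband30, thin_id)
            seqs.append(p1.sequence[:60])
        res = B.align_profiles(seqs)
        counts = res["counts"]
        for letter in "RGB":
            assert counts[letter].max() >= 3  # a hotspot column per colour
        # hotspot columns for different colours interleave, not coincide
        top = {letter: int(counts[letter].idxmax()) for letter in "RGB"}
        assert len(set(top.values())) > 1

    def test_strand2_mapping(self):
        assert B.map_strand2("E-RG", "BGE") == "B-GE"


class TestAngular:
    def test_span_and_mean_basics(self):
        assert B.angular_span(np.array([10.0])) == 0.0
        vals = np.array([350.0, 0.0, 10.0])
        assert B.angular_span(vals) == pytest.approx(20.0)
        assert B.circular_mean_deg(vals) == pytest.approx(0.0, abs=1e-9)

    def test_three_groups_separated_by_lattice_bearings(self, aband_model):
        # raw bound-subunit azimuths on one thin filament form three
        # clusters separated by ~120 deg (the trigonal thick bearings)
        orient = B.bound_orientations(aband_model)
        one = orient[orient["thin_id"] == orient["thin_id"].iloc[0]]
        dist = B.angular_distribution(one["azimuth"].to_numpy(),
                                      one["group"].to_numpy())
        means = sorted(d["circular_mean"] % 360 for d in dist.values())
        gaps = np.diff(means + [means[0] + 360.0])
        assert np.allclose(gaps, 120.0, atol=15.0)

    def test_gate_gives_120_deg_span(self, aband30):
        orient = B.bound_orientations(aband30)
        dist = B.angular_distribution(orient["rel_orientation"].to_numpy(),
                                      orient["group"].to_numpy())
        spans = [d["span"] for d in dist.values()]
        assert len(spans) == 3
        assert np.mean(spans) == pytest.approx(120.0, abs=10.0)

    def test_empty_group_skipped(self):
        out = B.angular_distribution(np.array([1.0, 2.0]),
                                     np.array(["a", "a"]))
        assert "a" in out and len(out) == 1


class TestDistances:
    def test_bookkeeping_three_per_subunit(self, aband_model):
        bound, free = B.measure_thin_thick_distances(aband_model)
        assert len(bound) + len(free) == 3 * len(aband_model.subunits)
        assert len(bound) == len(aband_model.heads)

    def test_published_parameters_recovered(self):
        rng = np.random.default_rng(11)
        bound = rng.normal(25.9, 2.7, 2734)
        free = rng.normal(26.3, 2.7, 3 * 5664 - 2734)
        res = B.distance_statistics(bound, free)
        assert res["bound"]["mean"] == pytest.approx(25.9, abs=0.1)
        assert res["free"]["mean"] == pytest.approx(26.3, abs=0.1)
        d = res["difference"]
        assert d["mean"] == pytest.approx(0.4, abs=0.15)
        lo, hi = d["ci"]
        assert lo <= 0.5 and hi >= 0.2  # overlaps the published 0.2-0.5
        assert not res["bound"]["significant"]

    def test_identical_populations_ci_contains_zero(self):
        rng = np.random.default_rng(12)
        x = rng.normal(26.0, 2.7, 2000)
        y = x + rng.normal(0.0, 0.001, 2000)  # statistically identical
        res = B.distance_statistics(x, y)
        lo, hi = res["difference"]["ci"]
        assert lo <= 0.0 <= hi

    def test_lognormal_flags_skewness(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0.0, 0.8, 3000)
        res = B.distance_statistics(x, rng.normal(26.3, 2.7, 3000))
        assert res["bound"]["significant"]

    def test_bootstrap_ci_close_to_welch(self):
        rng = np.random.default_rng(4)
        bound = rng.normal(25.9, 2.7, 800)
        free = rng.normal(26.3, 2.7, 2000)
        w = B.distance_statistics(bound, free, ci_method="welch")
        bs = B.distance_statistics(bound, free, ci_method="bootstrap",
                                   n_boot=2000, seed=0)
        assert np.allclose(w["difference"]["ci"], bs["difference"]["ci"],
                           atol=0.05)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            B.distance_statistics(np.array([1.0]), np.array([1.0, 2.0]))
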