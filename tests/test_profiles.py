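import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathprofiler.enrichment import EnrichmentResult, GeneStat
from pathprofiler.profiles import (
    PathwayProfile,
    build_profile,
    cep_fractions,
    fdr_sweep,
    read_profile_matrix,
    reference_profile,
    reproducibility,
    top_k_deg_overlap,
    venn_partition,
    write_profile_matrix,
)


def _result(pid, q, enriched=None):
    q = float(q)
    return EnrichmentResult(
        pathway_id=pid, n_genes_measured=10, score=1.0, p_value=min(q, 1.0),
        q_value=q, enriched=(q <= 0.1) if enriched is None else enriched,
    )


def _profile(label, universe, enriched_ids):
    bits = [1 if pid in enriched_ids else 0 for pid in universe]
    return PathwayProfile(disease_label=label, pathway_ids=tuple(universe), bits=tuple(bits))


UNIVERSE = tuple(f"P{i:02d}" for i in range(20))


class TestBuildProfile:
    def test_direct_construction(self):
        universe = ("P1", "P2", "P3")
        results = [_result("P2", 0.01), _result("P1", 0.5), _result("P3", 0.9)]
        prof = build_profile(results, universe, "d")
        assert prof.bits == (0, 1, 0)

    def test_empty_and_full(self):
        universe = ("P1", "P2")
        assert build_profile([], universe, "d").bits == (0, 0)
        full = [_result("P1", 0.01), _result("P2", 0.01)]
        assert build_profile(full, universe, "d").bits == (1, 1)

    def test_result_outside_universe_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            build_profile([_result("PX", 0.01)], ("P1",), "d")

    def test_missing_result_defaults_to_zero(self):
        prof = build_profile([_result("P1", 0.01)], ("P1", "P2"), "d")
        assert prof.bits == (1, 0)


class TestReproducibility:
    def test_identical_sets(self):
        res = reproducibility({"a", "b"}, {"a", "b"})
        assert res.r == 1.0 and res.N_c == 2

    def test_disjoint_sets(self):
        assert reproducibility({"a"}, {"b"}).r == 0.0

    def test_signature_overlap_worked_example(self):
        """Two survival signatures of 456 and 231 genes sharing 17 genes."""
        res = reproducibility(set(range(456)), set(range(450, 681)))
        assert (res.N, res.N_prime, res.N_c) == (456, 231, 6)
        direct = reproducibility([f"a{i}" for i in range(456)],
                                 [f"a{i}" for i in range(17)] + [f"b{i}" for i in range(214)])
        assert (direct.N, direct.N_prime, direct.N_c) == (456, 231, 17)
        assert direct.r == pytest.approx(17 / 343.5, abs=1e-6)

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            reproducibility(set(), set())

    def test_profiles_and_sets_agree(self):
        a = _profile("a", UNIVERSE, {"P01", "P02"})
        b = _profile("b", UNIVERSE, {"P02", "P03"})
        assert reproducibility(a, b) == reproducibility({"P01", "P02"}, {"P02", "P03"})

    def test_mismatched_universes_rejected(self):
        a = _profile("a", UNIVERSE, {"P01"})
        b = _profile("b", UNIVERSE[:10], {"P01"})
        with pytest.raises(ValueError, match="universes"):
            reproducibility(a, b)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.sets(st.integers(0, 30), max_size=20),
        st.sets(st.integers(0, 30), max_size=20),
    )
    def test_symmetry_and_range(self, a, b):
        if not a and not b:
            return
        fwd, rev = reproducibility(a, b), reproducibility(b, a)
        assert fwd.r == rev.r
        assert 0.0 <= fwd.r <= 1.0
        assert (fwd.r == 1.0) == (a == b and bool(a))
        assert fwd.N_c <= min(fwd.N, fwd.N_prime)


class TestReferenceProfile:
    def test_more_than_one_dataset_rule(self):
        profs = [
            _profile("d1", UNIVERSE, {"P01", "P02"}),
            _profile("d2", UNIVERSE, {"P01"}),
            _profile("d3", UNIVERSE, {"P03"}),
        ]
        ref = reference_profile(profs)
        assert ref.enriched_set == {"P01"}  # P02, P03 seen once only

    def test_identical_inputs_reproduce_themselves(self):
        prof = _profile("d", UNIVERSE, {"P05", "P06"})
        ref = reference_profile([prof, prof, prof])
        assert ref.bits == prof.bits

    def test_bounded_by_and_and_or(self):
        profs = [
            _profile("d1", UNIVERSE, {"P01", "P02", "P03"}),
            _profile("d2", UNIVERSE, {"P02", "P03"}),
            _profile("d3", UNIVERSE, {"P03", "P09"}),
        ]
        ref = np.array(reference_profile(profs).bits)
        bits = np.array([p.bits for p in profs])
        assert np.all(ref <= bits.max(axis=0))
        assert np.all(ref >= bits.min(axis=0))

    def test_threshold_knob(self):
        profs = [
            _profile("d1", UNIVERSE, {"P01", "P02"}),
            _profile("d2", UNIVERSE, {"P01", "P02"}),
            _profile("d3", UNIVERSE, {"P01"}),
        ]
        assert reference_profile(profs, min_support=3).enriched_set == {"P01"}

    def test_fewer_than_two_profiles_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            reference_profile([_profile("d", UNIVERSE, set())])


class TestVennPartition:
    def test_all_patterns_realized(self):
        """Four sets hitting every membership pattern give 15 regions."""
        labels = ("A", "B", "C", "D")
        universe = []
        enriched = {s: set() for s in labels}
        for i, pattern in enumerate(
            p for n in range(1, 5) for p in itertools.combinations(labels, n)
        ):
            pid = f"P{i:02d}"
            universe.append(pid)
            for s in pattern:
                enriched[s].add(pid)
        profiles = {s: _profile(s, tuple(universe), enriched[s]) for s in labels}
        part = venn_partition(profiles)
        assert len(part.regions) == 15

    def test_identical_profiles_single_region(self):
        prof_bits = {"P01", "P02"}
        profiles = {s: _profile(s, UNIVERSE, prof_bits) for s in ("A", "B", "C")}
        part = venn_partition(profiles)
        assert set(part.regions) == {frozenset({"A", "B", "C"})}
        assert part.cep == prof_bits

    def test_regions_disjoint_and_cover_union(self):
        profiles = {
            "A": _profile("A", UNIVERSE, {"P01", "P02", "P05"}),
            "B": _profile("B", UNIVERSE, {"P02", "P03"}),
            "C": _profile("C", UNIVERSE, {"P02", "P05", "P09"}),
        }
        part = venn_partition(profiles)
        regions = list(part.regions.values())
        union = frozenset().union(*regions)
        assert sum(len(r) for r in regions) == len(union)
        assert union == frozenset().union(*(p.enriched_set for p in profiles.values()))

    def test_mismatched_universes_rejected(self):
        profiles = {
            "A": _profile("A", UNIVERSE, set()),
            "B": _profile("B", UNIVERSE[:5], set()),
        }
        with pytest.raises(ValueError, match="universes"):
            venn_partition(profiles)


class TestCepFractions:
    def test_published_worked_example(self):
        """|CEP| = 28 against totals (66, 84, 55, 85) rounds to 42/33/51/33%."""
        labels = ("LuminalA", "LuminalB", "TripleNegative", "HER2pos")
        totals = dict(zip(labels, (66, 84, 55, 85)))
        universe, enriched = _cep_construction(labels, 28, totals)
        part = venn_partition({s: _profile(s, universe, enriched[s]) for s in labels})
        assert len(part.cep) == 28
        exact, rounded = cep_fractions(part)
        assert [rounded[s] for s in labels] == [42, 33, 51, 33]
        assert exact["LuminalA"] == pytest.approx(100 * 28 / 66)

    def test_empty_cep_gives_zero(self):
        profiles = {
            "A": _profile("A", UNIVERSE, {"P01"}),
            "B": _profile("B", UNIVERSE, {"P02"}),
        }
        _, rounded = cep_fractions(venn_partition(profiles))
        assert rounded == {"A": 0, "B": 0}

    def test_identical_profiles_give_100(self):
        profiles = {s: _profile(s, UNIVERSE, {"P01", "P04"}) for s in ("A", "B", "C", "D")}
        exact, rounded = cep_fractions(venn_partition(profiles))
        assert all(v == 100 for v in rounded.values())

    def test_zero_enriched_subtype_undefined(self):
        profiles = {
            "A": _profile("A", UNIVERSE, {"P01"}),
            "B": _profile("B", UNIVERSE, set()),
        }
        exact, rounded = cep_fractions(venn_partition(profiles))
        assert rounded["B"] is None and np.isnan(exact["B"])


def _cep_construction(labels, n_cep, totals):
    """Profiles sharing exactly ``n_cep`` pathways, padded to the totals
    with fillers unique to each label."""
    universe = [f"CEP{i:03d}" for i in range(n_cep)]
    enriched = {s: set(universe) for s in labels}
    for s in labels:
        fillers = [f"F_{s}_{i:03d}" for i in range(totals[s] - n_cep)]
        universe.extend(fillers)
        enriched[s].update(fillers)
    return tuple(universe), enriched


class TestTopKDegOverlap:
    @staticmethod
    def _stats(genes_in_rank_order):
        return [GeneStat(g, 10.0 - i, i + 1) for i, g in enumerate(genes_in_rank_order)]

    def test_identical_lists(self):
        s = self._stats(list("ABCDEF"))
        assert top_k_deg_overlap(s, s, k=3).r == 1.0

    def test_distinct_halves(self):
        a = self._stats(list("ABCDEF"))
        b = self._stats(list("DEFABC"))
        res = top_k_deg_overlap(a, b, k=3)
        assert res.r == 0.0 and res.N == res.N_prime == 3

    def test_equals_set_arithmetic(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(50)]
        a = self._stats(list(rng.permutation(genes)))
        b = self._stats(list(rng.permutation(genes)))
        k = 20
        top_a = {s.gene for s in a if s.rank <= k}
        top_b = {s.gene for s in b if s.rank <= k}
        assert top_k_deg_overlap(a, b, k=k).r == pytest.approx(len(top_a & top_b) / k)

    def test_k_too_large_rejected(self):
        s = self._stats(list("ABC"))
        with pytest.raises(ValueError, match="exceeds"):
            top_k_deg_overlap(s, s, k=4)


class TestFdrSweep:
    def test_cutoff_one_gives_r_one(self):
        a = [_result("P1", 0.5), _result("P2", 0.9)]
        b = [_result("P1", 0.7), _result("P2", 0.95)]
        assert fdr_sweep(a, b, [1.0]) == [(1.0, 1.0)]

    def test_cutoff_below_all_q_reports_missing(self):
        a = [_result("P1", 0.5)]
        b = [_result("P1", 0.7)]
        assert fdr_sweep(a, b, [0.01]) == [(0.01, None)]

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(1)
        ids = [f"P{i}" for i in range(30)]
        a = [_result(pid, q) for pid, q in zip(ids, rng.uniform(0.001, 1, 30))]
        b = [_result(pid, q) for pid, q in zip(ids, rng.uniform(0.001, 1, 30))]
        cutoffs = [0.05, 0.1, 0.3, 0.8]
        for cutoff, r in fdr_sweep(a, b, cutoffs):
            sa = {x.pathway_id for x in a if x.q_value <= cutoff}
            sb = {x.pathway_id for x in b if x.q_value <= cutoff}
            if not sa and not sb:
                assert r is None
            else:
                assert r == pytest.approx(reproducibility(sa, sb).r)

    def test_unsorted_cutoffs_rejected(self):
        a = [_result("P1", 0.5)]
        with pytest.raises(ValueError, match="sorted"):
            fdr_sweep(a, a, [0.5, 0.1])

    def test_out_of_range_cutoffs_rejected(self):
        a = [_result("P1", 0.5)]
        with pytest.raises(ValueError, match="0, 1"):
            fdr_sweep(a, a, [0.0, 0.5])


def test_profile_matrix_roundtrip(tmp_path):
    profs = [
        _profile("LuminalA", UNIVERSE, {"P01", "P05"}),
        _profile("GBM", UNIVERSE, {"P02"}),
    ]
    path = tmp_path / "profiles.tsv"
    write_profile_matrix(profs, path, header_comment="prov")
    back = read_profile_matrix(path)
    assert [p.disease_label for p in back] == ["LuminalA", "GBM"]
    assert all(a.bits == b.bits for a, b in zip(back, profs))
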