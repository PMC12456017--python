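"""Both decision procedures: complete-genome screen and MAG pipeline."""

import math

import numpy as np
import pytest

from chromidfinder import errors
from chromidfinder.classify import (
    CHROMID,
    CHROMOSOME,
    OTHER,
    UNASSIGNED,
    Thresholds,
    apply_distance_filter,
    classify_complete_genome,
    find_clusters,
    finalize_calls,
    prepare_pipeline,
    run_chromid_finder,
)
from chromidfinder.markers import MarkerProfile
from chromidfinder.seq_io import GenomeAssembly, Replicon
from chromidfinder.signatures import relative_abundance
from chromidfinder.synthetic import GeneratorParams, generate_assembly, generate_benchmark

from conftest import oracle_distance


def make_seq(length: int, gc_pct: float) -> str:
    """Deterministic sequence with exact GC fraction (shuffled fixed pattern)."""
    n_gc = round(length * gc_pct / 100)
    bases = ["G" if i % 2 else "C" for i in range(n_gc)]
    bases += ["A" if i % 2 else "T" for i in range(length - n_gc)]
    rng = np.random.default_rng(0)
    order = rng.permutation(length)
    return "".join(bases[i] for i in order)


def profile(rid, rep=0, par=0, core=0, dnaa=0):
    return MarkerProfile(rid, n_rep=rep, n_par=par, n_core=core, n_dnaa=dnaa)


class TestCompleteGenomeScreen:
    def test_single_replicon_assembly_is_unassigned(self):
        assembly = GenomeAssembly("g", [Replicon("solo", make_seq(1000, 50))])
        result = classify_complete_genome(assembly, {"solo": profile("solo")})
        assert result.calls == {"solo": UNASSIGNED}

    def test_secondary_with_markers_and_close_gc_is_chromid(self):
        assembly = GenomeAssembly(
            "g",
            [Replicon("chr", make_seq(30_000, 60.0)), Replicon("sec", make_seq(10_000, 60.3))],
        )
        profiles = {"chr": profile("chr", dnaa=1), "sec": profile("sec", rep=1, par=1, core=2)}
        result = classify_complete_genome(assembly, profiles)
        assert result.calls == {"chr": CHROMOSOME, "sec": CHROMID}

    def test_secondary_missing_core_is_other(self):
        assembly = GenomeAssembly(
            "g",
            [Replicon("chr", make_seq(30_000, 60.0)), Replicon("sec", make_seq(10_000, 60.3))],
        )
        profiles = {"chr": profile("chr", dnaa=1), "sec": profile("sec", rep=1, par=1, core=0)}
        result = classify_complete_genome(assembly, profiles)
        assert result.calls["sec"] == OTHER
        assert any("CORE" in reason for reason in result.evidence["sec"])

    def test_secondary_outside_gc_band_is_other(self):
        assembly = GenomeAssembly(
            "g",
            [Replicon("chr", make_seq(30_000, 60.0)), Replicon("sec", make_seq(10_000, 61.4))],
        )
        profiles = {"chr": profile("chr", dnaa=1), "sec": profile("sec", rep=1, par=1, core=2)}
        result = classify_complete_genome(assembly, profiles)
        assert result.calls["sec"] == OTHER
        assert any("GC delta" in reason for reason in result.evidence["sec"])

    def test_gc_band_boundary_is_inclusive(self):
        # 60.0 vs 61.0 passes (delta exactly 1.0 pp), 61.01 would fail
        assembly = GenomeAssembly(
            "g",
            [Replicon("chr", make_seq(50_000, 60.0)), Replicon("sec", make_seq(20_000, 61.0))],
        )
        profiles = {"chr": profile("chr", dnaa=1), "sec": profile("sec", rep=1, par=1, core=1)}
        assert classify_complete_genome(assembly, profiles).calls["sec"] == CHROMID

    def test_length_tie_broken_by_dnaa_then_id_with_warning(self):
        a, b = make_seq(10_000, 55.0), make_seq(10_000, 55.0)
        assembly = GenomeAssembly("g", [Replicon("zzz", a), Replicon("aaa", b)])
        profiles = {"zzz": profile("zzz", dnaa=1), "aaa": profile("aaa", rep=1, par=1, core=1)}
        with pytest.warns(UserWarning, match="tie"):
            result = classify_complete_genome(assembly, profiles)
        assert result.calls["zzz"] == CHROMOSOME

    def test_missing_profile_rejected(self):
        assembly = GenomeAssembly("g", [Replicon("chr", make_seq(1000, 50))])
        with pytest.raises(errors.ValidationError):
            classify_complete_genome(assembly, {})

    def test_dinucleotide_prescreen_rejects_divergent_composition(self):
        # same GC, very different dinucleotide structure: only the structured
        # secondary should fall to the pre-screen, before any marker check
        chrom = Replicon("chr", make_seq(300_000, 60.0))
        alike = Replicon("alike", make_seq(100_000, 60.3))
        skewed = Replicon("skewed", "CCCGGGAATT" * 10_000)  # 60% GC, homopolymer runs
        profiles = {
            "chr": profile("chr", dnaa=1, core=2),
            "alike": profile("alike", rep=1, par=1, core=1),
            "skewed": profile("skewed", rep=1, par=1, core=1),
        }
        th = Thresholds(dinuc_dist_max=0.4)
        result = classify_complete_genome(
            GenomeAssembly("g", [chrom, alike, skewed]), profiles, th
        )
        assert result.calls["alike"] == CHROMID
        assert result.calls["skewed"] == OTHER
        assert any("dinucleotide" in r for r in result.evidence["skewed"])


class TestFindClusters:
    def _pool(self):
        return [
            Replicon("center", make_seq(20_000, 60.0)),
            Replicon("cand", make_seq(15_000, 60.5)),
        ]

    def test_candidate_within_band_and_markers_joins(self):
        pool = self._pool()
        profiles = {
            "center": profile("center", dnaa=1),
            "cand": profile("cand", rep=1, par=1, core=1),
        }
        (cluster,) = find_clusters(pool, profiles)
        assert [m.replicon_id for m in cluster.members] == ["cand"]

    def test_candidate_longer_than_center_excluded(self):
        pool = [Replicon("center", make_seq(20_000, 60.0)), Replicon("big", make_seq(25_000, 60.0))]
        profiles = {"center": profile("center", dnaa=1), "big": profile("big", rep=1, par=1, core=1)}
        (cluster,) = find_clusters(pool, profiles)
        assert cluster.members == []

    def test_equal_length_candidate_excluded(self):
        pool = [Replicon("center", make_seq(20_000, 60.0)), Replicon("twin", make_seq(20_000, 60.0))]
        profiles = {"center": profile("center", dnaa=1), "twin": profile("twin", rep=1, par=1, core=1)}
        (cluster,) = find_clusters(pool, profiles)
        assert cluster.members == []

    def test_candidate_outside_gc_band_excluded(self):
        pool = [Replicon("center", make_seq(20_000, 60.0)), Replicon("far", make_seq(15_000, 62.0))]
        profiles = {"center": profile("center", dnaa=1), "far": profile("far", rep=1, par=1, core=1)}
        (cluster,) = find_clusters(pool, profiles)
        assert cluster.members == []

    def test_replicon_can_join_multiple_clusters(self):
        pool = [
            Replicon("c1", make_seq(20_000, 60.0)),
            Replicon("c2", make_seq(22_000, 60.2)),
            Replicon("small", make_seq(10_000, 60.4)),
        ]
        profiles = {
            "c1": profile("c1", dnaa=1),
            "c2": profile("c2", dnaa=1),
            "small": profile("small", rep=1, par=0, core=1),
        }
        clusters = find_clusters(pool, profiles)
        memberships = [m.replicon_id for c in clusters for m in c.members]
        assert memberships.count("small") == 2

    def test_relaxed_rule_admits_rep_or_par_with_core(self):
        pool = self._pool()
        profiles = {"center": profile("center", dnaa=1), "cand": profile("cand", par=1, core=1)}
        (cluster,) = find_clusters(pool, profiles, Thresholds(marker_rule="relaxed"))
        assert cluster.members
        (cluster,) = find_clusters(pool, profiles, Thresholds(marker_rule="strict"))
        assert cluster.members == []

    def test_no_dnaa_pool_warns_and_returns_empty(self):
        pool = self._pool()
        profiles = {"center": profile("center", core=1), "cand": profile("cand", rep=1, core=1)}
        with pytest.warns(UserWarning, match="DnaA"):
            assert find_clusters(pool, profiles) == []


class TestDistanceFilter:
    def _cluster_and_sigs(self, member_seq=None):
        center = Replicon("center", make_seq(20_000, 60.0))
        member = Replicon("m", member_seq or center.sequence[:15_000])
        profiles = {
            "center": profile("center", dnaa=1),
            "m": profile("m", rep=1, par=1, core=1),
        }
        (cluster,) = find_clusters([center, member], profiles)
        sigs = {
            "center": relative_abundance(center.sequence, 4),
            "m": relative_abundance(member.sequence, 4),
        }
        return cluster, sigs, center, member

    def test_identical_composition_passes_and_distance_zero_member(self):
        center = Replicon("center", make_seq(20_000, 60.0))
        member = Replicon("m", center.sequence[:8_000] * 2)  # not same seq, similar sig
        sigs = {"center": relative_abundance(center.sequence, 4),
                "m": relative_abundance(center.sequence, 4)}  # identical signature
        profiles = {"center": profile("center", dnaa=1), "m": profile("m", rep=1, core=1)}
        (cluster,) = find_clusters([center, member], profiles)
        filtered = apply_distance_filter(cluster, sigs)
        assert filtered.members[0].tetra_distance == 0.0
        assert filtered.members[0].passed

    def test_zero_threshold_passes_only_zero_distance(self):
        cluster, sigs, _, _ = self._cluster_and_sigs()
        filtered = apply_distance_filter(cluster, sigs, Thresholds(tetra_dist_max=0.0))
        assert all(m.passed is False for m in filtered.members)

    def test_missing_signature_rejected(self):
        cluster, sigs, _, _ = self._cluster_and_sigs()
        del sigs["m"]
        with pytest.raises(errors.ValidationError):
            apply_distance_filter(cluster, sigs)

    def test_passed_set_matches_brute_force_oracle(self, toy_db):
        """The passing member set equals an independent word-enumeration recomputation."""
        pool, _ = generate_benchmark(2, params=GeneratorParams(chromosome_length=60_000,
                                                               chromid_length=30_000,
                                                               plasmid_length=15_000),
                                     seed=5)
        state = prepare_pipeline(pool, toy_db)
        by_id = {r.id: r.sequence for r in pool}
        for cluster in state.clusters:
            for m in cluster.members:
                expected = oracle_distance(by_id[m.replicon_id], by_id[cluster.center_id], 4)
                assert m.tetra_distance == pytest.approx(expected, abs=1e-9)
                assert (expected < 1.6) == (m.tetra_distance < 1.6)


class TestRunChromidFinder:
    def test_seed7_assembly_chromid_called_plasmid_other(self, toy_db):
        asm, truth = generate_assembly(GeneratorParams(seed=7))
        result = run_chromid_finder(asm.replicons, toy_db)
        chrom, chromid, plasmid = [r.id for r in asm.replicons]
        assert result.calls[chrom] == CHROMOSOME
        assert result.calls[chromid] == CHROMID
        assert result.calls[plasmid] == OTHER

    def test_pool_without_dnaa_yields_no_chromids(self, toy_db):
        asm, _ = generate_assembly(GeneratorParams(seed=9, chromid_count=2))
        pool = [r for r in asm.replicons if "chromosome" not in r.id]
        with pytest.warns(UserWarning, match="DnaA"):
            result = run_chromid_finder(pool, toy_db)
        assert CHROMID not in result.calls.values()

    def test_single_dnaa_replicon_forms_empty_cluster(self, toy_db):
        asm, _ = generate_assembly(GeneratorParams(seed=4, chromid_count=0, plasmid_count=0))
        result = run_chromid_finder(asm.replicons, toy_db)
        assert len(result.clusters) == 1
        assert result.clusters[0].members == []
        assert list(result.calls.values()) == [CHROMOSOME]

    def test_duplicate_pool_ids_rejected(self, toy_db):
        rep = Replicon("dup", make_seq(5000, 50))
        with pytest.raises(errors.ValidationError):
            run_chromid_finder([rep, Replicon("dup", make_seq(5000, 50))], toy_db)

    def test_order_invariance(self, toy_db):
        pool, _ = generate_benchmark(3, seed=31)
        forward = run_chromid_finder(pool, toy_db)
        backward = run_chromid_finder(list(reversed(pool)), toy_db)
        assert forward.calls == backward.calls

    def test_raising_tetra_threshold_never_removes_chromid_calls(self, toy_db):
        pool, _ = generate_benchmark(3, seed=13)
        state = prepare_pipeline(pool, toy_db)
        previous: set[str] = set()
        for cutoff in (0.1, 0.5, 1.6, 5.0, math.inf):
            result = finalize_calls(state, Thresholds(tetra_dist_max=cutoff))
            current = {r for r, c in result.calls.items() if c == CHROMID}
            assert previous <= current
            previous = current

    def test_raising_gc_band_never_removes_cluster_members(self, toy_db):
        pool, _ = generate_benchmark(3, seed=17, params=GeneratorParams(plasmid_gc_offset=1.5,
                                                                        plasmid_markers="full"))
        previous: set[tuple[str, str]] = set()
        for band in (0.3, 1.0, 2.0, 4.0):
            state = prepare_pipeline(pool, toy_db, Thresholds(gc_delta_max=band))
            pairs = {(c.center_id, m.replicon_id) for c in state.clusters for m in c.members}
            assert previous <= pairs
            previous = pairs

    def test_complete_and_mag_modes_agree_on_conforming_assembly(self, toy_db):
        from chromidfinder.classify import compute_profiles

        asm, _ = generate_assembly(GeneratorParams(seed=23))
        profiles, _ = compute_profiles(asm.replicons, toy_db)
        complete = classify_complete_genome(asm, profiles)
        mag = run_chromid_finder(asm.replicons, toy_db)
        assert complete.calls == mag.calls

    def test_chromid_evidence_contains_center_and_distance(self, toy_db):
        asm, _ = generate_assembly(GeneratorParams(seed=7))
        result = run_chromid_finder(asm.replicons, toy_db)
        chromid_id = asm.replicons[1].id
        evidence = " ".join(result.evidence[chromid_id])
        assert asm.replicons[0].id in evidence  # which center
        assert "tetra=" in evidence and "dGC=" in evidence  # which numbers

    def test_centers_never_called_chromid(self, toy_db):
        pool, _ = generate_benchmark(3, seed=41)
        result = run_chromid_finder(pool, toy_db)
        for cluster in result.clusters:
            assert result.calls[cluster.center_id] == CHROMOSOME


class TestThresholds:
    def test_invalid_values_rejected(self):
        with pytest.raises(errors.ValidationError):
            Thresholds(gc_delta_max=0)
        with pytest.raises(errors.ValidationError):
            Thresholds(marker_rule="loose")

    def test_rule_resolution_defaults(self):
        th = Thresholds()
        assert th.resolved_rule("complete_genome") == "strict"
        assert th.resolved_rule("mag") == "relaxed"
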