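"""Library designer: constraint checks, toy-scale oracles, determinism."""

import random

import pytest

from dpiscreen import (
    DesignConfig,
    DesignError,
    LibraryProbe,
    ProbeLibrary,
    check_pair_rule,
    check_segment,
    cut_masterstrand,
    design_library,
    find_ambiguities,
    validate_library,
)
from dpiscreen.design import _Books, build_masterstrand, greedy_complete

from .brute import brute_validate, canon, rc, windows


class TestCheckSegment:
    def test_duplicate_directed_hexamer(self):
        v = check_segment("TTGACCTTGACC", 6)
        assert any(c == 1 for c, *_ in v)

    def test_kmer_with_its_reverse_complement(self):
        # TTGACC at the start, GGTCAA at the end
        seg = "TTGACCAAGGTCAA"
        assert "GGTCAA" in windows(seg, 6) and "TTGACC" in windows(seg, 6)
        v = check_segment(seg, 6)
        assert any(c == 2 for c, *_ in v)

    def test_two_palindromic_windows(self):
        seg = "TGATCAGACGTC"
        v = check_segment(seg, 6)
        assert any(c == 4 for c, *_ in v)

    def test_short_and_clean_segments_pass(self):
        assert check_segment("ACG", 6) == []
        assert check_segment("ACGTAGGCTAACCTG", 6) == []


class TestPairRule:
    @staticmethod
    def lib(regions: dict[str, str], k: int = 6) -> ProbeLibrary:
        return ProbeLibrary(
            probes=[LibraryProbe(pid, seq, "loaded") for pid, seq in regions.items()],
            k=k,
        )

    def test_rc_pair_on_another_probe_is_flagged(self):
        m1, m2 = "TTGACC", "ACCTGA"
        p1 = "TTGACCTGA"  # m1 and m2 overlapping
        p2 = rc(p1)  # carries rc(m1) and rc(m2) together
        violations = check_pair_rule(self.lib({"P1": p1, "P2": p2}))
        assert any({a, b} == {"P1", "P2"} for a, b, *_ in violations)

    def test_single_probe_library_is_clean(self):
        assert check_pair_rule(self.lib({"P1": "TTGACCTGAAC"})) == []

    def test_brute_force_agreement_on_random_toys(self):
        rng = random.Random(0)
        for _ in range(20):
            regions = {
                f"P{i}": "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 12)))
                for i in range(4)
            }
            got = bool(check_pair_rule(self.lib(regions)))
            brute = brute_validate(
                regions, 6, 1, 99, 1, set(), 99
            )
            expected = any(f.startswith("pair-rule") for f in brute)
            assert got == expected


class TestMasterstrand:
    def test_paper_scale_strand_is_exact_length_with_clean_segments(
        self, default_library, default_config
    ):
        for ms in default_library.masterstrands:
            assert len(ms.sequence) == 1600
            for seg in cut_masterstrand(ms):
                assert 15 <= len(seg) <= 20
                assert check_segment(seg, 6) == []

    def test_single_probe_edge_case(self):
        cfg = DesignConfig(masterstrand_target_len=20, n_masterstrands=1, seed=0)
        books = _Books(6)
        ms, seg_ids = build_masterstrand(books, cfg, random.Random(0), 1)
        assert len(ms.sequence) == 20
        assert ms.cut_marks == []
        assert len(seg_ids) == 1

    def test_cut_round_trip(self, default_library):
        for ms in default_library.masterstrands:
            assert "".join(cut_masterstrand(ms)) == ms.sequence

    def test_same_seed_reproduces_strands(self):
        cfg = DesignConfig(masterstrand_target_len=100, n_masterstrands=1, seed=9)
        out = []
        for _ in range(2):
            books = _Books(6)
            ms, _ids = build_masterstrand(books, cfg, random.Random(9), 1)
            out.append(ms.sequence)
        assert out[0] == out[1]


class TestAmbiguities:
    def test_empty_library_misses_every_class(self):
        lib = ProbeLibrary(probes=[], k=2)
        report = find_ambiguities(lib, DesignConfig(k=2, min_probe_len=4,
                                                    max_probe_len=6))
        assert len(report.missing) == 10

    def test_identical_signatures_collide(self):
        # GGATCC and TTCGAA occur exactly in probes A and B
        lib = ProbeLibrary(
            probes=[
                LibraryProbe("A", "GGATCCATTCGAA", "loaded"),
                LibraryProbe("B", "GGATCCTTTCGAA", "loaded"),
            ],
            k=6,
        )
        report = find_ambiguities(lib, DesignConfig())
        flat = {m for group in report.collisions for m in group}
        assert canon("GGATCC") in flat and canon("TTCGAA") in flat

    def test_designed_library_report_is_empty(self, default_library, default_config):
        report = find_ambiguities(default_library, default_config)
        assert report.empty

    def test_completion_fixes_a_single_missing_motif(self, toy_config_k2):
        # drop one probe from a valid toy library and let completion repair it
        lib = design_library(toy_config_k2)
        books = _Books(2)
        probes = []
        for p in lib.probes[:-1]:
            books.open_probe(p.probe_id)
            for w in set(windows(p.variable_region, 2)):
                books.add_window(p.probe_id, w)
            probes.append(p)
        before = books.deficit
        if before == 0:
            pytest.skip("dropped probe carried no unique support")
        out = greedy_complete(books, list(probes), toy_config_k2, random.Random(1))
        assert books.deficit == 0
        assert len(out) > len(probes)


class TestDesignLibrary:
    def test_toy_k2_matches_brute_force_validator(self, toy_config_k2):
        lib = design_library(toy_config_k2)
        regions = {p.probe_id: p.variable_region for p in lib.probes}
        completion = {p.probe_id for p in lib.probes if p.source == "completion"}
        failures = brute_validate(
            regions,
            k=2,
            min_len=toy_config_k2.min_probe_len,
            max_len=toy_config_k2.max_probe_len,
            min_completion_len=toy_config_k2.min_completion_probe_len,
            completion_ids=completion,
            max_probes=toy_config_k2.max_library_probes,
        )
        assert failures == []

    def test_toy_k3_matches_brute_force_validator(self, toy_config_k3):
        lib = design_library(toy_config_k3)
        regions = {p.probe_id: p.variable_region for p in lib.probes}
        completion = {p.probe_id for p in lib.probes if p.source == "completion"}
        failures = brute_validate(
            regions,
            k=3,
            min_len=toy_config_k3.min_probe_len,
            max_len=toy_config_k3.max_probe_len,
            min_completion_len=toy_config_k3.min_completion_probe_len,
            completion_ids=completion,
            max_probes=toy_config_k3.max_library_probes,
        )
        assert failures == []

    def test_same_seed_gives_byte_identical_library(self, tmp_path, toy_config_k3):
        paths = []
        for i in range(2):
            lib = design_library(toy_config_k3)
            path = tmp_path / f"lib{i}.tsv"
            lib.to_tsv(path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_different_seeds_give_different_libraries(self, toy_config_k3):
        import dataclasses

        other = dataclasses.replace(toy_config_k3, seed=toy_config_k3.seed + 1)
        a = design_library(toy_config_k3)
        b = design_library(other)
        assert [p.variable_region for p in a.probes] != [
            p.variable_region for p in b.probes
        ]

    def test_impossible_budget_raises(self):
        cfg = DesignConfig(seed=0, well_budget=40, n_control_wells=32,
                           masterstrand_target_len=100, n_masterstrands=1,
                           max_restarts=2)
        with pytest.raises(DesignError):
            design_library(cfg)


class TestValidateLibrary:
    def test_designed_library_passes(self, default_library, default_config):
        report = validate_library(default_library, default_config)
        assert report.passed, report.failures()

    def test_truncated_probe_fails_length_bound(self, toy_config_k3):
        lib = design_library(toy_config_k3)
        lib.probes[0].variable_region = lib.probes[0].variable_region[:3]
        report = validate_library(lib, toy_config_k3)
        assert not report.passed
        assert any(pid == lib.probes[0].probe_id for pid, _ in
                   report.length_violations)

    def test_validator_agrees_with_brute_force_on_corruption(self, toy_config_k2):
        lib = design_library(toy_config_k2)
        # two copies of one probe: every shared class has signature {P,DUP}
        first = lib.probes[0]
        dup = LibraryProbe("DUP", first.variable_region, "loaded")
        bad = ProbeLibrary(probes=[first, dup], k=2)
        report = validate_library(bad, toy_config_k2)
        regions = {p.probe_id: p.variable_region for p in bad.probes}
        brute = brute_validate(regions, 2, 4, 6, 3, set(), 44)
        assert not report.passed
        assert report.collisions, "identical probes must collide"
        assert any(f.startswith("collision") for f in brute)
        assert report.uncovered and any(f.startswith("coverage") for f in brute)

    def test_round_trip_through_tsv(self, tmp_path, toy_config_k3):
        lib = design_library(toy_config_k3)
        path = tmp_path / "lib.tsv"
        lib.to_tsv(path)
        loaded = ProbeLibrary.from_tsv(path, k=3)
        assert validate_library(loaded, toy_config_k3).passed
        assert [p.variable_region for p in loaded.probes] == [
            p.variable_region for p in lib.probes
        ]
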