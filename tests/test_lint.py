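"""Defect detectors: each against hand-built fixtures whose expected
verdicts were worked out by hand."""

import pytest

from keylint.lint import (
    AmbiguityLexicon,
    detect_ambiguity,
    detect_illustration_coverage,
    detect_leapfrog,
    detect_monothetic,
    detect_numbering_errors,
    detect_parallel_and_contrast,
    detect_retracing,
    detect_style,
    lint_key,
    subject_token,
)
from keylint.model import Key
from keylint.simulate import generate_topology

from conftest import comb_key, couplet, lead


def key_of(*couplets, **kw):
    return Key(key_id=kw.pop("key_id", "k"), couplets=list(couplets), **kw)


class TestLeapfrog:
    def test_inverted_continuation_flagged(self, example_report):
        ds = detect_leapfrog(example_report.key)
        assert [d.couplet_number for d in ds] == [3]

    def test_standard_ordering_not_flagged(self):
        k = key_of(
            couplet(3, lead(1, ["a"], 4), lead(2, ["b"], 9)),
            couplet(4, lead(1, ["c"], "Genus A"), lead(2, ["d"], 9)),
            couplet(9, lead(1, ["e"], "Genus B"), lead(2, ["f"], "Genus C")),
        )
        assert detect_leapfrog(k) == []

    def test_terminal_leads_not_eligible(self):
        k = key_of(couplet(1, lead(1, ["a"], "Genus A"), lead(2, ["b"], "Genus B")))
        assert detect_leapfrog(k) == []


class TestRetracing:
    def test_consistent_refs_supported(self):
        supported, ds = detect_retracing(comb_key(6))
        assert supported is True and ds == []

    def test_absent_refs_in_branching_key_unsupported(self):
        k = generate_topology(10, 1, 0, retracing=False)
        supported, ds = detect_retracing(k)
        assert supported is False and ds == []

    def test_two_couplet_key_not_applicable(self):
        supported, ds = detect_retracing(comb_key(3, retrace=False))
        assert supported is None and ds == []

    def test_mismatched_ref_is_numbering_error(self):
        # couplet 7 claims it was reached from 3, but 3 targets 4 and 9
        k = key_of(
            couplet(3, lead(1, ["a"], 4), lead(2, ["b"], 9)),
            couplet(4, lead(1, ["c"], "Genus A"), lead(2, ["d"], 7), retrace=3),
            couplet(7, lead(1, ["e"], "Genus B"), lead(2, ["f"], 9), retrace=3),
            couplet(9, lead(1, ["g"], "Genus C"), lead(2, ["h"], "Genus D"), retrace=7),
        )
        _, ds = detect_retracing(k)
        assert any(d.category == "numbering-error" and d.couplet_number == 7 for d in ds)

    def test_strict_mode_requires_every_ref(self):
        supported, _ = detect_retracing(comb_key(6, retrace=False), strict=True)
        assert supported is False


class TestNumbering:
    def test_consecutive_numbers_clean(self):
        assert detect_numbering_errors(comb_key(8)) == []

    def test_duplicate_and_gap(self):
        k = key_of(
            couplet(1, lead(1, ["a"], "Genus A"), lead(2, ["b"], 2)),
            couplet(2, lead(1, ["c"], "Genus B"), lead(2, ["d"], 4)),
            couplet(2, lead(1, ["e"], "Genus C"), lead(2, ["f"], "Genus D")),
            couplet(4, lead(1, ["g"], "Genus E"), lead(2, ["h"], "Genus F")),
        )
        cats = [d.category for d in detect_numbering_errors(k)]
        assert "numbering-error" in cats and "missing-numbers" in cats

    def test_backward_reference_is_cycle(self):
        k = key_of(
            couplet(1, lead(1, ["a"], "Genus A"), lead(2, ["b"], 2)),
            couplet(2, lead(1, ["c"], "Genus B"), lead(2, ["d"], 3)),
            couplet(3, lead(1, ["e"], "Genus C"), lead(2, ["f"], 2)),
        )
        ds = detect_numbering_errors(k)
        assert any(d.category == "numbering-error" and "cycle" in d.message for d in ds)


class TestMonothetic:
    def test_multi_feature_couplet_not_monothetic(self, example_report):
        per, prop, _ = detect_monothetic(example_report.key)
        assert per == {3: False} and prop == 0.0

    def test_single_feature_couplet_monothetic(self):
        k = key_of(couplet(1, lead(1, ["Wings present"], "Genus A"), lead(2, ["Wings absent"], "Genus B")))
        per, prop, all_hit = detect_monothetic(k)
        assert per == {1: True} and prop == 1.0 and all_hit is True

    def test_monothetic_root_hits_every_path(self):
        k = comb_key(5)
        # root has one feature per lead already (comb_key builds single-feature leads)
        per, prop, all_hit = detect_monothetic(k)
        assert per[1] is True and all_hit is True

    def test_paths_missed_when_monothetic_couplet_off_path(self):
        k = key_of(
            couplet(1, lead(1, ["a", "b"], 2), lead(2, ["c", "d"], 3)),
            couplet(2, lead(1, ["e", "f"], "Genus A"), lead(2, ["g", "h"], "Genus B"), retrace=1),
            couplet(3, lead(1, ["i"], "Genus C"), lead(2, ["j"], "Genus D"), retrace=1),
        )
        per, prop, all_hit = detect_monothetic(k)
        assert per == {1: False, 2: False, 3: True}
        assert prop == pytest.approx(1 / 3)
        assert all_hit is False


class TestParallelAndContrast:
    def test_parallel_contrasted_clean(self):
        c = couplet(1, lead(1, ["Head long", "tibia spined"], "Genus A"), lead(2, ["Head short", "tibia unspined"], "Genus B"))
        assert detect_parallel_and_contrast(c) == []
        assert all(f.is_contrasted for ld in c.leads for f in ld.features)

    def test_non_parallel_order(self):
        c = couplet(1, lead(1, ["Head long", "tibia spined"], "Genus A"), lead(2, ["tibia unspined", "Head short"], "Genus B"))
        ds = detect_parallel_and_contrast(c)
        assert [d.category for d in ds] == ["non-parallel-features"]

    def test_uncontrasted_feature(self):
        c = couplet(1, lead(1, ["Head long", "wing dark"], "Genus A"), lead(2, ["Head short"], "Genus B"))
        ds = detect_parallel_and_contrast(c)
        assert len(ds) == 1
        d = ds[0]
        assert d.category == "uncontrasted-feature" and d.lead_ordinal == 1
        assert not c.leads[0].features[1].is_contrasted

    def test_no_shared_subject_blocks_comparison(self):
        c = couplet(1, lead(1, ["Head long"], "Genus A"), lead(2, ["wing dark"], "Genus B"))
        ds = detect_parallel_and_contrast(c)
        assert any(d.lead_ordinal is None for d in ds if d.category == "uncontrasted-feature")

    def test_subject_skips_qualifiers(self):
        assert subject_token("usually head wider") == "head"
        assert subject_token("the strongly convex pronotum") == "convex"


class TestAmbiguity:
    def test_overlapping_ranges_flagged(self):
        c = couplet(1, lead(1, ["body length 9–12 mm"], "Genus A"), lead(2, ["body length 11–15 mm"], "Genus B"))
        ds = detect_ambiguity(c)
        assert any("overlapping-range" in f.ambiguity_flags for ld in c.leads for f in ld.features)
        assert any(d.category == "fully-indecisive-couplet" for d in ds)

    def test_disjoint_ranges_clean(self):
        c = couplet(1, lead(1, ["body length 9–12 mm"], "Genus A"), lead(2, ["body length 13–15 mm"], "Genus B"))
        assert detect_ambiguity(c) == []

    def test_relative_statement_resolved_by_illustration(self):
        c = couplet(
            1,
            lead(1, ["surface strongly convex"], "Genus A", figs=["Fig. 3A"]),
            lead(2, ["surface weakly convex"], "Genus B", figs=["Fig. 3B"]),
        )
        assert detect_ambiguity(c) == []
        # same wording without figures is flagged
        c2 = couplet(1, lead(1, ["surface strongly convex"], "Genus A"), lead(2, ["surface weakly convex"], "Genus B"))
        ds = detect_ambiguity(c2)
        assert any(d.category == "unresolved-relative-statement" for d in ds)

    def test_qualifier_not_cured_by_illustration(self):
        c = couplet(
            1,
            lead(1, ["punctures usually dense", "head long"], "Genus A", figs=["Fig. 1"]),
            lead(2, ["punctures sparse", "head short"], "Genus B", figs=["Fig. 2"]),
        )
        ds = detect_ambiguity(c)
        assert [d.category for d in ds] == ["indecisive-feature"]
        assert "qualifier-word" in c.leads[0].features[0].ambiguity_flags

    def test_quantified_relative_not_flagged(self):
        c = couplet(
            1,
            lead(1, ["ocellar distance wide, 2× ocellar diameter"], "Genus A"),
            lead(2, ["ocellar distance 1.2× ocellar diameter"], "Genus B"),
        )
        assert detect_ambiguity(c) == []

    def test_bare_comparative_without_standard_flagged(self):
        c = couplet(1, lead(1, ["ocellar distance wide"], "Genus A"), lead(2, ["ocellar distance narrower"], "Genus B"))
        ds = detect_ambiguity(c)
        assert any("implied-alternative" in f.ambiguity_flags for f in c.leads[1].features)
        # "longer than wide" carries its own standard
        c2 = couplet(1, lead(1, ["head longer than wide"], "Genus A"), lead(2, ["head as long as wide"], "Genus B"))
        assert detect_ambiguity(c2) == []

    def test_custom_lexicon(self):
        lex = AmbiguityLexicon(qualifier_words=("habitually",), relative_markers=("vaguely",))
        c = couplet(1, lead(1, ["setae habitually dense"], "Genus A"), lead(2, ["setae sparse"], "Genus B"))
        assert any(d.category == "indecisive-feature" for d in detect_ambiguity(c, lex))
        assert detect_ambiguity(c) == []  # default lexicon has no such word


class TestStyleAndCoverage:
    def test_polychotomy_and_duplicate_taxon(self):
        k = key_of(
            couplet(
                1,
                lead(1, ["a"], "Genus A"),
                lead(2, ["b"], 2),
                lead(3, ["c"], "Genus B"),
            ),
            couplet(2, lead(1, ["d"], "Genus A"), lead(2, ["e"], "Genus C")),
        )
        cats = [d.category for d in detect_style(k)]
        assert "polychotomy" in cats and "duplicate-taxon" in cats

    def test_looped_couplet(self):
        k = key_of(
            couplet(1, lead(1, ["a"], 2), lead(2, ["b"], 3)),
            couplet(2, lead(1, ["c"], "Genus A"), lead(2, ["d"], 3)),
            couplet(3, lead(1, ["e"], "Genus B"), lead(2, ["f"], "Genus C")),
        )
        ds = [d for d in detect_style(k) if d.category == "looped"]
        assert [d.couplet_number for d in ds] == [3]

    def test_multi_taxon_lead(self):
        k = key_of(couplet(1, lead(1, ["a"], "Genus A and Genus B"), lead(2, ["b"], "Genus C")))
        assert any(d.category == "multi-taxon-lead" for d in detect_style(k))

    def test_illustration_coverage_classes(self):
        none_key = comb_key(4)
        assert detect_illustration_coverage(none_key) == (0.0, "none")
        k = key_of(
            couplet(1, lead(1, ["a"], "Genus A", figs=["Fig. 1"]), lead(2, ["b"], 2)),
            couplet(2, lead(1, ["c"], "Genus B", figs=["Fig. 2"]), lead(2, ["d"], "Genus C")),
        )
        prop, cls = detect_illustration_coverage(k)
        assert prop == pytest.approx(0.5) and cls == "partial"
        full = generate_topology(6, 1, 0, illustration_rate=1.0)
        assert detect_illustration_coverage(full) == (1.0, "all-leads")


def test_lint_is_deterministic():
    k = generate_topology(20, 0.4, 7)
    assert lint_key(k) == lint_key(k)
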