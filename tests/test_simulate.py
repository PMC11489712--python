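"""Generator contracts: topology endpoints, seed determinism, labelled
injection validity, and corpus prevalence."""

import numpy as np
import pytest

from keylint.lint import detect_monothetic, lint_key
from keylint.metrics import compute_metrics
from keylint.model import build_graph
from keylint.parser import render_key
from keylint.simulate import (
    FEATURE_BANK,
    GroupSpec,
    KeyGenConfig,
    generate_corpus,
    generate_key,
    generate_topology,
    inject_defects,
)
from keylint.stats import pearson_chi_square, proportions_by_group


class TestTopology:
    @pytest.mark.parametrize("n", [4, 6, 16, 33, 128])
    def test_comb_endpoint(self, n):
        m = compute_metrics(generate_topology(n, 0.0, 1))
        assert m.s_actual == pytest.approx(m.s_max, abs=1e-9)

    @pytest.mark.parametrize("n", [4, 6, 16, 33, 128])
    def test_fan_endpoint(self, n):
        m = compute_metrics(generate_topology(n, 1.0, 1))
        assert m.s_actual == pytest.approx(m.s_min, abs=1e-9)
        assert m.is_max_fan

    def test_seed_determinism_byte_identical(self):
        cfg = dict(n_taxa=20, balance=0.5, seed=42, illustration_rate=0.4)
        a = render_key(generate_topology(**cfg))
        b = render_key(generate_topology(**cfg))
        assert a == b
        c = render_key(generate_topology(20, 0.5, 43, illustration_rate=0.4))
        assert c != a

    def test_preorder_numbering_and_taxon_names(self):
        k = generate_topology(10, 0.5, 0)
        assert k.numbers == list(range(1, len(k.couplets) + 1))
        assert k.taxa() == [f"genus_{i:03d}" for i in range(1, 11)]

    def test_clean_keys_have_no_syntactic_defects(self):
        bad_cats = {
            "leap-frog",
            "numbering-error",
            "missing-numbers",
            "polychotomy",
            "looped",
            "unreachable-couplet",
            "dangling-reference",
            "uncontrasted-feature",
            "indecisive-feature",
            "fully-indecisive-couplet",
            "non-parallel-features",
            "unresolved-relative-statement",
            "monothetic-couplet",
            "duplicate-taxon",
        }
        for seed in range(30):
            k = generate_topology(2 + seed, (seed % 6) / 5, seed)
            assert [d for d in lint_key(k) if d.category in bad_cats] == []

    def test_rejects_bad_config(self):
        with pytest.raises(ValueError):
            generate_topology(1, 0.5, 0)
        with pytest.raises(ValueError):
            KeyGenConfig(n_taxa=5, balance=1.5)
        with pytest.raises(ValueError):
            KeyGenConfig(n_taxa=5, defect_rates={"leap-frog": 1.2})


class TestInjection:
    def test_single_leapfrog_found_exactly(self):
        key = generate_topology(12, 0.3, 5)
        cfg = KeyGenConfig(n_taxa=12, balance=0.3, seed=5, defect_rates={"leap-frog": 1})
        injected, gt = inject_defects(key, cfg)
        loci = [(c, n) for c, n, _ in gt.injected_defects]
        assert loci and loci[0][0] == "leap-frog"
        found = [d for d in lint_key(injected) if d.category == "leap-frog"]
        assert [d.couplet_number for d in found] == [loci[0][1]]

    def test_monothetic_rate_one(self):
        cfg = KeyGenConfig(n_taxa=8, balance=0.5, seed=2, defect_rates={"monothetic": 1.0})
        key, gt = generate_key(cfg)
        _, prop, _ = detect_monothetic(key)
        assert prop == 1.0

    def test_injection_loci_exist_in_key(self):
        cfg = KeyGenConfig(
            n_taxa=20,
            balance=0.5,
            seed=9,
            defect_rates={
                "leap-frog": 1,
                "numbering-error": 1,
                "polychotomy": 1,
                "looped": 1,
                "monothetic": 2,
                "qualifier-word": 2,
                "uncontrasted": 1,
                "duplicate-taxon": 1,
            },
        )
        key, gt = generate_key(cfg)
        numbers = {c.number for c in key.couplets}
        assert gt.injected_defects
        for cat, cnum, lead_ord in gt.injected_defects:
            assert cnum in numbers
        assert gt.true_metrics is not None
        assert gt.true_metrics.s_actual is not None

    def test_looped_injection_reachable_twice(self):
        cfg = KeyGenConfig(n_taxa=15, balance=0.5, seed=3, defect_rates={"looped": 1})
        key, gt = generate_key(cfg)
        target = next(n for c, n, _ in gt.injected_defects if c == "looped")
        g = build_graph(key)
        assert target in g.extra_parents

    def test_injection_determinism(self):
        cfg = KeyGenConfig(n_taxa=18, balance=0.4, seed=7, defect_rates={"leap-frog": 1, "qualifier-word": 2})
        k1, g1 = generate_key(cfg)
        k2, g2 = generate_key(cfg)
        assert k1 == k2
        assert g1.injected_defects == g2.injected_defects


class TestCorpus:
    def test_prevalence_one_and_zero(self):
        corpus = generate_corpus(60, [GroupSpec("All", 1.0), GroupSpec("None", 0.0)], 4)
        tab = proportions_by_group(corpus, "order", pool_threshold=0)
        props = dict(zip(tab["group"], tab["prop"]))
        assert props["All"] == 1.0
        assert props["None"] == 0.0

    def test_configured_prevalence_within_binomial_ci(self):
        """Observed per-group key proportions stay inside the 99% binomial
        band around their configured probabilities."""
        specs = [GroupSpec("Coleoptera", 0.47), GroupSpec("Lepidoptera", 0.053)]
        corpus = generate_corpus(2000, specs, 11)
        tab = proportions_by_group(corpus, "order", pool_threshold=0)
        for spec in specs:
            row = tab[tab["group"] == spec.name].iloc[0]
            n = row["n_papers"]
            se = np.sqrt(spec.key_prob * (1 - spec.key_prob) / n)
            assert abs(row["prop"] - spec.key_prob) < 2.58 * se + 1e-9

    def test_power_against_distinct_prevalences(self):
        """With prevalences 0.05 vs 0.47 and 200 papers per group, the
        chi-square test rejects at alpha = 0.05 in at least 95% of corpora."""
        rejections = 0
        n_sim = 200
        specs = [GroupSpec("A", 0.05), GroupSpec("B", 0.47)]
        for s in range(n_sim):
            corpus = generate_corpus(400, specs, 1000 + s)
            tab = proportions_by_group(corpus, "order", pool_threshold=0)
            counts = np.column_stack([tab["n_with_key"], tab["n_papers"] - tab["n_with_key"]])
            _, _, p = pearson_chi_square(counts)
            rejections += p < 0.05
        assert rejections / n_sim >= 0.95

    def test_corpus_seed_determinism(self):
        specs = [GroupSpec("A", 0.3)]
        assert generate_corpus(50, specs, 8) == generate_corpus(50, specs, 8)


def test_feature_bank_subjects_unique_and_clean():
    subjects = [p[0].split()[0] for p in FEATURE_BANK]
    assert len(subjects) == len(set(subjects))
    for a, b in FEATURE_BANK:
        assert a.split()[0] == b.split()[0]  # contrasted pair shares its subject
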