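"""Synthetic keys and corpora with known ground truth.

Published keys cannot be redistributed, and the defects of interest are rare
enough in any small sample that detector testing needs controlled material.
This module generates:

* random key topologies spanning the comb↔fan continuum, with couplets
  worded from a bank of contrasted morphological phrase pairs in the
  conventional style ("Head longer than wide" / "Head shorter than wide"),
  pre-order numbering, retrace references and optional figure citations —
  clean by construction, so any defect a detector reports on them is a false
  positive;
* labelled defect injection: each injected defect is recorded with its locus
  in a :class:`GroundTruth`, giving detectors an exact recall/precision
  target;
* corpus metadata tables with configured per-group key prevalence, for the
  group-comparison statistics.

Everything is driven by an integer seed; identical configuration yields
byte-identical output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .metrics import compute_metrics
from .model import Couplet, Defect, Feature, Key, KeyGraph, KeyMetrics, KeyScope, Lead, PaperMetadata

__all__ = [
    "KeyGenConfig",
    "GroundTruth",
    "GroupSpec",
    "FEATURE_BANK",
    "generate_topology",
    "inject_defects",
    "generate_key",
    "generate_corpus",
]

#: Bank of contrasted feature pairs.  Each pair shares a unique subject
#: (first content word) so contrast pairing is unambiguous, and the phrasing
#: is deliberately clean: no qualifier words, no bare comparatives without
#: "than", no numeric ranges.
FEATURE_BANK = (
    ("head longer than wide", "head shorter than wide"),
    ("antenna with twelve segments", "antenna with thirteen segments"),
    ("pronotum densely punctate", "pronotum smooth and shining"),
    ("wings fully developed", "wings reduced to small pads"),
    ("eyes prominent, bulging", "eyes flat, not bulging"),
    ("mandibles bidentate apically", "mandibles simple apically"),
    ("scutellum flat", "scutellum convex"),
    ("abdomen petiolate", "abdomen sessile"),
    ("legs pale yellow", "legs dark brown to black"),
    ("tarsi pentamerous", "tarsi tetramerous"),
    ("clypeus emarginate medially", "clypeus truncate medially"),
    ("mesopleuron carinate", "mesopleuron smooth"),
    ("propodeum areolate", "propodeum rugose"),
    ("tegula glabrous", "tegula setose"),
    ("ocelli present", "ocelli absent"),
    ("forewing with two submarginal cells", "forewing with three submarginal cells"),
    ("hindwing with jugal lobe", "hindwing lacking jugal lobe"),
    ("metasoma red basally", "metasoma entirely black"),
    ("frons with median carina", "frons without median carina"),
    ("vertex punctate", "vertex impunctate"),
)

#: Default qualifier word used when injecting indecisive features.
INJECT_QUALIFIER = "usually"

SYNTACTIC_CATEGORIES = ("leap-frog", "numbering-error", "polychotomy", "looped")
WORDING_CATEGORIES = ("monothetic-couplet", "indecisive-feature", "uncontrasted-feature")


@dataclass
class KeyGenConfig:
    """Configuration for a synthetic key.

    ``balance`` interpolates between the caterpillar comb (0) and the
    balanced fan (1); ``defect_rates`` maps a defect category to either an
    integer count (exactly that many injections, eligibility permitting) or
    a probability in [0, 1) applied per eligible site.
    """

    n_taxa: int = 12
    balance: float = 0.5
    seed: int = 0
    defect_rates: dict = field(default_factory=dict)
    illustration_rate: float = 0.0
    retracing: bool = True
    feature_count_range: tuple = (2, 3)

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be at least 2")
        if not 0 <= self.balance <= 1:
            raise ValueError("balance must lie in [0, 1]")
        if not 0 <= self.illustration_rate <= 1:
            raise ValueError("illustration_rate must lie in [0, 1]")
        lo, hi = self.feature_count_range
        if not (1 <= lo <= hi <= len(FEATURE_BANK)):
            raise ValueError("feature_count_range out of range")
        for cat, rate in self.defect_rates.items():
            if isinstance(rate, float) and not 0 <= rate <= 1:
                raise ValueError(f"rate for {cat} must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Labelled injection record: every defect placed into a key, with its
    locus, plus the metrics of the clean topology it was derived from."""

    injected_defects: list = field(default_factory=list)  # (category, couplet, lead or None)
    true_metrics: Optional[KeyMetrics] = None


def _split_sizes(m: int, balance: float, rng: np.random.Generator) -> int:
    """Left-subtree size for ``m`` taxa.

    balance 0 → 1 (comb: one taxon keys out, the rest continue);
    balance 1 → ⌊m/2⌋ (fan: as even as possible); in between, a binomial
    draw on 1..⌊m/2⌋ — monotone in balance with exact endpoints.
    """
    half = m // 2
    if balance <= 0 or half == 1:
        return 1
    if balance >= 1:
        return half
    return 1 + int(rng.binomial(half - 1, balance))


def generate_topology(
    n_taxa: int,
    balance: float,
    seed: int,
    retracing: bool = True,
    illustration_rate: float = 0.0,
    feature_count_range: tuple = (2, 3),
    key_id: Optional[str] = None,
    title: str = "",
) -> Key:
    """Generate a clean dichotomous key over ``n_taxa`` taxa.

    Couplets are numbered in pre-order so the first onward lead of every
    couplet continues to the immediately following couplet (no leap-frog by
    construction); taxa are named ``Genus_001`` onward; leads are worded from
    :data:`FEATURE_BANK` in matching order (parallel and contrasted).
    """
    cfg = KeyGenConfig(
        n_taxa=n_taxa,
        balance=balance,
        seed=seed,
        illustration_rate=illustration_rate,
        retracing=retracing,
        feature_count_range=feature_count_range,
    )
    rng = np.random.default_rng(seed)

    # recursive topology: a node is either ('leaf', taxon_index) or
    # ('node', left, right, size)
    counter = [0]

    def build(m: int):
        if m == 1:
            counter[0] += 1
            return ("leaf", counter[0])
        k = _split_sizes(m, balance, rng)
        left = build(k)
        right = build(m - k)
        return ("node", left, right, m)

    root = build(n_taxa)

    couplets: list = []
    fig_counter = [0]
    lo, hi = feature_count_range

    def word_couplet(number: int, retrace: Optional[int]):
        k = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(FEATURE_BANK), size=k, replace=False)
        f1 = [FEATURE_BANK[i][0] for i in idx]
        f2 = [FEATURE_BANK[i][1] for i in idx]
        f1[0] = f1[0][0].upper() + f1[0][1:]
        f2[0] = f2[0][0].upper() + f2[0][1:]
        return f1, f2

    def figrefs():
        if illustration_rate > 0 and rng.random() < illustration_rate:
            fig_counter[0] += 1
            return [f"Fig. {fig_counter[0]}"]
        return []

    def size(node):
        return 1 if node[0] == "leaf" else node[3]

    def emit(node, parent_number: Optional[int]) -> int:
        """Emit the couplet for an internal node; returns its number."""
        number = len(couplets) + 1
        couplets.append(None)  # placeholder, filled after children are numbered
        _, left, right, _ = node
        # order leads so that an internal child, if any, sits where its
        # pre-order number is the successor: internal-left first; if only the
        # right child is internal it still gets number+1 because the leaf
        # left child consumes no couplet
        f1, f2 = word_couplet(number, parent_number)
        leads = []

        def lead_for(ordinal, child, feats):
            if child[0] == "leaf":
                return Lead(
                    ordinal=ordinal,
                    features=[Feature(t) for t in feats],
                    target_taxon=f"Genus_{child[1]:03d}",
                    figure_refs=figrefs(),
                )
            target = emit(child, number)
            return Lead(
                ordinal=ordinal,
                features=[Feature(t) for t in feats],
                target_couplet=target,
                figure_refs=figrefs(),
            )

        # children must be emitted left-to-right *after* reserving this
        # number, and the left subtree is emitted before the right so
        # pre-order numbering holds
        l1 = lead_for(1, left, f1)
        l2 = lead_for(2, right, f2)
        leads = [l1, l2]
        couplets[number - 1] = Couplet(
            number=number,
            leads=leads,
            retrace_ref=(parent_number if (retracing and parent_number is not None) else None),
        )
        return number

    emit(root, None)
    kid = key_id or f"sim-n{n_taxa}-b{balance:g}-s{seed}"
    return Key(
        key_id=kid,
        title=title or f"Key to the genera of the synthetic family ({n_taxa} genera)",
        couplets=couplets,
        scope=KeyScope(group_rank="tribe", extent="global"),
    )


def _count(rate, n_eligible: int, rng: np.random.Generator) -> int:
    if isinstance(rate, bool):
        return int(rate)
    if isinstance(rate, (int, np.integer)):
        return min(int(rate), n_eligible)
    return int(rng.binomial(n_eligible, float(rate)))


def inject_defects(key: Key, config: KeyGenConfig):
    """Inject labelled defects into a copy of ``key``.

    Returns ``(defective_key, ground_truth)``.  Injection sites for
    different categories are kept disjoint so every ground-truth locus is
    attributable to exactly one injection.  Structure-changing injections
    are sequenced (numbering → leap-frog → polychotomy → loop) with
    eligibility recomputed at each step so they do not mask one another.
    """
    key = copy.deepcopy(key)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7341]))
    gt = GroundTruth(injected_defects=[], true_metrics=None)
    rates = dict(config.defect_rates)
    claimed: set = set()  # couplet numbers already used by any injection

    def pick(eligible, want):
        pool = [c for c in eligible if c not in claimed]
        if not pool or want <= 0:
            return []
        take = min(want, len(pool))
        chosen = [pool[i] for i in rng.choice(len(pool), size=take, replace=False)]
        claimed.update(chosen)
        return chosen

    by_number = {c.number: c for c in key.couplets}

    # --- monothetic: strip both leads down to their first feature
    if "monothetic" in rates:
        eligible = [c.number for c in key.couplets if any(len(ld.features) > 1 for ld in c.leads)]
        for num in pick(eligible, _count(rates["monothetic"], len(eligible), rng)):
            for ld in by_number[num].leads:
                ld.features = ld.features[:1]
            gt.injected_defects.append(("monothetic-couplet", num, None))

    # --- qualifier word: make one feature indecisive
    if "qualifier-word" in rates:
        eligible = [c.number for c in key.couplets]
        for num in pick(eligible, _count(rates["qualifier-word"], len(eligible), rng)):
            ld = by_number[num].leads[int(rng.integers(0, 2))]
            f = ld.features[int(rng.integers(0, len(ld.features)))]
            words = f.text.split()
            words.insert(1, INJECT_QUALIFIER)
            f.text = " ".join(words)
            gt.injected_defects.append(("indecisive-feature", num, ld.ordinal))

    # --- uncontrasted: append a feature with a subject absent from the couplet
    if "uncontrasted" in rates:
        eligible = [c.number for c in key.couplets]
        for num in pick(eligible, _count(rates["uncontrasted"], len(eligible), rng)):
            c = by_number[num]
            used = {f.text.split()[0].lower() for ld in c.leads for f in ld.features}
            bank = [p for p in FEATURE_BANK if p[0].split()[0] not in used]
            if not bank:
                claimed.discard(num)
                continue
            pair = bank[int(rng.integers(0, len(bank)))]
            ld = c.leads[int(rng.integers(0, 2))]
            ld.features.append(Feature(pair[0]))
            gt.injected_defects.append(("uncontrasted-feature", num, ld.ordinal))

    # --- duplicate taxon: rename one terminal to an existing name
    if "duplicate-taxon" in rates:
        terminals = [
            (c.number, ld)
            for c in key.couplets
            for ld in c.leads
            if ld.is_terminal and c.number not in claimed
        ]
        names = sorted({ld.target_taxon for _, ld in terminals})
        want = _count(rates["duplicate-taxon"], len(terminals), rng)
        if want > 0 and len(names) >= 2:
            for _ in range(want):
                pool = [(n, ld) for n, ld in terminals if n not in claimed]
                if not pool:
                    break
                num, ld = pool[int(rng.integers(0, len(pool)))]
                other = [nm for nm in names if nm != ld.target_taxon]
                ld.target_taxon = other[int(rng.integers(0, len(other)))]
                claimed.add(num)
                gt.injected_defects.append(("duplicate-taxon", num, ld.ordinal))

    # --- numbering error: renumber a both-taxa couplet to duplicate an
    # earlier number (duplicate + gap + one dangling incoming reference)
    if "numbering-error" in rates:
        eligible = [
            c.number
            for c in key.couplets
            if c.number != key.couplets[0].number and all(ld.is_terminal for ld in c.leads)
        ]
        for num in pick(eligible, _count(rates["numbering-error"], len(eligible), rng)):
            c = by_number[num]
            earlier = [m for m in by_number if m < num and m not in claimed]
            if not earlier:
                continue
            new_number = int(earlier[int(rng.integers(0, len(earlier)))])
            claimed.add(new_number)
            c.number = new_number
            gt.injected_defects.append(("numbering-error", new_number, None))

    # --- leap-frog: swap the leads of a couplet whose first lead continues
    # to the numeric successor and whose second jumps elsewhere
    if "leap-frog" in rates:
        eligible = []
        for c in key.couplets:
            if c.number in claimed or not c.is_dichotomous:
                continue
            l1, l2 = c.leads
            if (
                not l1.is_terminal
                and not l2.is_terminal
                and l1.target_couplet == c.number + 1
                and l2.target_couplet != c.number + 1
            ):
                eligible.append(c.number)
        for num in pick(eligible, _count(rates["leap-frog"], len(eligible), rng)):
            c = next(cc for cc in key.couplets if cc.number == num)
            c.leads[0], c.leads[1] = c.leads[1], c.leads[0]
            c.leads[0].ordinal, c.leads[1].ordinal = 1, 2
            gt.injected_defects.append(("leap-frog", num, None))

    # --- polychotomy: add a third lead keying out a fresh taxon
    if "polychotomy" in rates:
        eligible = [c.number for c in key.couplets if c.number not in claimed and c.is_dichotomous]
        extra = 0
        for num in pick(eligible, _count(rates["polychotomy"], len(eligible), rng)):
            c = next(cc for cc in key.couplets if cc.number == num)
            used = {f.text.split()[0].lower() for ld in c.leads for f in ld.features}
            bank = [p for p in FEATURE_BANK if p[0].split()[0] not in used] or list(FEATURE_BANK)
            pair = bank[int(rng.integers(0, len(bank)))]
            extra += 1
            c.leads.append(
                Lead(
                    ordinal=len(c.leads) + 1,
                    features=[Feature(pair[0][0].upper() + pair[0][1:])],
                    target_taxon=f"Genus_X{extra:02d}",
                )
            )
            gt.injected_defects.append(("polychotomy", num, None))

    # --- looped: redirect a second-lead terminal onto a later couplet,
    # giving that couplet two parents without creating a cycle or a
    # leap-frog pattern
    if "looped" in rates:
        numbers = sorted(c.number for c in key.couplets)
        eligible = []
        for c in key.couplets:
            if c.number in claimed or not c.is_dichotomous:
                continue
            l2 = c.leads[1]
            later = [m for m in numbers if m > c.number + 1 and m not in claimed]
            if l2.is_terminal and later:
                eligible.append(c.number)
        for num in pick(eligible, _count(rates["looped"], len(eligible), rng)):
            c = next(cc for cc in key.couplets if cc.number == num)
            later = [m for m in numbers if m > c.number + 1 and m not in claimed]
            if not later:
                continue
            target = int(later[int(rng.integers(0, len(later)))])
            claimed.add(target)
            l2 = c.leads[1]
            l2.target_taxon = None
            l2.target_couplet = target
            gt.injected_defects.append(("looped", target, None))

    return key, gt


def generate_key(config: KeyGenConfig):
    """Generate a topology from ``config``, inject its defects, and return
    ``(key, ground_truth)`` with ``true_metrics`` filled from the clean
    topology."""
    clean = generate_topology(
        config.n_taxa,
        config.balance,
        config.seed,
        retracing=config.retracing,
        illustration_rate=config.illustration_rate,
        feature_count_range=config.feature_count_range,
    )
    true_metrics = compute_metrics(clean)
    key, gt = inject_defects(clean, config)
    gt.true_metrics = true_metrics
    return key, gt


# ---------------------------------------------------------------------------
# corpus generation


@dataclass
class GroupSpec:
    """One group (an insect order or a journal) in a synthetic corpus:
    its share of papers and its probability of a paper including a key."""

    name: str
    key_prob: float
    proportion: Optional[float] = None


#: marginal rates for the remaining metadata fields, chosen to resemble
#: current practice in generic-level insect taxonomy: most papers are openly
#: available, about two-thirds are discoverable by the word "key", about
#: half state the key's scope, diagnoses of every keyed taxon are the
#: exception, habitus images are near-universal.
DEFAULT_MARGINALS = {
    "freely_available": 0.74,
    "available_via_library": 0.05,
    "key_discoverable": 0.70,
    "scope_statement": 0.52,
    "sex_applicable": 0.30,
    "sex_stated": 0.70,
    "caste_applicable": 0.05,
    "caste_stated": 0.6,
    "diagnosis_all": 0.25,
    "diagnosis_some": 0.30,
    "habitus": 0.94,
    "placement_good": 0.12,
    "supplement_only": 0.02,
}


def generate_corpus(n_papers: int, group_specs, seed: int, marginals: Optional[dict] = None) -> list:
    """Generate ``n_papers`` :class:`PaperMetadata` records.

    ``group_specs`` is a sequence of :class:`GroupSpec`; papers are
    allocated to groups by their ``proportion`` (equal shares when omitted)
    and each paper includes a key with its group's ``key_prob``.
    """
    specs = list(group_specs)
    if not specs:
        raise ValueError("need at least one group")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0B5]))
    mg = dict(DEFAULT_MARGINALS)
    if marginals:
        mg.update(marginals)
    props = np.array([s.proportion if s.proportion is not None else 1.0 for s in specs], dtype=float)
    props = props / props.sum()
    groups = rng.choice(len(specs), size=n_papers, p=props)
    placements = ("adjacent", "adjacent-page", "hyperlinked", "grouped-at-key", "dispersed")
    out = []
    for i in range(n_papers):
        spec = specs[groups[i]]
        has_key = bool(rng.random() < spec.key_prob)
        n_new = 1 + int(rng.poisson(0.4))
        n_in_key = 0
        if has_key:
            n_in_key = max(n_new + 1, 2 + int(rng.geometric(0.12)))
        sex_app = rng.random() < mg["sex_applicable"]
        caste_app = rng.random() < mg["caste_applicable"]
        diag = rng.random()
        if diag < mg["diagnosis_all"]:
            coverage = "all"
        elif diag < mg["diagnosis_all"] + mg["diagnosis_some"]:
            coverage = "some-others"
        else:
            coverage = "new-genera-only"
        out.append(
            PaperMetadata(
                paper_id=f"paper_{i + 1:04d}",
                order=spec.name,
                journal=f"J{1 + int(rng.integers(0, 5))}",
                has_key=has_key,
                freely_available=bool(rng.random() < mg["freely_available"]),
                available_via_library=bool(rng.random() < mg["available_via_library"]),
                key_term_location=(("abstract",) if (has_key and rng.random() < mg["key_discoverable"]) else ()),
                scope_statement_present=bool(rng.random() < mg["scope_statement"]),
                scope_statement_location="above-key",
                sex_restriction_stated=(bool(rng.random() < mg["sex_stated"]) if sex_app else None),
                caste_restriction_stated=(bool(rng.random() < mg["caste_stated"]) if caste_app else None),
                diagnosis_coverage=coverage,
                habitus_present=bool(rng.random() < mg["habitus"]),
                habitus_kind="photograph",
                image_placement=str(rng.choice(placements, p=[0.05, 0.06, 0.01, 0.02, 0.86])),
                n_new_genera=n_new,
                n_genera_in_key=n_in_key,
                n_new_genera_keyed=(n_new if has_key else 0),
                key_in_supplement_only=bool(has_key and rng.random() < mg["supplement_only"]),
                emendation_standalone=None,
            )
        )
    return out
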