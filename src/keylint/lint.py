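"""Defect detectors for identification keys.

Every detector is a pure function from a :class:`~keylint.model.Key` (or a
single couplet) to a list of :class:`~keylint.model.Defect` records; running
the same key twice yields the same defects — there is no randomness anywhere
in this module.

Structural detectors (numbering, leap-frog, loops, polychotomies) are exact:
they follow from the couplet graph alone.  Wording detectors (contrast,
parallelism, ambiguity) are deliberately shallow — features are paired across
leads by their first content word, and ambiguity is keyed off a configurable
lexicon — because the published assessment they reproduce was done by eye and
full language understanding is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .model import Couplet, Defect, Key, KeyGraph, build_graph, normalize_taxon, validate_key

__all__ = [
    "AmbiguityLexicon",
    "detect_leapfrog",
    "detect_retracing",
    "detect_numbering_errors",
    "detect_monothetic",
    "detect_parallel_and_contrast",
    "detect_ambiguity",
    "detect_illustration_coverage",
    "detect_style",
    "lint_key",
]


@dataclass
class AmbiguityLexicon:
    """Word lists driving the ambiguity detector.

    *Qualifier words* ("usually", "often", …) make a feature fail whenever
    the specimen at hand is not of the usual phenotype.  *Relative markers*
    ("strongly", "weakly", …) and bare comparatives used without an explicit
    standard or measurement ("narrower" — narrower than what?) require
    knowledge the key's user does not have.  Matching is case-insensitive on
    word boundaries.
    """

    qualifier_words: tuple = (
        "usually",
        "often",
        "normally",
        "normal",
        "sometimes",
        "typically",
        "mostly",
        "rarely",
        "generally",
    )
    relative_markers: tuple = (
        "strongly",
        "weakly",
        "relatively",
        "comparatively",
        "slightly",
        "distinctly",
    )
    #: bare comparatives: flagged only when not followed by "than" and with
    #: no measurement/ratio in the feature
    bare_comparatives: tuple = (
        "wider",
        "narrower",
        "longer",
        "shorter",
        "larger",
        "smaller",
        "broader",
        "denser",
        "sparser",
    )
    #: words skipped when looking for a feature's subject token
    subject_stoplist: tuple = (
        "the",
        "a",
        "an",
        "with",
        "without",
        "in",
        "on",
        "of",
    )

    def __post_init__(self):
        if not self.qualifier_words or not self.relative_markers:
            raise ValueError("lexicons must be non-empty")
        self._qual_re = _word_re(self.qualifier_words)
        self._rel_re = _word_re(self.relative_markers)
        self._cmp_re = re.compile(
            r"\b(" + "|".join(map(re.escape, self.bare_comparatives)) + r")\b(?!\s+than)",
            re.IGNORECASE,
        )


def _word_re(words) -> re.Pattern:
    return re.compile(r"\b(" + "|".join(map(re.escape, words)) + r")\b", re.IGNORECASE)


DEFAULT_LEXICON = AmbiguityLexicon()

#: digits (measurements, counts) or an explicit ratio sign count as
#: quantification that rescues a relative statement
_MEASURE = re.compile(r"\d|×|\bx\b")
_RANGE = re.compile(r"(\d+(?:\.\d+)?)\s*[–—-]\s*(\d+(?:\.\d+)?)")


def subject_token(text: str, lexicon: AmbiguityLexicon = DEFAULT_LEXICON) -> Optional[str]:
    """First content word of a feature, the pairing handle for contrast
    checks.  Lowercased; qualifier/relative words and stop words are
    skipped so "usually head wider" still pairs on "head"."""
    skip = set(lexicon.subject_stoplist) | set(lexicon.qualifier_words) | set(lexicon.relative_markers)
    for tok in re.findall(r"[A-Za-zÀ-ſ_-]+", text):
        t = tok.lower()
        if t not in skip:
            return t
    return None


# ---------------------------------------------------------------------------
# structural detectors


def detect_leapfrog(key: Key) -> list:
    """Couplets whose first lead jumps to a distant couplet while the second
    lead continues to the numeric successor.

    Printed convention is that the *first* lead continues to the next
    couplet; inverting that invites users to take the wrong branch.  Only
    couplets whose leads both reference couplets are eligible.
    """
    defects = []
    for c in key.couplets:
        if not c.is_dichotomous:
            continue
        l1, l2 = c.leads
        if l1.is_terminal or l2.is_terminal:
            continue
        nxt = c.number + 1
        if l2.target_couplet == nxt and l1.target_couplet != nxt:
            defects.append(
                Defect(
                    "leap-frog",
                    couplet_number=c.number,
                    message=(
                        f"first lead jumps to couplet {l1.target_couplet} while the "
                        f"second continues to {nxt}"
                    ),
                )
            )
    return defects


def detect_retracing(key: Key, graph: Optional[KeyGraph] = None, strict: bool = False):
    """Whether a user can walk backwards through the key.

    Returns ``(supports_retracing, defects)``.  ``supports_retracing`` is
    ``None`` (not applicable) for keys of at most two couplets — there is
    nothing to retrace.  In the default mode a key supports retracing when
    every non-root couplet that does not simply continue from the couplet
    printed immediately above it carries a ``(M)`` reference; ``strict=True``
    demands a reference on every non-root couplet.  A retrace reference
    naming a couplet whose leads do not actually target the current one is a
    numbering error.
    """
    defects = []
    if len(key.couplets) <= 2:
        return None, defects
    if graph is None:
        graph = build_graph(key)
    by_number = {}
    for c in key.couplets:
        by_number.setdefault(c.number, c)
    doc_prev = {}
    for prev, cur in zip(key.couplets, key.couplets[1:]):
        doc_prev[id(cur)] = prev
    supports = True
    root = key.couplets[0].number
    for c in key.couplets:
        if c.retrace_ref is not None:
            src = by_number.get(c.retrace_ref)
            if src is None or all(ld.target_couplet != c.number for ld in src.leads):
                defects.append(
                    Defect(
                        "numbering-error",
                        couplet_number=c.number,
                        message=(
                            f"retrace reference ({c.retrace_ref}) names a couplet "
                            f"whose leads do not target couplet {c.number}"
                        ),
                    )
                )
            continue
        if c.number == root:
            continue
        if strict:
            supports = False
            continue
        prev = doc_prev.get(id(c))
        continues_from_prev = prev is not None and any(
            ld.target_couplet == c.number for ld in prev.leads
        )
        if not continues_from_prev:
            supports = False
    return supports, defects


def detect_numbering_errors(key: Key, graph: Optional[KeyGraph] = None) -> list:
    """Duplicate numbers, gaps in the printed sequence, and references back
    onto the user's own path (cycles)."""
    defects = [d for d in validate_key(key) if d.category == "numbering-error"]
    nums = sorted({c.number for c in key.couplets})
    missing = sorted(set(range(nums[0], nums[-1] + 1)) - set(nums))
    if missing:
        defects.append(
            Defect(
                "missing-numbers",
                message=f"couplet numbers missing from sequence: {missing}",
            )
        )
    if graph is None:
        graph = build_graph(key)
    for cnum, ordinal, target in graph.cycle_edges:
        defects.append(
            Defect(
                "numbering-error",
                couplet_number=cnum,
                lead_ordinal=ordinal,
                message=f"lead targets couplet {target}, an ancestor on its own path (cycle)",
            )
        )
    return defects


def detect_style(key: Key, graph: Optional[KeyGraph] = None) -> list:
    """Non-standard structure: yoked style, polychotomies, loops,
    unreachable couplets, taxa keying out repeatedly, several taxa sharing
    one lead."""
    defects = []
    if key.style == "yoked":
        defects.append(Defect("yoked-style", message="key is in the yoked (letter-paired) style"))
    for c in key.couplets:
        if len(c.leads) > 2:
            defects.append(
                Defect(
                    "polychotomy",
                    couplet_number=c.number,
                    message=f"couplet {c.number} offers {len(c.leads)} leads",
                )
            )
        for ld in c.leads:
            if ld.is_terminal and re.search(r"\b(and|&)\b", ld.target_taxon):
                defects.append(
                    Defect(
                        "multi-taxon-lead",
                        couplet_number=c.number,
                        lead_ordinal=ld.ordinal,
                        message=f"lead keys out more than one taxon: {ld.target_taxon!r}",
                    )
                )
    if graph is None:
        graph = build_graph(key)
    for num, parents in graph.extra_parents.items():
        defects.append(
            Defect(
                "looped",
                couplet_number=num,
                message=(
                    f"couplet {num} is reachable along two paths "
                    f"(parents {graph.parent_of.get(num)} and {parents})"
                ),
            )
        )
    for num in graph.unreachable:
        defects.append(
            Defect("unreachable-couplet", couplet_number=num, message=f"couplet {num} cannot be reached from the start")
        )
    for taxon, depths in graph.taxon_paths.items():
        if len(depths) > 1 and not graph.has_loop:
            defects.append(
                Defect(
                    "duplicate-taxon",
                    message=f"taxon {taxon!r} keys out {len(depths)} times (path lengths {sorted(depths)})",
                )
            )
    return defects


# ---------------------------------------------------------------------------
# couplet-wording detectors


def detect_monothetic(key: Key, graph: Optional[KeyGraph] = None):
    """Monothetic couplets: both leads rest on a single feature.

    Returns ``(per_couplet, proportion, all_paths_hit)`` where
    ``all_paths_hit`` says whether every taxon's path to identification
    crosses at least one monothetic couplet (commonly true whenever the
    first couplet is monothetic).
    """
    per_couplet = {}
    for c in key.couplets:
        per_couplet[c.number] = all(len(ld.features) == 1 for ld in c.leads)
    proportion = sum(per_couplet.values()) / len(per_couplet) if per_couplet else 0.0
    if graph is None:
        graph = build_graph(key)
    # walk each taxon's path through parent links, checking for a monothetic hit
    all_hit = bool(graph.taxon_paths)
    mono_numbers = {n for n, v in per_couplet.items() if v}
    for c in key.couplets:
        for ld in c.leads:
            if not ld.is_terminal:
                continue
            # climb from the deciding couplet to the root
            num, hit, guard = c.number, False, 0
            while num is not None and guard < len(key.couplets) + 2:
                if num in mono_numbers:
                    hit = True
                    break
                parent = graph.parent_of.get(num)
                num = parent[0] if parent else None
                guard += 1
            if not hit:
                all_hit = False
    return per_couplet, proportion, all_hit


def detect_parallel_and_contrast(
    couplet: Couplet, lexicon: AmbiguityLexicon = DEFAULT_LEXICON
) -> list:
    """Check that features are treated in parallel and each is contrasted.

    Features are paired across the two leads by shared subject token.  An
    unpaired feature is uncontrasted (the comparison it invites is
    impossible); paired features appearing in a different order are
    non-parallel; a couplet whose leads share no subject at all blocks
    comparison entirely.  Feature ``is_contrasted`` slots are annotated in
    place.  Polychotomous couplets are skipped (the pairing is pairwise).
    """
    if not couplet.is_dichotomous:
        return []
    defects = []
    l1, l2 = couplet.leads
    subj1 = [subject_token(f.text, lexicon) for f in l1.features]
    subj2 = [subject_token(f.text, lexicon) for f in l2.features]
    paired1 = [s in subj2 for s in subj1]
    paired2 = [s in subj1 for s in subj2]
    for ld, subs, paired in ((l1, subj1, paired1), (l2, subj2, paired2)):
        for f, s, ok in zip(ld.features, subs, paired):
            f.is_contrasted = bool(ok)
            if not ok:
                defects.append(
                    Defect(
                        "uncontrasted-feature",
                        couplet_number=couplet.number,
                        lead_ordinal=ld.ordinal,
                        message=f"feature {f.text!r} has no counterpart in the other lead",
                    )
                )
    shared = [s for s in subj1 if s in subj2]
    if not shared:
        defects.append(
            Defect(
                "uncontrasted-feature",
                couplet_number=couplet.number,
                message="leads share no contrasted feature; comparison is impossible",
            )
        )
        return defects
    order2 = [s for s in subj2 if s in subj1]
    if shared != order2:
        defects.append(
            Defect(
                "non-parallel-features",
                couplet_number=couplet.number,
                message=f"shared features appear in different orders: {shared} vs {order2}",
            )
        )
    return defects


def _feature_flags(text: str, lexicon: AmbiguityLexicon) -> list:
    flags = []
    if lexicon._qual_re.search(text):
        flags.append("qualifier-word")
    if lexicon._rel_re.search(text) and not _MEASURE.search(text):
        flags.append("relative-statement")
    if lexicon._cmp_re.search(text) and not _MEASURE.search(text):
        flags.append("implied-alternative")
    return flags


def detect_ambiguity(couplet: Couplet, lexicon: AmbiguityLexicon = DEFAULT_LEXICON) -> list:
    """Indecisive features within a couplet.

    A feature is flagged when it contains a qualifier word, a relative
    marker or bare comparative with no accompanying measurement or ratio, or
    when numeric ranges for the same subject overlap between the two leads
    (a specimen falling in the overlap cannot be placed).  Relative
    statements are considered *resolved* — downgraded to no defect — when
    both leads carry figure references, since an illustrated pair shows the
    user what "strongly" versus "weakly" means here.  A couplet in which
    every feature of some lead is indecisive (and unresolved) is flagged as
    fully indecisive.  Feature ``ambiguity_flags`` are annotated in place.
    """
    if not couplet.is_dichotomous:
        return []
    defects = []
    l1, l2 = couplet.leads
    both_illustrated = bool(l1.figure_refs) and bool(l2.figure_refs)

    # overlapping ranges, paired by subject
    ranges = {}
    for ld in (l1, l2):
        for f in ld.features:
            m = _RANGE.search(f.text)
            s = subject_token(f.text, lexicon)
            if m and s:
                ranges.setdefault(s, []).append((ld, f, float(m.group(1)), float(m.group(2))))
    overlapping = set()
    for s, hits in ranges.items():
        if len(hits) == 2 and hits[0][0] is not hits[1][0]:
            (_, fa, lo1, hi1), (_, fb, lo2, hi2) = hits
            if max(lo1, lo2) <= min(hi1, hi2):
                overlapping.update((id(fa), id(fb)))

    indecisive = {}
    for ld in (l1, l2):
        flagged = []
        for f in ld.features:
            flags = _feature_flags(f.text, lexicon)
            if id(f) in overlapping:
                flags.append("overlapping-range")
            f.ambiguity_flags = flags
            resolved = both_illustrated and set(flags) <= {"relative-statement"}
            if flags and not resolved:
                flagged.append(f)
                if flags == ["relative-statement"]:
                    cat = "unresolved-relative-statement"
                else:
                    cat = "indecisive-feature"
                defects.append(
                    Defect(
                        cat,
                        couplet_number=couplet.number,
                        lead_ordinal=ld.ordinal,
                        message=f"feature {f.text!r} is indecisive ({', '.join(flags)})",
                    )
                )
        indecisive[ld.ordinal] = flagged
    for ld in (l1, l2):
        if ld.features and len(indecisive[ld.ordinal]) == len(ld.features):
            defects.append(
                Defect(
                    "fully-indecisive-couplet",
                    couplet_number=couplet.number,
                    message=f"every feature of lead {ld.ordinal} is indecisive",
                )
            )
            break
    return defects


def detect_illustration_coverage(key: Key):
    """Proportion of leads citing at least one figure, and its class:
    ``none`` (no lead illustrated), ``partial``, or ``all-leads``."""
    leads = [ld for c in key.couplets for ld in c.leads]
    if not leads:
        return 0.0, "none"
    prop = sum(1 for ld in leads if ld.figure_refs) / len(leads)
    cls = "none" if prop == 0 else ("all-leads" if prop == 1 else "partial")
    return prop, cls


def lint_key(key: Key, lexicon: AmbiguityLexicon = DEFAULT_LEXICON, graph: Optional[KeyGraph] = None) -> list:
    """Run every detector on a key and return the combined defect list."""
    if graph is None:
        graph = build_graph(key)
    defects = []
    defects += [d for d in validate_key(key) if d.category == "dangling-reference"]
    defects += detect_numbering_errors(key, graph)
    defects += detect_leapfrog(key)
    defects += detect_style(key, graph)
    supports, retrace_defects = detect_retracing(key, graph)
    defects += retrace_defects
    if supports is False:
        defects.append(Defect("no-retracing", message="key does not state which couplet leads to each one"))
    per_couplet, _, _ = detect_monothetic(key, graph)
    for num, mono in per_couplet.items():
        if mono:
            defects.append(
                Defect("monothetic-couplet", couplet_number=num, message="both leads rest on a single feature")
            )
    for c in key.couplets:
        defects += detect_parallel_and_contrast(c, lexicon)
        defects += detect_ambiguity(c, lexicon)
    _, cls = detect_illustration_coverage(key)
    if cls != "all-leads":
        for c in key.couplets:
            for ld in c.leads:
                if not ld.figure_refs:
                    defects.append(
                        Defect(
                            "unillustrated-lead",
                            couplet_number=c.number,
                            lead_ordinal=ld.ordinal,
                            message="lead cites no figure",
                        )
                    )
    return defects
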