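"""The 17-criterion binary quality rubric for identification keys.

Each key is scored optimal / suboptimal / not-applicable on seventeen
criteria spanning availability, discoverability, scope statement, structural
soundness, decisiveness, illustration, and confirmation aids.  The headline
numbers are the count of suboptimal criteria (out of 17) and — because some
criteria do not apply to every key — the percentage of *applicable* criteria
on which the key is suboptimal.

Criteria (1–4, 13–17 come from paper-level metadata; 5–12 from the parsed
key, its metrics and its lint defects):

 1. the key is available (openly or via library subscription);
 2. the word "key" appears in title, abstract or keywords;
 3. the characteristics a specimen must possess for the key to apply are
    overtly stated;
 4. sex / caste restrictions are stated where they apply;
 5. no formatting (numbering) errors;
 6. no leap-frog couplets;
 7. all couplets dichotomous;
 8. retracing possible;
 9. the key is as fan-shaped as possible;
10. no monothetic couplets;
11. all features contrasted;
12. no couplet entirely indecisive;
13. images available for each lead;
14. images conveniently placed;
15. all taxa diagnosed;
16. a habitus image provided;
17. an emendation key stands alone.

All criteria are weighted equally; no importance ordering is invented.
"""

from __future__ import annotations

import math
from typing import Optional

from .model import Defect, Key, KeyMetrics, PaperMetadata, RubricResult

__all__ = ["score_key", "corpus_rubric_summary", "GOOD_PLACEMENTS"]

#: image placements counted as "conveniently placed"
GOOD_PLACEMENTS = ("adjacent", "adjacent-page", "hyperlinked", "grouped-at-key")

OPTIMAL, SUBOPT, NA = "optimal", "suboptimal", "not-applicable"


def _has(defects, *categories):
    cats = set(categories)
    hits = [d for d in defects if d.category in cats]
    return hits


def score_key(
    key: Key,
    meta: PaperMetadata,
    metrics: KeyMetrics,
    defects,
    supports_retracing: Optional[bool] = None,
    illustration_class: Optional[str] = None,
    family_scope_auto_optimal: bool = True,
) -> RubricResult:
    """Score one key against all seventeen criteria.

    ``supports_retracing`` and ``illustration_class`` are the outputs of the
    corresponding detectors; if omitted they are recomputed here.  Inputs
    must describe the same key (checked via ``key_id``).  Every verdict is
    accompanied by an evidence string naming the defect or metadata field
    that decided it.
    """
    if metrics.key_id != key.key_id:
        raise ValueError(f"metrics are for {metrics.key_id!r}, not {key.key_id!r}")
    if supports_retracing is None or illustration_class is None:
        from .lint import detect_illustration_coverage, detect_retracing

        if supports_retracing is None:
            supports_retracing, _ = detect_retracing(key)
        if illustration_class is None:
            _, illustration_class = detect_illustration_coverage(key)

    v: dict = {}
    ev: dict = {}

    def put(cid, verdict, evidence):
        v[cid] = verdict
        ev[cid] = evidence

    # 1 availability
    if meta.freely_available or meta.available_via_library:
        put(1, OPTIMAL, "freely_available" if meta.freely_available else "available_via_library")
    else:
        put(1, SUBOPT, "not available openly or via library")

    # 2 discoverability
    locs = tuple(meta.key_term_location)
    if locs and set(locs) != {"none"}:
        put(2, OPTIMAL, f"'key' found in {', '.join(locs)}")
    else:
        put(2, SUBOPT, "'key' absent from title, abstract and keywords")

    # 3 scope statement; family-rank keys need none by default
    if meta.scope_statement_present:
        where = meta.scope_statement_location or "unspecified location"
        put(3, OPTIMAL, f"scope statement present ({where})")
    elif family_scope_auto_optimal and key.scope.group_rank == "family":
        put(3, OPTIMAL, "family-rank key; group identification assumed known")
    else:
        put(3, SUBOPT, "no statement of what the key applies to")

    # 4 sex / caste statements; NA when neither applies
    sub4 = []
    if meta.sex_restriction_stated is False:
        sub4.append("sex restriction unstated")
    if meta.caste_restriction_stated is False:
        sub4.append("caste restriction unstated")
    if meta.sex_restriction_stated is None and meta.caste_restriction_stated is None:
        put(4, NA, "no sex or caste restriction applies")
    elif sub4:
        put(4, SUBOPT, "; ".join(sub4))
    else:
        put(4, OPTIMAL, "applicable sex/caste restrictions stated")

    # 5 formatting errors
    hits = _has(defects, "numbering-error", "missing-numbers")
    put(5, SUBOPT if hits else OPTIMAL, _ev(hits, "no numbering defects"))

    # 6 leap-frog
    hits = _has(defects, "leap-frog")
    put(6, SUBOPT if hits else OPTIMAL, _ev(hits, "no leap-frog couplets"))

    # 7 dichotomous throughout
    hits = _has(defects, "polychotomy")
    put(7, SUBOPT if hits else OPTIMAL, _ev(hits, "all couplets dichotomous"))

    # 8 retracing; NA for <=2-couplet keys (nothing to retrace) and yoked keys
    if supports_retracing is None or key.style == "yoked":
        put(8, NA, "retracing not sensible for this key")
    elif supports_retracing:
        put(8, OPTIMAL, "retrace references present and consistent")
    else:
        put(8, SUBOPT, "retracing not possible")

    # 9 fan-shapedness; NA when the comb/fan bounds don't apply; keys to
    # three or fewer taxa cannot meaningfully deviate
    if metrics.n_taxa <= 3:
        put(9, OPTIMAL, f"only {metrics.n_taxa} taxa; shape is forced")
    elif metrics.s_min is None or metrics.s_actual is None:
        put(9, NA, "excluded from fan/comb bounds (non-dichotomous or malformed)")
    elif metrics.is_max_fan:
        put(9, OPTIMAL, f"s_actual == s_min == {metrics.s_min:.4g}")
    else:
        put(9, SUBOPT, f"s_actual {metrics.s_actual:.4g} > s_min {metrics.s_min:.4g}")

    # 10 monothetic couplets
    hits = _has(defects, "monothetic-couplet")
    put(10, SUBOPT if hits else OPTIMAL, _ev(hits, "no monothetic couplets"))

    # 11 contrast
    hits = _has(defects, "uncontrasted-feature")
    put(11, SUBOPT if hits else OPTIMAL, _ev(hits, "every feature contrasted"))

    # 12 decisiveness
    hits = _has(defects, "fully-indecisive-couplet")
    put(12, SUBOPT if hits else OPTIMAL, _ev(hits, "no fully indecisive couplet"))

    # 13 illustration coverage
    if illustration_class == "all-leads":
        put(13, OPTIMAL, "every lead cites a figure")
    else:
        put(13, SUBOPT, f"illustration coverage: {illustration_class}")

    # 14 image placement; placement of nothing is unassessable
    if illustration_class == "none":
        put(14, NA, "no images to place")
    elif meta.image_placement in GOOD_PLACEMENTS:
        put(14, OPTIMAL, f"images {meta.image_placement}")
    else:
        put(14, SUBOPT, f"images {meta.image_placement or 'dispersed'}")

    # 15 diagnoses
    if meta.diagnosis_coverage == "all":
        put(15, OPTIMAL, "all keyed taxa diagnosed")
    else:
        put(15, SUBOPT, f"diagnosis coverage: {meta.diagnosis_coverage}")

    # 16 habitus
    put(16, OPTIMAL if meta.habitus_present else SUBOPT, f"habitus_present={meta.habitus_present}")

    # 17 emendation standing alone
    if not key.scope.is_emendation:
        put(17, NA, "not an emendation")
    elif meta.emendation_standalone:
        put(17, OPTIMAL, "emendation usable without the original key")
    else:
        put(17, SUBOPT, "emendation requires the previous key")

    return RubricResult(key_id=key.key_id, verdicts=v, evidence=ev)


def _ev(hits, clean_msg):
    if not hits:
        return clean_msg
    return "; ".join(str(h) for h in hits[:3]) + ("" if len(hits) <= 3 else f" (+{len(hits) - 3} more)")


def corpus_rubric_summary(results) -> dict:
    """Aggregate rubric results across a corpus.

    Returns mean/SD/min/max for the suboptimal count and for the percentage
    of applicable criteria that were suboptimal.  SD uses the sample (n−1)
    denominator; with a single key it is reported as 0.0 and
    ``sd_defined=False``.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one rubric result")
    counts = [r.n_suboptimal for r in results]
    pcts = [r.pct_suboptimal for r in results]

    def sd(xs):
        if len(xs) < 2:
            return 0.0
        m = sum(xs) / len(xs)
        return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))

    return {
        "n_keys": len(results),
        "mean_suboptimal": sum(counts) / len(counts),
        "sd_suboptimal": sd(counts),
        "min_suboptimal": min(counts),
        "max_suboptimal": max(counts),
        "mean_pct": sum(pcts) / len(pcts),
        "sd_pct": sd(pcts),
        "min_pct": min(pcts),
        "max_pct": max(pcts),
        "sd_defined": len(results) >= 2,
    }
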