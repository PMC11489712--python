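"""Data model for dichotomous identification keys.

An identification key is an ordered list of numbered *couplets*; each couplet
offers two (occasionally more) alternative *leads*.  A lead lists one or more
discriminating *features* (the word "character" is avoided because of its
phylogenetic connotations) and ends either in the number of the next couplet
to consult or in a taxon name — the identification.  Authors may additionally
print, in a ``N(M)`` header, the number ``M`` of the couplet that led to the
current one (*retracing*), cite figures from a lead, and append bracketed
*ancillary* information (helpful but deliberately non-decisive, e.g.
geography).

The model here is intentionally permissive: published keys contain duplicated
couplet numbers, dangling references, loops and polychotomies, and the whole
point of this package is to measure such pathology rather than refuse it.
Every structural problem is reported as a :class:`Defect` record; nothing in
this module raises on a malformed (but representable) key.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Union

__all__ = [
    "Feature",
    "Lead",
    "Couplet",
    "KeyScope",
    "Key",
    "KeyGraph",
    "KeyMetrics",
    "Defect",
    "DEFECT_CATEGORIES",
    "PaperMetadata",
    "RubricResult",
    "validate_key",
    "build_graph",
    "key_to_dict",
    "key_from_dict",
    "key_to_json",
    "key_from_json",
]

#: Closed vocabulary of defect categories.  Structural categories come from
#: the graph/numbering layer; wording categories from the couplet text layer.
DEFECT_CATEGORIES = frozenset(
    {
        "numbering-error",
        "missing-numbers",
        "leap-frog",
        "polychotomy",
        "looped",
        "unreachable-couplet",
        "dangling-reference",
        "no-retracing",
        "yoked-style",
        "monothetic-couplet",
        "non-parallel-features",
        "uncontrasted-feature",
        "indecisive-feature",
        "fully-indecisive-couplet",
        "unresolved-relative-statement",
        "unillustrated-lead",
        "multi-taxon-lead",
        "duplicate-taxon",
    }
)

#: Ambiguity categories attachable to a single feature.
AMBIGUITY_FLAGS = ("qualifier-word", "relative-statement", "overlapping-range", "implied-alternative")


@dataclass
class Feature:
    """A single discriminating observation within a lead.

    ``is_contrasted`` and ``ambiguity_flags`` are annotation slots filled in
    by the lint detectors; a freshly parsed feature is assumed contrasted and
    unambiguous until shown otherwise.
    """

    text: str
    is_contrasted: bool = True
    ambiguity_flags: list = field(default_factory=list)

    def __post_init__(self):
        self.text = " ".join(str(self.text).split())


@dataclass
class Lead:
    """One alternative within a couplet.

    Exactly one of ``target_couplet`` / ``target_taxon`` is set: a lead either
    sends the user onward to another couplet or keys out a taxon.
    """

    ordinal: int
    features: list  # list[Feature]
    target_couplet: Optional[int] = None
    target_taxon: Optional[str] = None
    figure_refs: list = field(default_factory=list)
    ancillary: Optional[str] = None

    def __post_init__(self):
        if (self.target_couplet is None) == (self.target_taxon is None):
            raise ValueError("a lead must have exactly one of a couplet target or a taxon target")
        self.features = [f if isinstance(f, Feature) else Feature(str(f)) for f in self.features]

    @property
    def is_terminal(self) -> bool:
        return self.target_taxon is not None

    @property
    def target(self) -> Union[int, str]:
        return self.target_couplet if self.target_couplet is not None else self.target_taxon


@dataclass
class Couplet:
    """A numbered decision point: the printed number, the optional ``(M)``
    retrace reference, and two or more leads."""

    number: int
    leads: list  # list[Lead]
    retrace_ref: Optional[int] = None

    def __post_init__(self):
        if len(self.leads) < 2:
            raise ValueError("a couplet needs at least two leads")
        ordinals = [ld.ordinal for ld in self.leads]
        if ordinals != list(range(1, len(self.leads) + 1)):
            raise ValueError(f"lead ordinals must be 1..{len(self.leads)} with no gaps, got {ordinals}")

    @property
    def is_dichotomous(self) -> bool:
        return len(self.leads) == 2


@dataclass
class KeyScope:
    """What the key claims to cover: rank of the group keyed, geographic
    extent, sex/caste restriction, emendation status."""

    group_rank: Optional[str] = None  # family | subfamily | tribe | subtribe | genus-group | other
    extent: Optional[str] = None  # global | continental | country | part-of-country
    sex: Optional[str] = None
    caste: Optional[str] = None
    is_emendation: bool = False


KEY_STYLES = ("dichotomous", "yoked", "mixed-polychotomous")


def normalize_taxon(name: str) -> str:
    """Taxon identity is exact string match after whitespace/case folding."""
    return " ".join(str(name).split()).casefold()


@dataclass
class Key:
    """A titled, scoped, ordered collection of couplets.

    Duplicate couplet numbers and dangling targets are representable; they
    are surfaced by :func:`validate_key`, never rejected here.
    """

    key_id: str
    couplets: list  # list[Couplet]
    title: str = ""
    scope: KeyScope = field(default_factory=KeyScope)
    style: str = "dichotomous"

    def __post_init__(self):
        if self.style not in KEY_STYLES:
            raise ValueError(f"unknown key style {self.style!r}")
        if not self.couplets:
            raise ValueError("a key needs at least one couplet")

    @property
    def numbers(self) -> list:
        return [c.number for c in self.couplets]

    def couplet_by_number(self, number: int) -> Optional[Couplet]:
        """First couplet (in document order) carrying ``number``.

        With duplicated numbers the first occurrence wins, mimicking how a
        reader scanning forward would resolve the reference.
        """
        for c in self.couplets:
            if c.number == number:
                return c
        return None

    def taxa(self) -> list:
        """Distinct terminal taxa in document order (normalized names)."""
        seen, out = set(), []
        for c in self.couplets:
            for ld in c.leads:
                if ld.is_terminal:
                    t = normalize_taxon(ld.target_taxon)
                    if t not in seen:
                        seen.add(t)
                        out.append(t)
        return out

    @property
    def is_strictly_dichotomous(self) -> bool:
        return all(c.is_dichotomous for c in self.couplets)


@dataclass
class Defect:
    """A single detected problem.  Defects are data, not exceptions."""

    category: str
    couplet_number: Optional[int] = None
    lead_ordinal: Optional[int] = None
    message: str = ""

    def __post_init__(self):
        if self.category not in DEFECT_CATEGORIES:
            raise ValueError(f"unknown defect category {self.category!r}")

    def __str__(self):
        loc = ""
        if self.couplet_number is not None:
            loc = f" couplet {self.couplet_number}"
            if self.lead_ordinal is not None:
                loc += f" lead {self.lead_ordinal}"
        return f"[{self.category}]{loc}: {self.message}"


@dataclass
class KeyGraph:
    """Rooted traversal structure of a key.

    ``parent_of`` holds the first-discovered parent of each reached couplet;
    any further parents (a "looped" key: the same couplet reachable along two
    paths) are collected in ``extra_parents``.  ``taxon_paths`` maps each
    normalized taxon name to the path length of every occurrence; the root
    couplet contributes path length 1.
    """

    root: int
    parent_of: dict = field(default_factory=dict)  # number -> (parent number, lead ordinal)
    extra_parents: dict = field(default_factory=dict)  # number -> [(parent, ordinal), ...]
    taxon_paths: dict = field(default_factory=dict)  # taxon -> [int, ...]
    unreachable: list = field(default_factory=list)  # couplet numbers never visited
    dangling: list = field(default_factory=list)  # (couplet, ordinal, target)
    cycle_edges: list = field(default_factory=list)  # (couplet, ordinal, target)

    @property
    def has_loop(self) -> bool:
        return bool(self.extra_parents)

    @property
    def is_clean(self) -> bool:
        return not (self.extra_parents or self.unreachable or self.dangling or self.cycle_edges)

    def all_depths(self) -> list:
        return sorted(d for ds in self.taxon_paths.values() for d in ds)


# Guard against path explosion in heavily looped keys: no couplet is entered
# more than this many times during traversal.
_MAX_VISITS = 8


def build_graph(key: Key) -> KeyGraph:
    """Traverse a key from its first couplet, recording parents, taxon path
    lengths, and every structural anomaly met on the way.

    Couplet references are resolved to the first couplet (document order)
    carrying the target number.  A reference back onto the current path is
    recorded as a cycle edge and not followed; a reference to an
    already-reached couplet off the current path is a second parent (loop)
    and *is* followed, so taxa below it receive one path length per route.
    """
    first_by_number: dict = {}
    for idx, c in enumerate(key.couplets):
        first_by_number.setdefault(c.number, idx)

    g = KeyGraph(root=key.couplets[0].number)
    visits = [0] * len(key.couplets)
    reached = set()

    def walk(idx: int, depth: int, path: tuple):
        if visits[idx] >= _MAX_VISITS:
            return
        visits[idx] += 1
        reached.add(idx)
        c = key.couplets[idx]
        for ld in c.leads:
            if ld.is_terminal:
                g.taxon_paths.setdefault(normalize_taxon(ld.target_taxon), []).append(depth)
                continue
            t = ld.target_couplet
            tidx = first_by_number.get(t)
            if tidx is None:
                g.dangling.append((c.number, ld.ordinal, t))
                continue
            if tidx in path:
                g.cycle_edges.append((c.number, ld.ordinal, t))
                continue
            tnum = key.couplets[tidx].number
            if tnum in g.parent_of or tnum == g.root:
                g.extra_parents.setdefault(tnum, []).append((c.number, ld.ordinal))
            else:
                g.parent_of[tnum] = (c.number, ld.ordinal)
            walk(tidx, depth + 1, path + (tidx,))

    walk(0, 1, (0,))
    g.unreachable = [key.couplets[i].number for i in range(len(key.couplets)) if i not in reached]
    return g


def validate_key(key: Key) -> list:
    """Representation-level checks run before any analysis.

    Returns duplicate-couplet-number and dangling-reference defects; an empty
    list means graph construction can proceed without surprises.  Nothing is
    raised — pathology is data.
    """
    defects = []
    seen: dict = {}
    for c in key.couplets:
        if c.number in seen:
            defects.append(
                Defect(
                    "numbering-error",
                    couplet_number=c.number,
                    message=f"couplet number {c.number} appears more than once",
                )
            )
        else:
            seen[c.number] = c
    numbers = set(key.numbers)
    for c in key.couplets:
        for ld in c.leads:
            if not ld.is_terminal and ld.target_couplet not in numbers:
                defects.append(
                    Defect(
                        "dangling-reference",
                        couplet_number=c.number,
                        lead_ordinal=ld.ordinal,
                        message=f"lead targets couplet {ld.target_couplet}, which does not exist",
                    )
                )
    return defects


@dataclass
class KeyMetrics:
    """Path-length statistics for a key.

    ``s_actual`` is the mean number of couplets traversed to an
    identification, averaging per taxon first when a taxon keys out more than
    once.  ``s_max``/``s_min`` are the closed-form comb (caterpillar) and fan
    (balanced) bounds; they are left unset for keys excluded from the
    comparison (polychotomies, loops, unreachable couplets), mirroring how
    the bounds only apply to strictly dichotomous keys.
    """

    key_id: str
    n_taxa: int
    n_couplets: int
    n_couplets_expected: int
    s_actual: Optional[float] = None
    s_max: Optional[float] = None
    s_min: Optional[float] = None
    q: Optional[int] = None
    x: Optional[int] = None
    is_max_fan: Optional[bool] = None
    depth_range: Optional[tuple] = None  # (min, max)


@dataclass
class PaperMetadata:
    """Per-paper survey record: availability, discoverability, scope
    statement, sex/caste statements, diagnosis and habitus coverage.

    Boolean-or-not-applicable fields use ``True``/``False``/``None`` with
    ``None`` meaning not applicable.
    """

    paper_id: str
    order: str = ""
    journal: str = ""
    has_key: bool = True
    freely_available: bool = True
    available_via_library: bool = False
    key_term_location: tuple = ()  # subset of ("title", "abstract", "keywords")
    scope_statement_present: bool = False
    scope_statement_location: Optional[str] = None
    sex_restriction_stated: Optional[bool] = None
    caste_restriction_stated: Optional[bool] = None
    diagnosis_coverage: str = "none"  # none | new-genera-only | some-others | all
    habitus_present: bool = False
    habitus_kind: Optional[str] = None  # photograph | drawing | SEM
    image_placement: Optional[str] = None  # adjacent | adjacent-page | hyperlinked | grouped-at-key | dispersed
    n_new_genera: int = 1
    n_genera_in_key: int = 0
    n_new_genera_keyed: int = 0
    key_in_supplement_only: bool = False
    emendation_standalone: Optional[bool] = None

    def __post_init__(self):
        if self.has_key and self.n_genera_in_key and self.n_new_genera > self.n_genera_in_key:
            raise ValueError("n_new_genera cannot exceed n_genera_in_key when a key exists")


@dataclass
class RubricResult:
    """Verdicts for the 17 binary quality criteria.

    ``verdicts`` maps criterion id (1..17) to one of ``optimal`` /
    ``suboptimal`` / ``not-applicable``; ``evidence`` records, per criterion,
    the defect or metadata field that decided the verdict (the audit trail).
    """

    key_id: str
    verdicts: dict  # int -> str
    evidence: dict = field(default_factory=dict)  # int -> str
    n_suboptimal: int = 0
    n_applicable: int = 0
    pct_suboptimal: float = 0.0

    def __post_init__(self):
        n_sub = sum(1 for v in self.verdicts.values() if v == "suboptimal")
        n_app = sum(1 for v in self.verdicts.values() if v != "not-applicable")
        if self.n_suboptimal == 0 and self.n_applicable == 0:
            self.n_suboptimal, self.n_applicable = n_sub, n_app
        if self.n_suboptimal != n_sub or self.n_applicable != n_app:
            raise ValueError("suboptimal/applicable counts disagree with verdicts")
        if self.n_applicable:
            self.pct_suboptimal = 100.0 * self.n_suboptimal / self.n_applicable


# ---------------------------------------------------------------------------
# JSON serialization


def _lead_to_dict(ld: Lead) -> dict:
    return {
        "ordinal": ld.ordinal,
        "features": [
            {"text": f.text, "is_contrasted": f.is_contrasted, "ambiguity_flags": list(f.ambiguity_flags)}
            for f in ld.features
        ],
        "target_couplet": ld.target_couplet,
        "target_taxon": ld.target_taxon,
        "figure_refs": list(ld.figure_refs),
        "ancillary": ld.ancillary,
    }


def key_to_dict(key: Key) -> dict:
    return {
        "key_id": key.key_id,
        "title": key.title,
        "style": key.style,
        "scope": dataclasses.asdict(key.scope),
        "couplets": [
            {
                "number": c.number,
                "retrace_ref": c.retrace_ref,
                "leads": [_lead_to_dict(ld) for ld in c.leads],
            }
            for c in key.couplets
        ],
    }


def key_from_dict(d: dict) -> Key:
    couplets = []
    for cd in d["couplets"]:
        leads = []
        for ldd in cd["leads"]:
            leads.append(
                Lead(
                    ordinal=ldd["ordinal"],
                    features=[
                        Feature(fd["text"], fd.get("is_contrasted", True), list(fd.get("ambiguity_flags", [])))
                        for fd in ldd["features"]
                    ],
                    target_couplet=ldd.get("target_couplet"),
                    target_taxon=ldd.get("target_taxon"),
                    figure_refs=list(ldd.get("figure_refs", [])),
                    ancillary=ldd.get("ancillary"),
                )
            )
        couplets.append(Couplet(number=cd["number"], leads=leads, retrace_ref=cd.get("retrace_ref")))
    return Key(
        key_id=d["key_id"],
        title=d.get("title", ""),
        style=d.get("style", "dichotomous"),
        scope=KeyScope(**d.get("scope", {})),
        couplets=couplets,
    )


def key_to_json(key: Key, **kwargs) -> str:
    return json.dumps(key_to_dict(key), **kwargs)


def key_from_json(s: str) -> Key:
    return key_from_dict(json.loads(s))


def record_to_dict(obj) -> dict:
    """Generic dataclass -> dict for KeyMetrics, Defect, RubricResult, PaperMetadata."""
    return dataclasses.asdict(obj)
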