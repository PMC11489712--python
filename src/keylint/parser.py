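"""Plain-text parser and canonical renderer for dichotomous keys.

The conventional printed format looks like::

    3(2) Head longer than wide; hind tibia with apicoventral spines  9
    –    Head shorter than wide; hind tibia lacking apicoventral spines  4

A couplet header is ``N``, ``N.`` or ``N(M)`` where ``M`` is the retrace
reference; the header line carries the first lead and each subsequent lead
opens with a dash (-, – or —) or with the repeated couplet number carrying a
prime mark (``3'.``).  A trailing integer is an onward couplet reference; a
trailing capitalized name (optionally with an author string) is a taxon.
Bracketed material before the target is ancillary, figure citations are
extracted per lead, and features within a lead are separated by semicolons.

Yoked keys — lead markers ``A``/``AA``, ``B``/``BB`` instead of numbers —
are recognized and folded into the same couplet model with ``style="yoked"``.

The parser never silently drops input: every line is either consumed into a
couplet, lead or title, or listed in ``ParseReport.unparsed_lines``.  It
raises only when no couplet header can be found at all (the text is not a
key); anything less becomes a warning ``Defect``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .model import Couplet, Defect, Feature, Key, KeyScope, Lead, validate_key

__all__ = [
    "ParseReport",
    "KeyParseError",
    "parse_key",
    "render_key",
    "split_keys",
    "structurally_equal",
]


def structurally_equal(a: Key, b: Key) -> bool:
    """Equality of everything a printed key can carry: title, style and the
    full couplet structure.  ``Key.scope`` is extrinsic metadata (it comes
    from the surrounding paper, not the key text) and is excluded."""
    return a.title == b.title and a.style == b.style and a.couplets == b.couplets


class KeyParseError(ValueError):
    """Raised when the text contains no recognizable couplet at all."""


@dataclass
class ParseReport:
    key: Key
    warnings: list = field(default_factory=list)  # list[Defect]
    unparsed_lines: list = field(default_factory=list)  # list[(lineno, text)]


_HEADER = re.compile(r"^\s*(\d+)\s*(?:\((\d+)\))?\s*[.)]?\s+(\S.*)$")
_DASH_LEAD = re.compile(r"^\s*[-–—]\s*(\S.*)$")
_PRIME_LEAD = re.compile(r"^\s*(\d+)\s*['′’]+\s*[.)]?\s*(\S.*)$")
_YOKED_LEAD = re.compile(r"^\s*([A-Z])(\1*)\s*[.)]\s+(\S.*)$")

# A parenthesized group whose content starts with a figure citation, e.g.
# "(Fig. 3A)" or "(Figs 2, 5)"; contents are split on ";" into refs.
_PAREN_FIG = re.compile(r"\(\s*([Ff]igs?\.?\s*[^()]*)\)")
_BARE_FIG = re.compile(r"\b[Ff]igs?\.?\s*\d[\w.–-]*(?:\s*,\s*\d[\w.–-]*)*")
_BRACKET = re.compile(r"\[([^\]]*)\]")
_RANGE_NUM = re.compile(r"^\d+$")

# Tokens acceptable inside a trailing taxon name, scanned right-to-left:
# capitalized words (incl. Genus_007), author initials, '&'/'and', 4-digit
# years, parenthesized author strings, commas attached to any of those.
_NAME_CAP = re.compile(r"^[A-Z][\wÀ-ſ.\-]*[,.]?$")
_NAME_CONN = re.compile(r"^(?:&|and|\d{4}[,.]?|\([^()]*\)[,.]?)$")


def _extract_figrefs(text: str):
    refs = []

    def grab_paren(m):
        refs.extend(p.strip() for p in m.group(1).split(";") if p.strip())
        return " "

    text = _PAREN_FIG.sub(grab_paren, text)

    def grab_bare(m):
        refs.append(m.group(0).strip())
        return " "

    text = _BARE_FIG.sub(grab_bare, text)
    return " ".join(text.split()), refs


def _extract_ancillary(text: str):
    parts = []

    def grab(m):
        parts.append(m.group(1).strip())
        return " "

    text = _BRACKET.sub(grab, text)
    return " ".join(text.split()), ("; ".join(parts) if parts else None)


def _split_target(text: str):
    """Split a lead body into (feature text, couplet target, taxon target).

    A trailing pure integer is a couplet reference.  Otherwise tokens are
    scanned right-to-left while they look name-like; the accumulated suffix,
    anchored on a capitalized word, is the taxon name.  The scan stops at the
    first lowercase non-connector token so feature text is never swallowed.
    """
    tokens = text.split()
    if not tokens:
        return "", None, None
    last = tokens[-1].rstrip(".,")
    # a trailing integer is an onward couplet reference, but a 4-digit value
    # is far more likely the year of a trailing author citation
    if _RANGE_NUM.match(last) and len(last) < 4:
        return " ".join(tokens[:-1]), int(last), None
    i = len(tokens)
    while i > 0 and (_NAME_CAP.match(tokens[i - 1]) or _NAME_CONN.match(tokens[i - 1])):
        i -= 1
    # the name must start with a capitalized word, not a connector
    while i < len(tokens) and not _NAME_CAP.match(tokens[i]):
        i += 1
    if i == len(tokens):
        return text, None, None
    return " ".join(tokens[:i]), None, " ".join(tokens[i:]).rstrip(".,")


def _finalize_lead(ordinal: int, raw: str, warnings: list, couplet_number):
    body, figrefs = _extract_figrefs(raw)
    body, ancillary = _extract_ancillary(body)
    body, tc, tt = _split_target(body)
    if tc is None and tt is None:
        # no recognizable target: keep the text as a taxon so the lead stays
        # representable, and warn
        tt = body or raw
        body = ""
        warnings.append(
            Defect(
                "numbering-error",
                couplet_number=couplet_number,
                lead_ordinal=ordinal,
                message="lead has no recognizable couplet or taxon target",
            )
        )
    # trailing parenthesized group before the target (figure refs were already
    # removed) is ancillary, not a feature
    m = re.search(r"\(([^()]*)\)\s*$", body)
    if m:
        extra = m.group(1).strip()
        body = body[: m.start()].strip()
        ancillary = f"{ancillary}; {extra}" if ancillary else extra
    feats = [Feature(p) for p in (s.strip() for s in body.split(";")) if p]
    if not feats:
        feats = [Feature(tt if tt else str(tc))]
    return Lead(
        ordinal=ordinal,
        features=feats,
        target_couplet=tc,
        target_taxon=tt,
        figure_refs=figrefs,
        ancillary=ancillary,
    )


def _yoked_parse(lines, key_id, title, warnings, unparsed):
    """Fold letter-marked yoked leads (A/AA, B/BB …) into couplets."""
    groups: dict = {}
    order = []
    letter_no: dict = {}
    for lineno, line in lines:
        m = _YOKED_LEAD.match(line)
        if not m:
            unparsed.append((lineno, line))
            continue
        letter = m.group(1)
        reps = len(m.group(2)) + 1
        if letter not in letter_no:
            letter_no[letter] = len(letter_no) + 1
            order.append(letter)
        groups.setdefault(letter, []).append((reps, m.group(3)))
    couplets = []
    for letter in order:
        num = letter_no[letter]
        leads = []
        for k, (_, raw) in enumerate(sorted(groups[letter]), start=1):
            # letter targets ("AA ... B") refer to the couplet of that letter
            raw2 = re.sub(
                r"\s([A-Z])\1*\s*$",
                lambda m: f" {letter_no[m.group(1)]}" if m.group(1) in letter_no else m.group(0),
                raw,
            )
            leads.append(_finalize_lead(k, raw2, warnings, num))
        while len(leads) < 2:
            leads.append(Lead(ordinal=len(leads) + 1, features=[Feature("(unstated alternative)")], target_taxon="Incertae"))
        couplets.append(Couplet(number=num, leads=leads))
    warnings.append(Defect("yoked-style", message="key uses yoked (letter-paired) lead markers"))
    return Key(key_id=key_id, title=title, couplets=couplets, style="yoked")


def parse_key(text: str, key_id: str = "key", dialect_hints: Optional[dict] = None) -> ParseReport:
    """Parse one plain-text key into a :class:`ParseReport`.

    Raises :class:`KeyParseError` if no couplet header is found anywhere;
    every lesser problem (polychotomies, numbering anomalies, yoked style)
    is reported as a warning defect and the key is still returned.
    """
    if not text or not text.strip():
        raise KeyParseError("empty input")
    warnings: list = []
    unparsed: list = []
    title_lines: list = []
    raw_lines = text.splitlines()

    numbered = [(i + 1, ln) for i, ln in enumerate(raw_lines) if ln.strip()]
    if not any(_HEADER.match(ln) or _PRIME_LEAD.match(ln) for _, ln in numbered):
        if any(_YOKED_LEAD.match(ln) for _, ln in numbered):
            body = [(n, ln) for n, ln in numbered if _YOKED_LEAD.match(ln) or not title_lines]
            # leading non-yoked lines are title
            head = []
            rest = []
            seen_lead = False
            for n, ln in numbered:
                if _YOKED_LEAD.match(ln):
                    seen_lead = True
                if seen_lead:
                    rest.append((n, ln))
                else:
                    head.append(ln.strip())
            key = _yoked_parse(rest, key_id, " ".join(head), warnings, unparsed)
            return ParseReport(key=key, warnings=warnings, unparsed_lines=unparsed)
        raise KeyParseError("no couplet header found: not an identification key")

    couplets: list = []
    cur_number: Optional[int] = None
    cur_retrace: Optional[int] = None
    cur_leads_raw: list = []  # raw text per lead of current couplet
    seen_first_header = False

    def close_couplet():
        nonlocal cur_number, cur_retrace, cur_leads_raw
        if cur_number is None:
            return
        if len(cur_leads_raw) < 2:
            warnings.append(
                Defect(
                    "numbering-error",
                    couplet_number=cur_number,
                    message=f"couplet {cur_number} has {len(cur_leads_raw)} lead(s); a couplet needs two",
                )
            )
            cur_leads_raw.append("(unstated alternative) Incertae")
        if len(cur_leads_raw) > 2:
            warnings.append(
                Defect(
                    "polychotomy",
                    couplet_number=cur_number,
                    message=f"couplet {cur_number} has {len(cur_leads_raw)} leads",
                )
            )
        leads = [_finalize_lead(k, raw, warnings, cur_number) for k, raw in enumerate(cur_leads_raw, start=1)]
        couplets.append(Couplet(number=cur_number, leads=leads, retrace_ref=cur_retrace))
        cur_number, cur_retrace, cur_leads_raw = None, None, []

    for lineno, line in numbered:
        m = _PRIME_LEAD.match(line)
        if m and seen_first_header:
            num = int(m.group(1))
            if num != cur_number:
                warnings.append(
                    Defect(
                        "numbering-error",
                        couplet_number=cur_number,
                        message=f"primed lead numbered {num} inside couplet {cur_number}",
                    )
                )
            cur_leads_raw.append(m.group(2))
            continue
        m = _HEADER.match(line)
        if m:
            close_couplet()
            seen_first_header = True
            cur_number = int(m.group(1))
            cur_retrace = int(m.group(2)) if m.group(2) else None
            cur_leads_raw = [m.group(3)]
            continue
        m = _DASH_LEAD.match(line)
        if m:
            if not seen_first_header:
                unparsed.append((lineno, line))
                continue
            cur_leads_raw.append(m.group(1))
            continue
        if not seen_first_header:
            title_lines.append(line.strip())
            continue
        if cur_leads_raw:
            # wrapped continuation of the current lead
            cur_leads_raw[-1] = cur_leads_raw[-1] + " " + line.strip()
        else:
            unparsed.append((lineno, line))
    close_couplet()

    if not couplets:
        raise KeyParseError("no couplet could be assembled")

    key = Key(key_id=key_id, title=" ".join(title_lines), couplets=couplets)
    for d in validate_key(key):
        if d.category == "numbering-error":
            warnings.append(d)
    nums = sorted({c.number for c in couplets})
    missing = sorted(set(range(nums[0], nums[-1] + 1)) - set(nums))
    if missing:
        warnings.append(
            Defect("missing-numbers", message=f"couplet numbers missing from sequence: {missing}")
        )
    if any(len(c.leads) > 2 for c in couplets):
        key = Key(key_id=key_id, title=key.title, couplets=couplets, style="mixed-polychotomous")
    return ParseReport(key=key, warnings=warnings, unparsed_lines=unparsed)


def _render_lead(ld: Lead) -> str:
    parts = ["; ".join(f.text for f in ld.features)]
    if ld.figure_refs:
        parts.append("(" + "; ".join(ld.figure_refs) + ")")
    if ld.ancillary:
        parts.append(f"[{ld.ancillary}]")
    parts.append(str(ld.target))
    return " ".join(parts)


def render_key(key: Key) -> str:
    """Render a key back to canonical text.

    ``N(M)`` headers appear iff the couplet has a retrace reference; second
    and later leads are prefixed with an en-dash.  For any key free of
    dangling references, ``parse_key(render_key(k))`` is structurally equal
    to ``k``.  Raises on dangling references (such a key has no faithful
    printed form).
    """
    for d in validate_key(key):
        if d.category == "dangling-reference":
            raise ValueError(f"cannot render key with dangling reference: {d}")
    lines = []
    if key.title:
        lines.append(key.title)
    for c in key.couplets:
        header = f"{c.number}({c.retrace_ref})" if c.retrace_ref is not None else str(c.number)
        lines.append(f"{header} {_render_lead(c.leads[0])}")
        for ld in c.leads[1:]:
            lines.append(f"– {_render_lead(ld)}")
    return "\n".join(lines) + "\n"


def split_keys(text: str, header_pattern: str = r"(?mi)^\s*key to\b.*$") -> list:
    """Split a file containing several keys on a configurable header line.

    Returns a list of text blocks, each starting with its header (or the
    whole text if the pattern never matches).
    """
    starts = [m.start() for m in re.finditer(header_pattern, text)]
    if not starts:
        return [text]
    starts.append(len(text))
    return [text[a:b].strip("\n") + "\n" for a, b in zip(starts[:-1], starts[1:])]
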