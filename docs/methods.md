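# Methods

This note documents the model behind `keylint`, the choices made where the
design was genuinely open, and what the synthetic material does and does not
establish about real published keys.

## The key model

A key is an ordered list of numbered couplets; a couplet holds two or more
leads; a lead holds an ordered list of features, optional figure citations,
optional bracketed ancillary text, and exactly one target (an onward couplet
number or a taxon name). Taxon identity is exact string match after
whitespace and case normalization, so a genus keying out twice is one taxon
with two path lengths. The model is deliberately permissive: duplicated
couplet numbers, dangling references, loops and polychotomies are all
representable, because the material this package is built to analyse is
published keys *with* their errors. All pathology is reported as `Defect`
records by the lint layer; the model itself only rejects structures that
have no printed interpretation at all (a couplet with one lead, a lead with
two targets).

Graph construction resolves couplet references to the first couplet in
document order carrying the target number (how a reader scanning forward
resolves an ambiguous reference). A reference back onto the current path is
a cycle and is not followed; a reference to a couplet already reached along
another path is a second parent — the "looped" pathology — and *is*
followed, so taxa below it receive one path length per route. Traversal is
capped at eight entries per couplet, which bounds pathological loop nests
without affecting any well-formed key.

Path length counts the deciding couplet, so the root contributes 1; a
16-taxon comb has path lengths 1 through 15.

## Path-length bounds

For $n \ge 2$ taxa, the comb (caterpillar) mean is
$S_{\max} = (n+1)/2 - 1/n$ and the fan (balanced) mean is
$S_{\min} = (Q(2^Q - x) + (Q+1)\,2x)/n$ with $Q = \lfloor\log_2 n\rfloor$
and $x = n - 2^Q$. $Q$ is computed from the integer bit length, never from
floating-point logarithms, so the power-of-two identity $S_{\min} = Q$ is
exact. The fan formula is the minimum external path length of an $n$-leaf
binary tree divided by $n$; the test suite verifies both closed forms
against an independent dynamic program over all root splits for
$n \le 64$.

`s_actual` averages per taxon first (a taxon keying out at depths 2 and 4
contributes 3), then over distinct taxa. Keys with polychotomies, loops,
unreachable couplets or dangling references get no $S_{\min}$/$S_{\max}$:
the bounds assume strict dichotomy. Keys with loops additionally get no
`s_actual`, because a looped couplet gives its taxa two defensible path
lengths and averaging them would assert a user model (which branch is taken
how often) that nothing in the key supports; the key is flagged instead.
`is_max_fan` is `|s_actual − s_min| < 1e-9`; all bound comparisons use the
same 1e-9 absolute tolerance, comfortably above accumulated rounding at any
realistic key size.

## Parsing and rendering

Couplet headers `N`, `N.`, `N(M)` are recognized; subsequent leads open with
a dash (-, –, —) or a primed repeat of the couplet number (`3'.`). Features
split on semicolons only — commas subordinate clauses within one feature,
and splitting on them would inflate feature counts and corrupt the
monothetic statistic. A trailing integer is an onward reference unless it
has four digits, which in practice is the year of an author citation;
otherwise the taxon name is the longest name-like suffix (capitalized words,
initials, "&"/"and", years, parenthesized authors) scanned right to left.
Bracketed text is ancillary and excluded from all wording analysis;
parenthesized groups beginning with "Fig." are figure citations, captured
per lead. Yoked keys (letter-paired leads `A`/`AA`) are folded into the same
couplet model with `style="yoked"`.

The renderer emits the canonical layout (header with `(M)` iff a retrace
reference exists, en-dash continuation leads, semicolon-joined features,
figure refs in parentheses, ancillary in brackets), and `parse ∘ render` is
the identity on any key free of dangling references — enforced as a
property test over generated keys. Structural equality excludes `Key.scope`,
which comes from the surrounding paper rather than the key text. The parser
conserves input: every line is consumed or listed as unparsed, and it raises
only when no couplet header exists anywhere.

## Lint detectors

Structural detectors are exact graph predicates. Leap-frog is defined
numerically: both leads reference couplets, the second targets `number+1`
and the first does not — matching the printed convention that the first
lead continues to the next couplet, and stable under numbering errors
elsewhere in the key. Retracing is supported when every couplet that does
not simply continue from the couplet printed above it carries a consistent
`(M)` reference (a strict mode demands references everywhere); keys of at
most two couplets return not-applicable. Retrace references naming a
couplet that does not lead to the current one are numbering errors.

Wording detectors are deliberately shallow. Features are paired across
leads by their first content word (after a configurable stop list that also
skips qualifier and relative words); unpaired features are uncontrasted,
shared features in different orders are non-parallel. Ambiguity combines
three signals: qualifier words ("usually", "often", …), relative markers
and bare comparatives without an accompanying measurement, ratio or
explicit "than" standard, and numeric ranges for the same subject that
overlap between leads (a specimen in the overlap cannot be placed — note
that the defect is *overlap*). Relative statements are downgraded to
resolved when both leads cite figures, since an illustrated pair shows the
user what the relative terms mean here; qualifier words are not curable by
illustration — the unusual phenotype is unusual no matter how well drawn. A
couplet is fully indecisive when every feature of some lead is flagged and
unresolved. No semantic understanding of morphological terminology is
attempted: the published assessments these rules reproduce were made by
eye, and the detectors' worth is established on labelled synthetic
fixtures, not on free prose.

## Rubric

The seventeen binary criteria are wired as follows: 1–4 and 13–17 read
paper metadata (availability, discoverability, scope statement, sex/caste
statements, image placement, diagnosis coverage, habitus, emendation
standing); 5–12 read the lint defects and metrics (numbering, leap-frog,
dichotomy, retracing, fan-shapedness, monothetic couplets, contrast,
decisiveness). Not-applicable handling: criterion 4 when no sex or caste
restriction applies; 8 for keys of at most two couplets and yoked keys; 9
for keys excluded from the bounds (keys of at most three taxa are
auto-optimal — their shape is forced); 14 when there are no images to
place; 17 for non-emendations. Criterion 3 is auto-optimal for family-rank
keys (group identification is assumed accessible elsewhere), overridable.
Each verdict carries an evidence string naming the deciding defect or
metadata field, so every score is auditable. The summary statistics use the
sample (n−1) standard deviation, reported as 0 with a flag for a single
key.

## Corpus statistics

Group proportions pool groups at or below a configurable paper-count
threshold (default 20) into "other". The chi-square test is the plain
Pearson statistic without continuity correction (Yates available by
option), delegated to scipy behind this module's surface and cross-checked
in the tests against the longhand Σ(O−E)²/E. The two-proportion z uses the
pooled variance. Mann–Whitney U reports min(U₁, U₂) with midrank ties;
for combined samples of at most 12 the two-sided p is exact by enumeration
of all rank interleavings (valid under ties), larger samples use the
normal approximation with tie correction and a 0.5 continuity correction.

## Synthetic material

The generator emulates the variation the pipeline must survive: topologies
spanning the comb↔fan continuum, conventional wording, retrace references,
figure citations, and labelled defects. Topology: taxa are split
recursively, the left share drawn as `1 + Binomial(⌊m/2⌋ − 1, balance)` —
monotone in `balance` with exact endpoints, so `balance=0` is the
caterpillar (mean = $S_{\max}$) and `balance=1` the balanced tree
(mean = $S_{\min}$); these endpoint contracts, not the interpolation curve,
are the tested guarantee. Couplets are numbered in pre-order, which makes
the first onward lead continue to the next couplet — clean keys are
leap-frog-free by construction. Wording comes from a bank of twenty
contrasted morphological phrase pairs with unique subjects and no lexicon
hits, so contrast and ambiguity detectors see realistic positives and
negatives. Default feature counts are 2–3 per lead (non-monothetic by
default).

Defect injection edits a deep copy at recorded loci: lead-order swaps
(leap-frog), renumbering a terminal couplet to duplicate an earlier number
(numbering error, with its attendant gap and dangling reference), a third
lead (polychotomy), redirecting a second-lead terminal onto a later couplet
(loop — later in pre-order, so no cycle and no spurious leap-frog),
single-feature reduction (monothetic), qualifier insertion and unpaired
features (wording). Injection sites are disjoint across categories so each
ground-truth locus has one cause. Everything is driven by integer seeds;
identical configuration gives byte-identical text.

Corpus generation fills metadata from configured per-group key prevalences
and marginal rates chosen to resemble current practice in generic-level
insect taxonomy (roughly three-quarters of papers openly available,
two-thirds discoverable by the word "key", a quarter diagnosing every keyed
taxon, habitus images near-universal).

What passing tests therefore show: the detectors are exact on the defect
*definitions*, the bounds and their generator endpoints are correct, and
the pipeline is deterministic and round-trip faithful. What they do not
show: recall on real prose, whose wording is far more varied than the
template bank; parsing of typographically degraded sources (OCR, PDF
extraction) is explicitly out of scope, as is any judgement of taxonomic
validity or diagnosis content, and no optimizer rebalances keys — the
fan-shapedness criterion flags, it does not restructure.

## Problem sizes

The default test run generates a few thousand keys of 2–45 taxa, 500-key
injection and sandwich experiments, 2000 simulated null corpora for the
chi-square calibration, and exhaustive tree enumeration to 64 leaves;
the whole suite runs in well under a minute. The acceptance script builds
three keys (two 16-taxon, one 128-taxon) and finishes in seconds.
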