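import pytest

from keylint.model import Couplet, Feature, Key, KeyScope, Lead, PaperMetadata

#: the conventional leap-frog example couplet, in standard printed layout
EXAMPLE_COUPLET = (
    "3(2) Head longer than wide; hind tibia with apicoventral spines 9\n"
    "– Head shorter than wide; hind tibia lacking apicoventral spines, surface flat 4\n"
)

MINIMAL_KEY = "1 Wings present Genus A\n– Wings absent Genus B\n"


def lead(ordinal, feats, target, figs=None, ancillary=None):
    kw = {"target_couplet": target} if isinstance(target, int) else {"target_taxon": target}
    return Lead(
        ordinal=ordinal,
        features=[Feature(f) for f in feats],
        figure_refs=list(figs or []),
        ancillary=ancillary,
        **kw,
    )


def couplet(number, l1, l2, *more, retrace=None):
    return Couplet(number=number, leads=[l1, l2, *more], retrace_ref=retrace)


def comb_key(n, key_id="comb", retrace=True):
    """Hand-built caterpillar: couplet i keys out Genus i and continues to
    couplet i+1; the last couplet keys out two taxa."""
    couplets = []
    for i in range(1, n):
        last = i == n - 1
        l1 = lead(1, [f"feature {i} present"], f"Genus_{i:03d}")
        l2 = lead(2, [f"feature {i} absent"], f"Genus_{n:03d}" if last else i + 1)
        couplets.append(couplet(i, l1, l2, retrace=(i - 1 if retrace and i > 1 else None)))
    return Key(key_id=key_id, couplets=couplets)


@pytest.fixture
def example_report():
    from keylint.parser import parse_key

    return parse_key(EXAMPLE_COUPLET, key_id="example")


@pytest.fixture
def optimal_setup():
    """A fully optimal key with matching metadata: every criterion of the
    rubric applicable and satisfied."""
    from keylint.lint import lint_key
    from keylint.metrics import compute_metrics
    from keylint.simulate import generate_topology

    key = generate_topology(8, 1, 3, retracing=True, illustration_rate=1.0)
    key.scope = KeyScope(group_rank="tribe", extent="global", is_emendation=True)
    meta = PaperMetadata(
        paper_id="p1",
        has_key=True,
        freely_available=True,
        key_term_location=("title",),
        scope_statement_present=True,
        scope_statement_location="above-key",
        sex_restriction_stated=True,
        caste_restriction_stated=None,
        diagnosis_coverage="all",
        habitus_present=True,
        habitus_kind="photograph",
        image_placement="adjacent",
        n_new_genera=1,
        n_genera_in_key=8,
        n_new_genera_keyed=1,
        emendation_standalone=True,
    )
    return key, meta, compute_metrics(key), lint_key(key)
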