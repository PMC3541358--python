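import pytest

from cnediv import (
    ExpressionProfile,
    classify_records,
    default_vocabulary,
    load_divergent_gene_table,
)


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def fourway_records():
    """Packaged table of the 11 CNEs with divergent target genes (39 rows)."""
    return load_divergent_gene_table()


@pytest.fixture(scope="session")
def classified_fourway(fourway_records):
    return classify_records(fourway_records)


def make_profiles(cne_id, mouse_domains, zebrafish_domains):
    return (
        ExpressionProfile(cne_id, "mouse", "transgenic", frozenset(mouse_domains)),
        ExpressionProfile(cne_id, "zebrafish", "transgenic", frozenset(zebrafish_domains)),
    )


@pytest.fixture(scope="session")
def worked_profile_pairs():
    """Three worked comparisons: one global, one partial, one identical."""
    return {
        "Hs608": make_profiles("Hs608", {"DRG", "spinal cord"}, {"forebrain"}),
        "Hs278": make_profiles("Hs278", {"hindbrain", "spinal cord"}, {"spinal cord"}),
        "Hs123": make_profiles("Hs123", {"forebrain"}, {"forebrain"}),
    }
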