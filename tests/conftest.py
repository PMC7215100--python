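import pytest

from repotax import (
    ClassLabel,
    Indication,
    RepositioningCase,
    TargetProtein,
    classify_all,
    filter_eligible,
    load_case_fixture,
    load_fixture_sequences,
    parse_mesh_root_key,
)


def make_case(
    drug="drug",
    modality="small_molecule",
    orig_mesh="C04",
    sec_mesh="C10",
    orig_targets=(),
    sec_targets=(),
):
    """Terse case builder; targets given as ids or (id, kind) pairs."""

    def _targets(entries):
        out = []
        for t in entries:
            if isinstance(t, tuple):
                out.append(TargetProtein(t[0], molecule_kind=t[1]))
            else:
                out.append(TargetProtein(t))
        return frozenset(out)

    return RepositioningCase(
        drug_name=drug,
        modality=modality,
        original=Indication(label=orig_mesh, mesh_key=parse_mesh_root_key(orig_mesh)),
        secondary=Indication(label=sec_mesh, mesh_key=parse_mesh_root_key(sec_mesh)),
        original_targets=_targets(orig_targets),
        secondary_targets=_targets(sec_targets),
    )


@pytest.fixture(scope="session")
def fixture_cases():
    return load_case_fixture()


@pytest.fixture(scope="session")
def fixture_sequences():
    return load_fixture_sequences()


@pytest.fixture(scope="session")
def fixture_kept(fixture_cases):
    return filter_eligible(fixture_cases).kept


@pytest.fixture(scope="session")
def fixture_summary(fixture_kept, fixture_sequences):
    return classify_all(fixture_kept, fixture_sequences)
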