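from __future__ import annotations

import pytest

from slimcons.orthologs import OrthologGroup


def make_group(rows: dict[str, str], reference_species: str = "Scer",
               reference_id: str = "P0001") -> OrthologGroup:
    return OrthologGroup(
        reference_id=reference_id,
        reference_species=reference_species,
        rows=dict(rows),
        protein_ids={sp: reference_id for sp in rows},
    )


@pytest.fixture
def group_factory():
    return make_group
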