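import pytest

from ethnogarden import (
    Inventory,
    LifeForm,
    PlantRecord,
    UseCategory,
    load_laershan_fixture,
)


@pytest.fixture(scope="session")
def laershan() -> Inventory:
    """The packaged Laershan Plateau survey (152 species)."""
    return load_laershan_fixture()


def make_record(
    name: str,
    voucher: str | None = None,
    cats: tuple[str, ...] = ("edible",),
    towns: tuple[str, ...] = ("HK",),
    parts: tuple[str, ...] = (),
    life: str = "herb",
    **kwargs,
) -> PlantRecord:
    """Terse record builder for hand-constructed inventories."""
    return PlantRecord(
        voucher_code=voucher or name.replace(" ", "_"),
        scientific_name=name,
        local_name="",
        family=kwargs.pop("family", "Testaceae"),
        life_form=LifeForm(life),
        townships=frozenset(towns),
        use_categories=frozenset(UseCategory(c) for c in cats),
        parts_used=frozenset(parts),
        **kwargs,
    )


@pytest.fixture
def record_factory():
    return make_record
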