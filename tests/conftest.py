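import pytest

from scatdiet import (
    DietItem,
    FilterConfig,
    ScatComposition,
    ScatStatus,
    TaxonRecord,
    Taxonomy,
)


@pytest.fixture
def taxonomy():
    """Small fixture taxonomy: five prey taxa and three carnivores."""
    return Taxonomy(
        [
            TaxonRecord("red_fox", "Mammalia", "Carnivora", "Canidae", "Vulpes", "Vulpes vulpes", True),
            TaxonRecord("coyote", "Mammalia", "Carnivora", "Canidae", "Canis", "Canis latrans", True),
            TaxonRecord("bobcat", "Mammalia", "Carnivora", "Felidae", "Lynx", "Lynx rufus", True),
            TaxonRecord("ground_squirrel", "Mammalia", "Rodentia", "Sciuridae", "Callospermophilus", "Callospermophilus lateralis", False),
            TaxonRecord("deer_mouse", "Mammalia", "Rodentia", "Cricetidae", "Peromyscus", "Peromyscus maniculatus", False),
            TaxonRecord("vole", "Mammalia", "Rodentia", "Cricetidae", "Myodes", "Myodes californicus", False),
            TaxonRecord("hare", "Mammalia", "Lagomorpha", "Leporidae", "Lepus", "Lepus americanus", False),
            TaxonRecord("chipmunk", "Mammalia", "Rodentia", "Sciuridae", "Tamias", "", False),
            TaxonRecord("grouse", "Aves", "Galliformes", "Phasianidae", "Dendragapus", "Dendragapus fuliginosus", False),
        ]
    )


@pytest.fixture
def config():
    return FilterConfig()


def make_scat(scat_id, items, defecator="red_fox", status=ScatStatus.ASSIGNED):
    """Build an assigned ScatComposition from taxon → share (reads faked)."""
    diet = {
        taxon: DietItem(combined_reads=int(share * 10000), share=share)
        for taxon, share in items.items()
    }
    return ScatComposition(
        scat_id=scat_id, status=status, defecator=defecator, diet_items=diet
    )


@pytest.fixture
def make_composition():
    return make_scat
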