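import textwrap

import pytest

from ssrkit import GenotypePanel, Locus, PlantRecord, read_panel


@pytest.fixture
def tiny_csv(tmp_path):
    """Three plants, two varieties, three loci; includes a dropout."""
    text = textwrap.dedent(
        """\
        plant_id,variety,breeder,ploidy,loc1,loc2,loc3
        P1,VarA,KWS,2,201;293,135,
        P2,VarA,KWS,2,201,135;138,250
        P3,VarB,SES,3,201;240;293,138,250;253
        """
    )
    path = tmp_path / "tiny.csv"
    path.write_text(text)
    return path


@pytest.fixture
def tiny_panel(tiny_csv):
    return read_panel(tiny_csv)


def make_panel(calls_by_plant, loci_alleles, ploidy=2, varieties=None, breeders=None):
    """Build a panel from {plant: {locus: set(labels) | None}} plus a registry.

    loci_alleles: {locus: [labels...]}; lengths are synthesised as
    100 + 2*index so tests can ignore them.
    """
    loci = [
        Locus(name, tuple(labels), {a: 100 + 2 * i for i, a in enumerate(labels)})
        for name, labels in loci_alleles.items()
    ]
    plants = []
    for pid, calls in calls_by_plant.items():
        variety = (varieties or {}).get(pid, "V1")
        breeder = (breeders or {}).get(pid, "B1")
        pl = ploidy[pid] if isinstance(ploidy, dict) else ploidy
        norm = {
            loc: (None if c is None else frozenset(c)) for loc, c in calls.items()
        }
        plants.append(PlantRecord(pid, variety, breeder, pl, norm))
    return GenotypePanel(loci, plants)
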