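from __future__ import annotations

import pytest

import barcodeval as bv


def make_records(spec: list[tuple[str, str, str, str, str]]) -> list[bv.SpecimenRecord]:
    return [bv.SpecimenRecord(*row) for row in spec]


@pytest.fixture
def toy_records() -> list[bv.SpecimenRecord]:
    """Two species in one genus, one species in another family; 5 specimens."""
    return make_records(
        [
            ("a1", "Alpha one", "Alpha", "Alphaceae", "BB"),
            ("a2", "Alpha one", "Alpha", "Alphaceae", "JJYL"),
            ("b1", "Alpha two", "Alpha", "Alphaceae", "BB"),
            ("b2", "Alpha two", "Alpha", "Alphaceae", "BB"),
            ("c1", "Gamma three", "Gamma", "Gammaceae", "LSL"),
        ]
    )


@pytest.fixture
def toy_dataset(toy_records) -> bv.Dataset:
    aln = bv.LocusAlignment(
        "rbcL",
        ["a1", "a2", "b1", "b2", "c1"],
        [
            "AAAAACGTGC",
            "AAAAACGTGC",
            "AAAATTGTGC",
            "AAAATTGTGC",
            "CCGGTTAAAT",
        ],
    )
    return bv.Dataset(toy_records, {"rbcL": aln})


@pytest.fixture
def clean_sim_config() -> bv.SimConfig:
    """Well-separated barcode gap, full recovery, no injected errors."""
    return bv.SimConfig(
        n_families=3,
        genera_per_family=2,
        species_per_genus=2,
        samples_per_species=(2, 3),
        loci=(
            bv.LocusConfig("rbcL", 1000),
            bv.LocusConfig("matK", 1000),
        ),
        misid_rate=0.0,
        between_plot_extra=0.0,
        seed=101,
    )
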