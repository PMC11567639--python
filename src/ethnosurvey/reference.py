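"""Reference dataset: plants used for vernacular building in Ghana.

A published ethnobotanical survey of 258 vernacular-building artisans in
the Volta Region of Ghana documented 26 plant species across six building
elements (main pole, main beam, wall lath, roof lath, binding material,
thatch material).  Its summary statistics — per-species use reports and
citation frequencies together with per-element fidelity levels — pin down
the full species-by-element informant count matrix, which is recorded
here and expanded on demand into a synthetic record-level table with
exactly those margins.

The expansion assigns informant codes deterministically: each species'
citing informants are the first FC_s codes of the 258-strong pool, and
every informant citing a species also cites it for the species' anchor
(highest-count) element, so each species keeps one 100% fidelity element.
Which *individual* informant made which mention is not recoverable from
the published margins, so record-level structure beyond the margins
(informant specialisation, co-citation patterns) is synthetic.  Every
statistic computed by this package — UR, FC, NU, CI, RFC, RI, CVe per
species, Nur/Ns/IAR per element, and all FL percentages — depends on the
margins only and is therefore exact.
"""

from __future__ import annotations

from ethnosurvey.survey_data import StudyDesign, UseReportTable, table_from_records

__all__ = [
    "REFERENCE_N_INFORMANTS",
    "REFERENCE_CATEGORIES",
    "REFERENCE_COUNTS",
    "REFERENCE_SPECIES_META",
    "reference_design",
    "reference_table",
]

REFERENCE_N_INFORMANTS = 258

REFERENCE_CATEGORIES: tuple[str, ...] = (
    "main pole",
    "main beam",
    "wall lath",
    "roof lath",
    "binding material",
    "thatch material",
)

#: Species-by-element informant counts (UR_su).  A species' citation
#: frequency FC equals its largest element count (the anchor element is
#: cited by every informant citing the species); its UR is the row sum.
REFERENCE_COUNTS: dict[str, dict[str, int]] = {
    "bambusa vulgaris": {
        "main beam": 110,
        "wall lath": 88,
        "roof lath": 162,
        "thatch material": 80,
    },
    "borassus aethiopum": {"main beam": 211, "roof lath": 195},
    "elaeis guineensis": {"wall lath": 251, "thatch material": 146},
    "senna siamea": {"main pole": 88, "main beam": 107, "roof lath": 93},
    "azadirachta indica": {"main pole": 103, "main beam": 73, "roof lath": 89},
    "funtumia africana": {"main pole": 61, "main beam": 138},
    "rhipsalis baccifera": {"binding material": 187},
    "raphia palma-pinus": {"thatch material": 175},
    "antiaris toxicaria": {"main pole": 163},
    "bridelia ferruginea": {"main pole": 137},
    "baphia nitida": {"main pole": 130},
    "cryptolepis nigrescens": {"binding material": 127},
    "andropogon gayanus": {"thatch material": 124},
    "musa sapientum": {"binding material": 121},
    "anogeissus leiocarpa": {"main pole": 110},
    "gardenia ternifolia": {"main pole": 101},
    "leucaena leucocephala": {"main beam": 91},
    "eremospatha macrocarpa": {"binding material": 83},
    "avicennia germinans": {"main pole": 81},
    "cyperus papyrus": {"thatch material": 79},
    "tectona grandis": {"main pole": 74},
    "cocos nucifera": {"thatch material": 73},
    "tamarindus indica": {"main pole": 68},
    "diospyros mespiliformis": {"main pole": 67},
    "raphia hookeri": {"thatch material": 62},
    "typha domingensis": {"thatch material": 61},
}

REFERENCE_SPECIES_META: dict[str, dict[str, str]] = {
    "bambusa vulgaris": {"family": "Poaceae", "local_name": "Pamploti", "status": "LC"},
    "borassus aethiopum": {"family": "Arecaceae", "local_name": "Agorti", "status": "LC"},
    "elaeis guineensis": {"family": "Arecaceae", "local_name": "Deti", "status": "LC"},
    "senna siamea": {"family": "Fabaceae", "local_name": "Zangarati", "status": "LC"},
    "azadirachta indica": {"family": "Meliaceae", "local_name": "Liliti", "status": "LC"},
    "funtumia africana": {"family": "Apocynaceae", "local_name": "Kpomi", "status": "LC"},
    "rhipsalis baccifera": {"family": "Cactaceae", "local_name": "Adzorka", "status": "LC"},
    "raphia palma-pinus": {"family": "Arecaceae", "local_name": "Ebe", "status": "NT"},
    "antiaris toxicaria": {"family": "Moraceae", "local_name": "Logo", "status": "LC"},
    "bridelia ferruginea": {"family": "Phyllanthaceae", "local_name": "Akamiti", "status": "LC"},
    "baphia nitida": {"family": "Fabaceae", "local_name": "Toti", "status": "LC"},
    "cryptolepis nigrescens": {"family": "Apocynaceae", "local_name": "Globo", "status": "NE"},
    "andropogon gayanus": {"family": "Poaceae", "local_name": "-", "status": "NE"},
    "musa sapientum": {"family": "Musaceae", "local_name": "Toworka", "status": "LC"},
    "anogeissus leiocarpa": {"family": "Combretaceae", "local_name": "Hehe", "status": "LC"},
    "gardenia ternifolia": {"family": "Rubiaceae", "local_name": "Efeti", "status": "LC"},
    "leucaena leucocephala": {"family": "Fabaceae", "local_name": "Klikagbe", "status": "NE"},
    "eremospatha macrocarpa": {"family": "Arecaceae", "local_name": "Mfia", "status": "LC"},
    "avicennia germinans": {"family": "Acanthaceae", "local_name": "Amuti", "status": "LC"},
    "cyperus papyrus": {"family": "Cyperaceae", "local_name": "Keti", "status": "LC"},
    "tectona grandis": {"family": "Lamiaceae", "local_name": "Teak", "status": "EN"},
    "cocos nucifera": {"family": "Arecaceae", "local_name": "Neti", "status": "NE"},
    "tamarindus indica": {"family": "Fabaceae", "local_name": "Eforti", "status": "LC"},
    "diospyros mespiliformis": {"family": "Ebenaceae", "local_name": "Keyi", "status": "LC"},
    "raphia hookeri": {"family": "Arecaceae", "local_name": "Alati", "status": "LC"},
    "typha domingensis": {"family": "Typhaceae", "local_name": "Ava", "status": "LC"},
}


def reference_design() -> StudyDesign:
    """The survey frame: N=258 respondents, six building elements."""
    return StudyDesign(REFERENCE_N_INFORMANTS, REFERENCE_CATEGORIES)


def _informant_code(i: int) -> str:
    return f"I{i:03d}"


def reference_table(with_meta: bool = True) -> UseReportTable:
    """Expand the count matrix into a record-level use-report table.

    For each species the first FC_s informant codes cite it; the anchor
    element is cited by all of them and every other element by the first
    UR_su of them.  The expansion is deterministic and reproduces all
    published margins exactly (4109 records over 26 species).
    """
    records: list[tuple[str, str, str]] = []
    for species, counts in REFERENCE_COUNTS.items():
        for category, n in counts.items():
            records.extend(
                (_informant_code(i), species, category) for i in range(1, n + 1)
            )
    return table_from_records(
        records,
        design=reference_design(),
        species_meta=REFERENCE_SPECIES_META if with_meta else None,
    )
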