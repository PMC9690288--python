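"""Bookkeeping for the arctic fox study cohort the pipeline was built around.

The published survey sampled arctic foxes (*Vulpes lagopus*) across northern
Eurasia, from the fragmented Fennoscandian range edge to the large Siberian
populations.  The sampling-area table below (population, country, area,
collection years, individuals) is the cohort input for sample-count
bookkeeping and grouping; genotype data itself is consumed from VCF.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["study_cohort", "total_genomes", "FENNOSCANDIA", "SIBERIA"]

# sampling areas belonging to each regional grouping used in the tests
FENNOSCANDIA = ("Vindelfjällen", "Arjeplog", "Saltfjellet", "Reisa nord",
                "Varangerhalvøya", "Øvre Dividal", "Kola")
SIBERIA = ("Indigirka", "Yamal", "Taymyr", "Faddeyevsky Island", "Wrangel Island")

_ROWS = [
    # population, country, sample_area, years, n (n_new sequenced for the study)
    ("Fennoscandia", "Sweden", "Vindelfjällen", "1989-2019", 15, 0),
    ("Fennoscandia", "Sweden", "Arjeplog", "2008-2019", 11, 5),
    ("Fennoscandia", "Norway", "Saltfjellet", "2007", 1, 0),
    ("Fennoscandia", "Norway", "Reisa nord", "2007", 1, 0),
    ("Fennoscandia", "Norway", "Varangerhalvøya", "2011", 1, 0),
    ("Fennoscandia", "Norway", "Øvre Dividal", "2005", 1, 0),
    ("Fennoscandia", "Russia", "Kola", "1990s", 1, 0),
    ("Siberia", "Russia", "Indigirka", "1994", 1, 1),
    ("Siberia", "Russia", "Yamal", "1994-2011", 4, 0),
    ("Siberia", "Russia", "Taymyr", "1994", 5, 4),
    ("Siberia", "Russia", "Faddeyevsky Island", "1994", 1, 1),
    ("Siberia", "Russia", "Wrangel Island", "2008", 1, 1),
]


def study_cohort() -> pd.DataFrame:
    """Sampling-area summary of the sequenced cohort."""
    return pd.DataFrame(
        _ROWS,
        columns=["population", "country", "sample_area", "years", "n", "n_new"],
    )


def total_genomes() -> int:
    """Total whole genomes in the cohort (sum of the per-area counts)."""
    return int(study_cohort()["n"].sum())
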