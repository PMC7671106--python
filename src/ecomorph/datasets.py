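"""Packaged example data: the sculpin (Cottoidea) prey-trait and diet tables.

Two small fixtures ship with the package, transcribed verbatim from the
printed tables of the cottoid ecomorphology study the package's methods are
modelled on:

* ``prey_traits``: 29 prey items x 25 binary functional traits;
* ``diet_importance``: 54 sculpin species with habitat, published synthetic
  and coarse diet labels, and the summed importance of each of the six
  published prey categories in each species' diet.

``PUBLISHED_CATEGORIES`` records the six prey-category memberships reported
by that study, used for comparison against de novo clustering.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_prey_traits
from .prey import PreyTraitMatrix

__all__ = [
    "load_prey_traits",
    "load_diet_importance",
    "PUBLISHED_CATEGORIES",
    "CATEGORY_COLUMNS",
]

CATEGORY_COLUMNS = (
    "Vermes",
    "Stationary benthic items",
    "Tentacles and appendages",
    "Benthic arthropods",
    "Pelagic arthropods",
    "Squishy swimmers",
)

PUBLISHED_CATEGORIES: dict[str, frozenset[str]] = {
    "Benthic arthropods": frozenset({
        "Cumacea", "Isopoda", "Gammaridae", "Insecta", "Crab",
        "Hermit crab", "Crayfish", "Pandalid shrimp",
    }),
    "Pelagic arthropods": frozenset({
        "Ostracoda", "Euphausiidae", "Pelagic amphipod", "Copepoda", "Mysidae",
    }),
    "Stationary benthic items": frozenset({
        "Eggs", "Algae and plant matter", "Detritus",
    }),
    "Squishy swimmers": frozenset({"Octopus", "Fishes", "Larval fishes"}),
    "Tentacles and appendages": frozenset({
        "Barnacle cirri", "Anemone", "Ctenophora",
    }),
    "Vermes": frozenset({
        "Bivalvia", "Gastropoda", "Leech", "Polychaete annelid",
        "Planaria", "Oligochaeta", "Sipuncula",
    }),
}


def _data_path(name: str):
    return resources.files("ecomorph").joinpath("data", name)


def load_prey_traits() -> PreyTraitMatrix:
    """The 29 x 25 binary prey-item functional-trait matrix."""
    with resources.as_file(_data_path("prey_traits.csv")) as p:
        return read_prey_traits(p)


def load_diet_importance() -> pd.DataFrame:
    """Per-species prey-category importances with habitat and published labels.

    Columns: species, habitat, synthetic_category, coarse_category, and one
    importance column per prey category.  Importances are printed at two
    decimals and rows need not sum to 1 (unclassified diet remainder).
    """
    with resources.as_file(_data_path("diet_importance.csv")) as p:
        return pd.read_csv(p)
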