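"""Registry of the 18 modelled true-mangrove species.

The registry ships with the package as a small CSV: species code,
scientific name, family, IUCN Red List category (LC/NT/EN), the number of
archival occurrence records and GPS-verified field records used in the
Sundarban Biosphere Reserve study system, and the intertidal position the
species typically occupies (low/middle/high shore, or mixed).

A second packaged table holds the published per-species evaluation scores
(intrinsic ROC/TSS/KAPPA of the ensemble models and the extrinsic Boyce
index) used to exercise the report-summarisation code.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

IUCN_SCORES = {"LC": 1, "NT": 2, "EN": 3}
INTERTIDAL_POSITIONS = ("low", "middle", "high", "mixed")


class UnknownSpeciesError(KeyError):
    """A species code is not in the registry."""


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("mangrovesdm.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_species_registry() -> pd.DataFrame:
    """The 18-species registry, indexed by two-letter species code."""
    df = _read_packaged("species_registry.csv").set_index("code")
    bad = set(df["iucn_status"]) - set(IUCN_SCORES)
    if bad:
        raise ValueError(f"unknown IUCN categories in registry: {bad}")
    return df


def load_evaluation_scores() -> pd.DataFrame:
    """Published per-species evaluation scores (ROC, TSS, KAPPA, Boyce)."""
    return _read_packaged("evaluation_scores.csv")


def species_codes() -> list[str]:
    return list(load_species_registry().index)


def validate_codes(codes, registry: pd.DataFrame | None = None) -> None:
    known = set((registry if registry is not None else load_species_registry()).index)
    unknown = sorted(set(codes) - known)
    if unknown:
        raise UnknownSpeciesError(f"species code(s) not in registry: {unknown}")
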