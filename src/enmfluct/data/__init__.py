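"""Bundled parameter tables.

The sequence-specific (``sanm``) and sequence+distance-dependent
(``sdanm``) stiffness tables shipped here are *synthetic* stand-ins: full
20×20 parameterisations generated from a hydrophobicity-derived
per-residue factor, pinned to the published anchor values of the original
parameterisation (glycine–glycine 0.226, isoleucine–valine 2.348 for the
sequence-specific dialect; far-range softness 10⁻³ and a 16.5 Å
interaction radius for the distance-binned dialect).  They reproduce the
published heterogeneity — roughly one order of magnitude between the
softest and stiffest pairs — but individual entries beyond the anchors
are not the published constants.  Both files are plain TSV and can be
replaced by externally supplied tables without code changes.

The chemical decision table maps each standard residue to hydrophobic /
polar / charged and is likewise replaceable data.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

__all__ = [
    "data_path",
    "sanm_table",
    "sdanm_table",
    "chemical_classes",
    "SANM_BACKBONE_KAPPA",
    "SDANM_BACKBONE_KAPPA",
]

#: Backbone (sequence-adjacent) stiffness constants of the published
#: parameterisations.
SANM_BACKBONE_KAPPA = 10.0
SDANM_BACKBONE_KAPPA = 43.52


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(resources.files(__package__) / name)


@lru_cache(maxsize=None)
def sanm_table():
    """Bundled sequence-specific stiffness table (synthetic stand-in)."""
    from ..network import load_stiffness_table

    return load_stiffness_table(data_path("sanm_stiffness_synthetic.tsv"), "pairwise")


@lru_cache(maxsize=None)
def sdanm_table():
    """Bundled distance-binned stiffness table (synthetic stand-in)."""
    from ..network import load_stiffness_table

    return load_stiffness_table(data_path("sdanm_stiffness_synthetic.tsv"), "distance_binned")


@lru_cache(maxsize=None)
def chemical_classes() -> dict[str, str]:
    """Residue → hydrophobic/polar/charged mapping from the bundled table."""
    mapping: dict[str, str] = {}
    for line in data_path("chemical_classes.tsv").read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("residue"):
            continue
        res, cls = line.split("\t")
        mapping[res] = cls
    return mapping
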