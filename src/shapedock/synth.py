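"""Seeded synthetic fixtures: molecules, parent/anion pairs, enthalpy tables.

Everything here is a pure function of its seed so tests are
bit-reproducible without any downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .mol_io import Atom, AtomMap, Molecule
from .thermo import (
    ReferenceEnthalpies,
    Role,
    SpeciesEnthalpy,
    WATER_REFERENCES,
)

__all__ = [
    "FixtureSpec",
    "random_molecule",
    "make_anion_pair",
    "synth_enthalpy_table",
]

_BOX_EDGE = 10.0  # Å, coordinates drawn uniformly in [0, _BOX_EDGE)^3


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible random molecule."""

    k: int
    elements: tuple[str, ...]
    seed: int
    perturbation: float = 0.0
    delete_hydrogen: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError(f"k must be >= 4, got {self.k}")
        if len(self.elements) != self.k:
            raise ValueError(f"need {self.k} element symbols, got {len(self.elements)}")
        if self.perturbation < 0:
            raise ValueError("perturbation sigma must be >= 0")


def random_molecule(spec: FixtureSpec) -> Molecule:
    """Molecule with elements in spec order and uniform coordinates in a
    10 Å cube, deterministic under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    coords = rng.uniform(0.0, _BOX_EDGE, size=(spec.k, 3))
    atoms = [
        Atom(i, el, f"{el}{i + 1}", coords[i])
        for i, el in enumerate(spec.elements)
    ]
    return Molecule(f"synth_seed{spec.seed}", atoms, {"format": "synthetic"})


def make_anion_pair(
    parent: Molecule, site_hydrogen: int, sigma: float, seed: int
) -> tuple[Molecule, AtomMap]:
    """Deprotonated variant: delete one H, jitter the rest isotropically.

    Returns the variant plus the ground-truth atom map (the deleted parent
    hydrogen is the single unmatched atom).
    """
    if not 0 <= site_hydrogen < len(parent):
        raise ValueError(f"atom index {site_hydrogen} out of range")
    if parent.atoms[site_hydrogen].element != "H":
        raise ValueError(
            f"atom {site_hydrogen} is {parent.atoms[site_hydrogen].element}, not H"
        )
    rng = np.random.default_rng(seed)
    keep = [i for i in range(len(parent)) if i != site_hydrogen]
    coords = parent.coords[keep]
    if sigma > 0:
        coords = coords + rng.normal(scale=sigma, size=coords.shape)
    atoms = [
        Atom(new, parent.atoms[old].element, parent.atoms[old].label, coords[new])
        for new, old in enumerate(keep)
    ]
    variant = Molecule(f"{parent.name}_anion{site_hydrogen}", atoms, {"format": "synthetic"})
    amap = AtomMap(
        pairs=[(old, new) for new, old in enumerate(keep)],
        unmatched_a=[site_hydrogen],
    )
    return variant, amap


def synth_enthalpy_table(
    targets: Mapping[str, tuple[float, float]],
    ip: Optional[float] = None,
    ref: ReferenceEnthalpies = WATER_REFERENCES,
    base_h: float = 0.0,
    compound: str = "synthetic",
) -> list[SpeciesEnthalpy]:
    """Species enthalpies that reproduce chosen (BDE, PA) per site and IP.

    Inverts the descriptor definitions: the parent sits at ``base_h`` and
    each radical/anion (and the cation-radical, when ``ip`` is given) is
    placed so that the computed descriptors equal the targets exactly.
    ETE and PDE then follow from the cycle identities.
    """
    species = [
        SpeciesEnthalpy(compound=compound, site="parent", role=Role.PARENT, h=base_h)
    ]
    if ip is not None:
        species.append(
            SpeciesEnthalpy(
                compound=compound,
                site="parent",
                role=Role.CATION_RADICAL,
                h=ip - ref.h_electron + base_h,
            )
        )
    for site, (bde, pa) in targets.items():
        species.append(
            SpeciesEnthalpy(
                compound=compound,
                site=site,
                role=Role.RADICAL,
                h=bde - ref.h_hydrogen_atom + base_h,
            )
        )
        species.append(
            SpeciesEnthalpy(
                compound=compound,
                site=site,
                role=Role.ANION,
                h=pa - ref.h_proton + base_h,
            )
        )
    return species
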