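"""Loaders for the small reference tables shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .thermo import DescriptorTable, WATER_REFERENCES

__all__ = [
    "load_published_descriptors",
    "published_descriptor_tables",
    "load_published_shape_distances",
]


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.files("shapedock.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_published_descriptors() -> pd.DataFrame:
    """Literature per-site BDE/PA/ETE/IP/PDE values (kcal/mol) for the four
    betalain study compounds in water."""
    return _read_tsv("betalain_descriptors.tsv")


def published_descriptor_tables() -> dict[str, DescriptorTable]:
    """The same values as one :class:`DescriptorTable` per compound."""
    frame = load_published_descriptors()
    out: dict[str, DescriptorTable] = {}
    for compound, group in frame.groupby("compound", sort=False):
        values = {
            row["site"]: {d: row[d] for d in ("BDE", "PA", "ETE", "IP", "PDE")}
            for _, row in group.iterrows()
        }
        out[compound] = DescriptorTable.from_values(
            compound, values, reference=WATER_REFERENCES
        )
    return out


def load_published_shape_distances() -> pd.DataFrame:
    """Literature parent-vs-anion shape distances (3-decimal display) with
    the matching proton affinities."""
    return _read_tsv("betalain_shape_distances.tsv")
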