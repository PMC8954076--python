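"""Antioxidant-mechanism thermodynamic descriptors from species enthalpies.

Five descriptors per deprotonation site, all in kcal/mol:

    BDE = H(ArO.)   + H(H.)  - H(ArOH)        (HAT, first step)
    PA  = H(ArO-)   + H(H+)  - H(ArOH)        (SPLET, first step)
    ETE = H(ArO.)   + H(e-)  - H(ArO-)        (SPLET, second step)
    IP  = H(ArOH.+) + H(e-)  - H(ArOH)        (SET-PT, first step)
    PDE = H(ArO.)   + H(H+)  - H(ArOH.+)      (SET-PT, second step)

These satisfy the exact cycle identities BDE = PA + ETE + delta and
BDE = IP + PDE + delta with delta = H(H.) - H(H+) - H(e-), which
``cycle_residuals`` verifies (to machine precision for internally computed
tables, to rounding tolerance for externally printed ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

__all__ = [
    "HARTREE_TO_KCAL",
    "ReferenceEnthalpies",
    "WATER_REFERENCES",
    "Role",
    "SpeciesEnthalpy",
    "DescriptorTable",
    "MechanismVerdict",
    "compute_descriptors",
    "cycle_residuals",
    "rank_sites",
    "classify_mechanism",
    "rd_pa_concordance",
    "read_species_table",
]

HARTREE_TO_KCAL = 627.5095

DESCRIPTORS = ("BDE", "PA", "ETE", "IP", "PDE")

#: tolerance for cycle residuals of tables printed at one decimal
PRINTED_TABLE_TOL = 0.15
#: tolerance for internally computed tables
INTERNAL_TOL = 1e-10


@dataclass(frozen=True)
class ReferenceEnthalpies:
    """Solvated enthalpies of H+, e- and H. in kcal/mol."""

    h_proton: float = -259.00
    h_electron: float = -55.61
    h_hydrogen_atom: float = -314.65

    @property
    def delta(self) -> float:
        """H(H.) - H(H+) - H(e-): the constant closing both cycles."""
        return self.h_hydrogen_atom - self.h_proton - self.h_electron


#: aqueous-phase reference values used throughout
WATER_REFERENCES = ReferenceEnthalpies()


class Role(str, Enum):
    PARENT = "parent"
    RADICAL = "radical"
    ANION = "anion"
    CATION_RADICAL = "cation_radical"


@dataclass(frozen=True)
class SpeciesEnthalpy:
    """Enthalpy of one chemical species of a compound's reaction network."""

    compound: str
    site: str  # deprotonation-site label, or "parent" for site-free species
    role: Role
    h: float
    unit: str = "kcal/mol"

    def __post_init__(self) -> None:
        if self.unit not in ("kcal/mol", "hartree"):
            raise ValueError(f"unit must be 'kcal/mol' or 'hartree', got {self.unit!r}")
        if not np.isfinite(self.h):
            raise ValueError(f"non-finite enthalpy for {self.compound}/{self.site}")

    @property
    def h_kcal(self) -> float:
        return self.h * HARTREE_TO_KCAL if self.unit == "hartree" else self.h


@dataclass
class DescriptorTable:
    """Per-site descriptor values (kcal/mol) for one compound.

    ``rows`` is indexed by site label with columns BDE/PA/ETE/IP/PDE; the
    IP column is constant over sites (it involves no site-specific
    species).  Missing cells are NaN.
    """

    compound: str
    rows: pd.DataFrame
    reference: ReferenceEnthalpies = field(default_factory=ReferenceEnthalpies)

    @property
    def sites(self) -> list[str]:
        return list(self.rows.index)

    def __getitem__(self, site: str) -> pd.Series:
        return self.rows.loc[site]

    @classmethod
    def from_values(
        cls,
        compound: str,
        values: Mapping[str, Mapping[str, float]],
        reference: ReferenceEnthalpies = WATER_REFERENCES,
    ) -> "DescriptorTable":
        """Build a table directly from per-site descriptor values.

        For externally published tables; no cycle consistency is assumed
        (use :func:`cycle_residuals` to check it).
        """
        rows = pd.DataFrame.from_dict(values, orient="index")
        rows = rows.reindex(columns=list(DESCRIPTORS))
        return cls(compound=compound, rows=rows, reference=reference)


def compute_descriptors(
    species: Iterable[SpeciesEnthalpy],
    ref: ReferenceEnthalpies = WATER_REFERENCES,
) -> DescriptorTable:
    """Compute the descriptor table of one compound from species enthalpies.

    Requires exactly one parent and at most one cation-radical; radicals
    and anions are keyed by site.  A missing species leaves the dependent
    cells NaN with a warning.  Hartree inputs are converted at
    627.5095 kcal/mol per hartree.
    """
    species = list(species)
    if not species:
        raise ValueError("no species given")
    compounds = sorted({s.compound for s in species})
    if len(compounds) != 1:
        raise ValueError(f"one compound per table; got {compounds}")
    compound = compounds[0]

    parents = [s for s in species if s.role == Role.PARENT]
    cations = [s for s in species if s.role == Role.CATION_RADICAL]
    if len(parents) != 1:
        raise ValueError(f"{compound}: need exactly one parent species, got {len(parents)}")
    if len(cations) > 1:
        raise ValueError(f"{compound}: at most one cation_radical, got {len(cations)}")
    h_parent = parents[0].h_kcal
    h_cation = cations[0].h_kcal if cations else None

    radicals: dict[str, float] = {}
    anions: dict[str, float] = {}
    site_order: list[str] = []
    for s in species:
        if s.role in (Role.RADICAL, Role.ANION):
            bucket = radicals if s.role == Role.RADICAL else anions
            if s.site in bucket:
                raise ValueError(f"{compound}: duplicate {s.role.value} for site {s.site}")
            bucket[s.site] = s.h_kcal
            if s.site not in site_order:
                site_order.append(s.site)

    ip = h_cation + ref.h_electron - h_parent if h_cation is not None else np.nan
    if h_cation is None:
        warnings.warn(f"{compound}: no cation_radical species; IP and PDE left empty",
                      stacklevel=2)

    rows = {}
    for site in site_order:
        h_rad = radicals.get(site)
        h_an = anions.get(site)
        if h_rad is None or h_an is None:
            missing = "radical" if h_rad is None else "anion"
            warnings.warn(f"{compound}/{site}: missing {missing} species", stacklevel=2)
        bde = h_rad + ref.h_hydrogen_atom - h_parent if h_rad is not None else np.nan
        pa = h_an + ref.h_proton - h_parent if h_an is not None else np.nan
        ete = (h_rad + ref.h_electron - h_an
               if h_rad is not None and h_an is not None else np.nan)
        pde = (h_rad + ref.h_proton - h_cation
               if h_rad is not None and h_cation is not None else np.nan)
        rows[site] = {"BDE": bde, "PA": pa, "ETE": ete, "IP": ip, "PDE": pde}

    if not rows:
        raise ValueError(f"{compound}: no site species (radical/anion) given")
    frame = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(DESCRIPTORS))
    return DescriptorTable(compound=compound, rows=frame, reference=ref)


def cycle_residuals(
    table: DescriptorTable, ref: Optional[ReferenceEnthalpies] = None
) -> pd.DataFrame:
    """Per-site residuals of the two thermodynamic-cycle identities.

    Columns ``splet`` = BDE - PA - ETE - delta and ``setpt`` =
    BDE - IP - PDE - delta; a row with missing cells yields NaN for the
    affected residual.
    """
    ref = ref or table.reference
    r = table.rows
    out = pd.DataFrame(index=r.index)
    out["splet"] = r["BDE"] - r["PA"] - r["ETE"] - ref.delta
    out["setpt"] = r["BDE"] - r["IP"] - r["PDE"] - ref.delta
    return out


def rank_sites(table: DescriptorTable, by: str = "PA") -> list[str]:
    """Sites ordered ascending by the chosen descriptor.

    Ties keep input order and are reported via warning.
    """
    if by not in DESCRIPTORS:
        raise ValueError(f"unknown descriptor {by!r}")
    col = table.rows[by].dropna()
    if col.empty:
        raise ValueError(f"{table.compound}: descriptor {by} absent for every site")
    order = col.sort_values(kind="stable").index.tolist()
    dup = col[col.duplicated(keep=False)]
    if not dup.empty:
        warnings.warn(
            f"{table.compound}: ties in {by} at value(s) "
            f"{sorted(set(round(v, 6) for v in dup))}; input order kept",
            stacklevel=2,
        )
    return order


@dataclass(frozen=True)
class MechanismVerdict:
    """Favored first-step mechanism and the compared descriptor minima."""

    mechanism: str  # "HAT" | "SPLET" | "SET-PT"
    first_step: dict  # mechanism -> (value, site or None)
    tie: tuple[str, ...] = ()

    @property
    def value(self) -> float:
        return self.first_step[self.mechanism][0]

    @property
    def site(self) -> Optional[str]:
        return self.first_step[self.mechanism][1]


def classify_mechanism(table: DescriptorTable) -> MechanismVerdict:
    """Pick the mechanism whose first-step enthalpy requirement is smallest.

    HAT is gauged by min-over-sites BDE, SPLET by min-over-sites PA and
    SET-PT by the (site-free) IP.  On an exact tie SPLET is preferred over
    HAT over SET-PT and the tie is reported.
    """
    r = table.rows
    candidates: dict[str, tuple[float, Optional[str]]] = {}
    bde = r["BDE"].dropna()
    if not bde.empty:
        candidates["HAT"] = (float(bde.min()), str(bde.idxmin()))
    pa = r["PA"].dropna()
    if not pa.empty:
        candidates["SPLET"] = (float(pa.min()), str(pa.idxmin()))
    ip = r["IP"].dropna()
    if not ip.empty:
        candidates["SET-PT"] = (float(ip.iloc[0]), None)
    if not candidates:
        raise ValueError(f"{table.compound}: no descriptor available for classification")

    preference = {"SPLET": 0, "HAT": 1, "SET-PT": 2}
    winner = min(candidates, key=lambda m: (candidates[m][0], preference[m]))
    best = candidates[winner][0]
    tied = tuple(m for m in candidates if candidates[m][0] == best)
    return MechanismVerdict(
        mechanism=winner,
        first_step=candidates,
        tie=tied if len(tied) > 1 else (),
    )


@dataclass(frozen=True)
class ConcordanceReport:
    tau: float
    n: int
    discordant_pairs: tuple[tuple[str, str], ...]


def rd_pa_concordance(
    pa_by_site: Mapping[str, float], rd_by_site: Mapping[str, float]
) -> ConcordanceReport:
    """Kendall rank concordance between per-site PA and global shape distance.

    Accepts mappings keyed by shared site labels; pairs ordered oppositely
    by the two quantities are listed as discordant.
    """
    shared = [s for s in pa_by_site if s in rd_by_site]
    if len(shared) < 2:
        raise ValueError(f"need >= 2 shared sites, got {len(shared)}")
    pa = np.array([pa_by_site[s] for s in shared], dtype=float)
    rd = np.array([rd_by_site[s] for s in shared], dtype=float)
    tau = float(kendalltau(pa, rd).statistic)
    discordant = []
    for i in range(len(shared)):
        for j in range(i + 1, len(shared)):
            if (pa[i] - pa[j]) * (rd[i] - rd[j]) < 0:
                discordant.append((shared[i], shared[j]))
    return ConcordanceReport(tau=tau, n=len(shared), discordant_pairs=tuple(discordant))


# ---------------------------------------------------------------------------
# species-table input
# ---------------------------------------------------------------------------

def read_species_table(path: Union[str, Path]) -> list[SpeciesEnthalpy]:
    """Read species enthalpies from TSV/CSV (columns compound, site, role,
    H, unit) or JSON (list of objects with the same keys)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = pd.read_json(path).to_dict(orient="records")
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep, comment="#")
        frame.columns = [c.strip().lower() for c in frame.columns]
        records = frame.to_dict(orient="records")
    species = []
    for rec in records:
        rec = {str(k).lower(): v for k, v in rec.items()}
        if "unit" not in rec or (isinstance(rec["unit"], float) and np.isnan(rec["unit"])):
            raise ValueError(f"{path}: every row needs an explicit unit column")
        species.append(
            SpeciesEnthalpy(
                compound=str(rec["compound"]),
                site=str(rec["site"]),
                role=Role(str(rec["role"]).strip().lower()),
                h=float(rec["h"]),
                unit=str(rec["unit"]).strip(),
            )
        )
    return species


def group_by_compound(species: Sequence[SpeciesEnthalpy]) -> dict[str, list[SpeciesEnthalpy]]:
    """Split a mixed species list into per-compound lists, input order kept."""
    out: dict[str, list[SpeciesEnthalpy]] = {}
    for s in species:
        out.setdefault(s.compound, []).append(s)
    return out
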