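"""Similarity-invariant canonical ligand orientation and rotation ensemble.

The canonical *template* places a ligand in a frame defined purely by its
own geometry: axes follow decreasing coordinate variance (principal
directions), while the farthest atom pair — a generalisation of a
two-landmark baseline to 3-D — fixes the axis signs so that the transform
is always a proper rotation.  This removes both ambiguities of a plain
principal-component alignment (axis ordering under near-ties, and
reflections that would invert chirality).

On top of the template, a 10-member ensemble (the template plus 90/180/270
degree rotations in the xy, xz and yz planes) is generated for docking,
together with grid-box configuration files for AutoDock Vina.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import mol_io
from .mol_io import Molecule

__all__ = [
    "TemplateFrame",
    "RotationEnsemble",
    "GridBox",
    "ENSEMBLE_TAGS",
    "farthest_pair",
    "canonical_template",
    "rotation_ensemble",
    "emit_docking_job",
    "collate_scores",
    "parse_vina_affinity",
]

ENSEMBLE_TAGS = (
    "none",
    "xy90", "xy180", "xy270",
    "xz90", "xz180", "xz270",
    "yz90", "yz180", "yz270",
)

_VARIANCE_TIE_TOL = 1e-9


@dataclass(frozen=True)
class TemplateFrame:
    """Rotation/translation taking the input ligand to its canonical frame."""

    rotation: np.ndarray  # 3x3, det = +1; canonical = (x - translation) @ rotation
    translation: np.ndarray  # centroid of the input ligand, Å
    baseline: tuple[int, int]  # farthest atom pair (i < j)
    axis_variances: tuple[float, float, float]  # v_x >= v_y >= v_z, Å^2

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if abs(np.linalg.det(r) - 1.0) > 1e-10:
            raise ValueError(f"rotation must be proper (det=+1), det={np.linalg.det(r)}")
        vx, vy, vz = self.axis_variances
        if not (vx >= vy - 1e-12 and vy >= vz - 1e-12):
            raise ValueError(f"axis variances not ordered: {self.axis_variances}")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=float) - self.translation) @ self.rotation


@dataclass
class RotationEnsemble:
    """Template plus its nine tagged plane rotations."""

    members: list[tuple[str, Molecule]]

    def __post_init__(self) -> None:
        tags = [t for t, _ in self.members]
        if tags != list(ENSEMBLE_TAGS):
            raise ValueError(f"ensemble tags must be {ENSEMBLE_TAGS}, got {tags}")

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, tag: str) -> Molecule:
        for t, m in self.members:
            if t == tag:
                return m
        raise KeyError(tag)

    @property
    def template(self) -> Molecule:
        return self["none"]


@dataclass(frozen=True)
class GridBox:
    """Axis-aligned docking search volume (center + edge lengths, Å)."""

    center: tuple[float, float, float] = (26.0, 10.0, 118.0)
    size: tuple[float, float, float] = (20.0, 20.0, 20.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError(f"grid box sizes must be positive, got {self.size}")


def farthest_pair(mol: Molecule) -> tuple[int, int, float]:
    """Indices (i < j) and distance of the maximally separated atom pair.

    Ties are broken by the lexicographically smallest (i, j).
    """
    x = mol.coords
    k = len(x)
    if k < 2:
        raise ValueError("need at least 2 atoms")
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    dmax = float(d.max())
    tol = 1e-12 * max(dmax, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            if d[i, j] >= dmax - tol:
                return i, j, float(d[i, j])
    raise AssertionError("unreachable")


def _principal_axes(centered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and eigenvector columns of the coordinate
    covariance (second moments about the centroid, divisor k)."""
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def canonical_template(mol: Molecule) -> tuple[TemplateFrame, Molecule]:
    """Canonical similarity-invariant orientation of a ligand.

    The ligand is centered at its centroid and rotated so the coordinate
    variances satisfy v_x >= v_y >= v_z.  Signs are fixed
    deterministically: the x-axis points so that the smaller-index atom of
    the farthest pair has non-positive x; the y-axis so that the atom of
    largest \\|y\\| has positive y (ties to the smaller index); the z sign
    then follows from det = +1.  Physical scale is preserved.

    If adjacent variances tie beyond tolerance, the x-axis falls back to
    the baseline (farthest-pair) direction, with the remaining variance
    split deciding y/z; a warning is emitted.
    """
    if len(mol) < 4:
        raise ValueError(f"need k >= 4 atoms for a canonical frame, got {len(mol)}")
    x = mol.coords
    centroid = x.mean(axis=0)
    centered = x - centroid
    i, j, _ = farthest_pair(mol)

    evals, axes = _principal_axes(centered)
    spread = max(evals[0], 1.0)
    if (evals[0] - evals[1] < _VARIANCE_TIE_TOL * spread
            or evals[1] - evals[2] < _VARIANCE_TIE_TOL * spread):
        warnings.warn(
            "degenerate coordinate variances; falling back to the "
            "baseline-direction frame",
            stacklevel=2,
        )
        ex = centered[j] - centered[i]
        ex = ex / np.linalg.norm(ex)
        residual = centered - np.outer(centered @ ex, ex)
        r_evals, r_axes = _principal_axes(residual)
        ey = r_axes[:, 0]
        axes = np.column_stack([ex, ey, np.cross(ex, ey)])
        evals = np.array([
            float(((centered @ ex) ** 2).mean()),
            float(r_evals[0]),
            float(r_evals[1]),
        ])

    # deterministic sign conventions -> proper rotation
    if centered[i] @ axes[:, 0] > 0:
        axes[:, 0] = -axes[:, 0]
    y_proj = centered @ axes[:, 1]
    top = int(np.argmax(np.abs(y_proj)))  # argmax takes the first of tied maxima
    if y_proj[top] < 0:
        axes[:, 1] = -axes[:, 1]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])

    canonical = centered @ axes
    variances = tuple(float(v) for v in (canonical ** 2).mean(axis=0))
    frame = TemplateFrame(
        rotation=axes,
        translation=centroid,
        baseline=(i, j),
        axis_variances=variances,
    )
    template = mol.with_coords(canonical, name=f"{mol.name}_template")
    return frame, template


_PLANE_AXIS = {"xy": 2, "xz": 1, "yz": 0}  # normal axis index of each rotation plane

# exact sin/cos for multiples of 90 degrees
_EXACT = {90: (0.0, 1.0), 180: (-1.0, 0.0), 270: (0.0, -1.0)}


def _plane_rotation(plane: str, degrees: int) -> np.ndarray:
    c, s = _EXACT[degrees]
    axis = _PLANE_AXIS[plane]
    r = np.zeros((3, 3))
    r[axis, axis] = 1.0
    others = [a for a in range(3) if a != axis]
    r[others[0], others[0]] = c
    r[others[0], others[1]] = s
    r[others[1], others[0]] = -s
    r[others[1], others[1]] = c
    return r


def rotation_ensemble(template: Molecule) -> RotationEnsemble:
    """The template plus its nine exact 90/180/270-degree plane rotations.

    xy-plane rotations are about the z-axis, xz about y, yz about x, all
    applied about the template's centroid with exact (0/±1) trigonometry.
    """
    x = template.coords
    centroid = x.mean(axis=0)
    members: list[tuple[str, Molecule]] = [("none", template)]
    for tag in ENSEMBLE_TAGS[1:]:
        plane, deg = tag[:2], int(tag[2:])
        r = _plane_rotation(plane, deg)
        rotated = (x - centroid) @ r + centroid
        members.append((tag, template.with_coords(rotated, name=f"{template.name}_{tag}")))
    return RotationEnsemble(members=members)


def _vina_config_text(
    receptor: str,
    ligand: str,
    box: GridBox,
    extra: Optional[Mapping[str, object]] = None,
) -> str:
    lines = [
        f"receptor = {receptor}",
        f"ligand = {ligand}",
        f"center_x = {box.center[0]:g}",
        f"center_y = {box.center[1]:g}",
        f"center_z = {box.center[2]:g}",
        f"size_x = {box.size[0]:g}",
        f"size_y = {box.size[1]:g}",
        f"size_z = {box.size[2]:g}",
    ]
    for key, value in (extra or {}).items():
        lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"


def emit_docking_job(
    ensemble: RotationEnsemble,
    box: GridBox,
    receptor: Union[str, Path],
    outdir: Union[str, Path],
    ligand_format: str = "pdbqt",
    extra_config: Optional[Mapping[str, object]] = None,
) -> pd.DataFrame:
    """Write ligand files, per-member Vina configs and a manifest.

    Returns the manifest (tag, ligand file, config file) as a DataFrame;
    it is also written to ``manifest.tsv`` in ``outdir``.
    """
    receptor = Path(receptor)
    if not receptor.exists():
        raise FileNotFoundError(f"receptor file not found: {receptor}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for tag, member in ensemble:
        ligand_path = outdir / f"ligand_{tag}.{ligand_format}"
        mol_io.write_structure(member, ligand_path, format=ligand_format)
        config_path = outdir / f"config_{tag}.txt"
        config_path.write_text(
            _vina_config_text(str(receptor), ligand_path.name, box, extra_config)
        )
        rows.append({"tag": tag, "ligand": ligand_path.name, "config": config_path.name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Vina result collation
# ---------------------------------------------------------------------------

def parse_vina_affinity(path: Union[str, Path]) -> float:
    """Best (lowest) affinity in a Vina stdout log or docked PDBQT.

    Looks for ``REMARK VINA RESULT`` records first, then for the numbered
    rows of the stdout result table.
    """
    path = Path(path)
    affinities: list[float] = []
    for line in path.read_text().splitlines():
        if line.startswith("REMARK VINA RESULT:"):
            affinities.append(float(line.split()[3]))
            continue
        parts = line.split()
        if len(parts) >= 3 and parts[0].isdigit():
            try:
                affinities.append(float(parts[1]))
            except ValueError:
                continue
    if not affinities:
        raise ValueError(f"{path}: no Vina affinities found")
    return min(affinities)


def collate_scores(results: Mapping[str, Union[str, Path]]) -> pd.DataFrame:
    """Best affinity per ensemble member from Vina output files.

    ``results`` maps member tag to a result file (log or docked PDBQT).
    Unparseable files are warned about and omitted.  The returned frame
    carries min/max/spread across members in ``frame.attrs["summary"]``.
    """
    rows = []
    for tag, path in results.items():
        try:
            rows.append({"tag": tag, "affinity": parse_vina_affinity(path)})
        except (OSError, ValueError) as exc:
            warnings.warn(f"skipping {tag}: {exc}", stacklevel=2)
    frame = pd.DataFrame(rows, columns=["tag", "affinity"])
    if not frame.empty:
        best = frame["affinity"].min()
        worst = frame["affinity"].max()
        frame.attrs["summary"] = {
            "min": float(best),
            "max": float(worst),
            "spread": float(worst - best),
        }
    return frame
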