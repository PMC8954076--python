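"""Preshapes and Riemannian shape distances between matched configurations.

A configuration of k points in 3-D is reduced to its *preshape* by
centering and scaling to unit Frobenius norm, placing it on a
hypersphere.  The Riemannian shape distance between two configurations is
the angle between their preshapes after optimal rotation alignment:

    rd = arccos( max_R  <Z_A R, Z_B> )

with R ranging over proper rotations (default) or all orthogonal matrices
when reflections are allowed.  The maximiser has the closed form of the
orthogonal Procrustes problem: with the SVD Z_A^T Z_B = U diag(l1,l2,l3) V^T,
l1 >= l2 >= l3 >= 0, the maximum is l1 + l2 + l3 over O(3) and
l1 + l2 + sign(det(UV^T)) * l3 over SO(3).

``rd_oracle`` re-derives the same quantity by dense numeric maximisation
over unit quaternions and exists purely as an independent check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .mol_io import AtomMap, Molecule

__all__ = [
    "Preshape",
    "ShapeDistance",
    "DegenerateConfigurationError",
    "preshape",
    "riemannian_distance",
    "rd_oracle",
    "rd_table",
]

MODES = ("proper_rotation", "allow_reflection")

_DEGENERATE_EPS = 1e-12
_CLIP_GUARD = 1e-12


class DegenerateConfigurationError(ValueError):
    """All points coincide: the configuration has no shape."""


@dataclass(frozen=True)
class Preshape:
    """Centered, unit-size configuration plus the removed centroid and scale."""

    z: np.ndarray  # (k, 3), column sums 0, unit Frobenius norm
    centroid: np.ndarray  # (3,), Å
    size: float  # centroid size (Frobenius norm of centered coords), Å
    collinear: bool = False


@dataclass
class ShapeDistance:
    """Global and per-element Riemannian distances for one matched pair."""

    rd: float
    mode: str
    n_atoms: int
    by_element: dict[str, float] = field(default_factory=dict)
    by_element_n: dict[str, int] = field(default_factory=dict)
    refit: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.rd <= np.pi / 2 + 1e-12):
            raise ValueError(f"rd out of [0, pi/2]: {self.rd}")


def _as_coords(obj: Union[Molecule, np.ndarray]) -> np.ndarray:
    if isinstance(obj, Molecule):
        return obj.coords
    return np.asarray(obj, dtype=float)


def preshape(
    mol: Union[Molecule, np.ndarray], subset: Optional[Sequence[int]] = None
) -> Preshape:
    """Center and scale a configuration (optionally a row subset) to a preshape."""
    x = _as_coords(mol)
    if subset is not None:
        x = x[np.asarray(subset, dtype=int)]
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"expected (k, 3) coordinates, got {x.shape}")
    if x.shape[0] < 3:
        raise ValueError(f"need at least 3 points for a shape, got {x.shape[0]}")
    centroid = x.mean(axis=0)
    centered = x - centroid
    size = float(np.linalg.norm(centered))
    if size <= _DEGENERATE_EPS:
        raise DegenerateConfigurationError("all points coincide (centroid size 0)")
    z = centered / size
    # rank < 2 after centering means all points on a line
    collinear = bool(np.linalg.matrix_rank(centered, tol=1e-9 * size) < 2)
    return Preshape(z=z, centroid=centroid, size=size, collinear=collinear)


def _procrustes_alignment(za: np.ndarray, zb: np.ndarray, mode: str) -> tuple[float, np.ndarray]:
    """Max of <Z_A R, Z_B> over rotations, and one maximising R (3x3)."""
    m = za.T @ zb
    u, s, vt = np.linalg.svd(m)
    if mode == "proper_rotation" and np.linalg.det(u @ vt) < 0:
        d = np.array([1.0, 1.0, -1.0])
    else:
        d = np.ones(3)
    value = float(np.dot(s, d))
    r = u @ np.diag(d) @ vt
    # <Z_A R, Z_B> with R applied on the right of Z_A: tr(R^T M); maximised by
    # R = U diag(d) V^T (smallest singular value sign-corrected in SO(3) mode)
    return value, r


def _angle(value: float) -> float:
    if abs(value) > 1.0 + _CLIP_GUARD:
        raise FloatingPointError(
            f"preshape inner product {value} exceeds 1 beyond rounding guard"
        )
    return float(np.arccos(np.clip(value, -1.0, 1.0)))


def _chordal_angle(za_aligned: np.ndarray, zb: np.ndarray) -> float:
    """Angle between unit preshapes via the chord length.

    Equivalent to arccos of the inner product but numerically stable near
    0, where arccos loses half the significant digits.
    """
    half_chord = 0.5 * float(np.linalg.norm(za_aligned - zb))
    if half_chord > 1.0 + _CLIP_GUARD:
        raise FloatingPointError(f"preshape chord {2 * half_chord} exceeds the diameter")
    return float(2.0 * np.arcsin(min(half_chord, 1.0)))


def _resolve_pairs(
    a: Molecule,
    b: Molecule,
    atom_map: Optional[AtomMap],
    subset: Optional[Union[str, Sequence[int]]],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Matched index arrays (into a and b) plus the parent-side element list."""
    if atom_map is None:
        if len(a) != len(b):
            raise ValueError("molecules differ in size; supply an AtomMap")
        atom_map = AtomMap.identity(len(a))
    ia, ib = atom_map.indices_a, atom_map.indices_b
    elements = [a.elements[i] for i in ia]
    for i, j, el in zip(ia, ib, elements):
        if b.elements[j] != el:
            raise ValueError(f"mapped pair ({i}, {j}) has elements {el} vs {b.elements[j]}")
    if subset is not None:
        if isinstance(subset, str):
            keep = np.array([el == subset for el in elements], dtype=bool)
        else:
            wanted = set(int(i) for i in subset)
            keep = np.array([i in wanted for i in ia], dtype=bool)
        ia, ib = ia[keep], ib[keep]
        elements = [el for el, k in zip(elements, keep) if k]
    return ia, ib, elements


def riemannian_distance(
    a: Molecule,
    b: Molecule,
    atom_map: Optional[AtomMap] = None,
    mode: str = "proper_rotation",
    subset: Optional[Union[str, Sequence[int]]] = None,
    refit: bool = True,
) -> ShapeDistance:
    """Riemannian shape distance between two atom-matched molecules.

    Parameters
    ----------
    a, b:
        The two molecules.  Without ``atom_map`` they must be the same size
        and are matched by shared ordering.
    mode:
        ``proper_rotation`` (default; mirror images are distinguished) or
        ``allow_reflection``.
    subset:
        Restrict the computation to one element symbol or to explicit
        parent-side atom indices.
    refit:
        Per-element distances re-solve the rotation on each element subset
        when true; otherwise they inherit the global rotation and evaluate
        the angle of the subset inner product.

    Returns
    -------
    ShapeDistance
        Global ``rd`` in radians in [0, pi/2] and per-element distances for
        every element with at least 3 matched atoms (smaller subsets are
        skipped with a warning).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    ia, ib, elements = _resolve_pairs(a, b, atom_map, subset)
    if len(ia) < 3:
        raise ValueError(f"need >= 3 matched atoms, got {len(ia)}")
    xa, xb = a.coords[ia], b.coords[ib]
    pa, pb = preshape(xa), preshape(xb)
    value, rotation = _procrustes_alignment(pa.z, pb.z, mode)
    _ = _angle(value)  # clipping-guard check on the inner-product path
    rd = _chordal_angle(pa.z @ rotation, pb.z)

    by_element: dict[str, float] = {}
    by_element_n: dict[str, int] = {}
    for el in dict.fromkeys(elements):  # preserve first-appearance order
        idx = np.array([i for i, e in enumerate(elements) if e == el], dtype=int)
        if len(idx) < 3:
            warnings.warn(
                f"element subspace {el!r} has {len(idx)} matched atoms (< 3); skipped",
                stacklevel=2,
            )
            continue
        sa, sb = preshape(xa[idx]), preshape(xb[idx])
        if refit:
            _, sub_rotation = _procrustes_alignment(sa.z, sb.z, mode)
        else:
            sub_rotation = rotation
        by_element[el] = _chordal_angle(sa.z @ sub_rotation, sb.z)
        by_element_n[el] = int(len(idx))

    return ShapeDistance(
        rd=rd,
        mode=mode,
        n_atoms=int(len(ia)),
        by_element=by_element,
        by_element_n=by_element_n,
        refit=refit,
    )


def rd_oracle(
    a: Molecule,
    b: Molecule,
    atom_map: Optional[AtomMap] = None,
    mode: str = "proper_rotation",
    n_samples: int = 6000,
    n_polish: int = 5,
    seed: int = 0,
) -> float:
    """Brute-force shape distance via dense rotation search.

    Maximises the preshape inner product over rotations parameterised by
    unit quaternions: ``n_samples`` uniformly random rotations are scored,
    and the ``n_polish`` best are refined by derivative-free local search
    (in ``allow_reflection`` mode the whole search is repeated composed
    with a fixed improper reflection).  Intended as an independent
    verification oracle for small configurations.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    ia, ib, _ = _resolve_pairs(a, b, atom_map, None)
    pa, pb = preshape(a.coords[ia]), preshape(b.coords[ib])
    m = pa.z.T @ pb.z
    reflection = np.diag([1.0, 1.0, -1.0])
    targets = [m] if mode == "proper_rotation" else [m, m @ reflection]

    rng = np.random.default_rng(seed)

    best = -np.inf
    for target in targets:
        def neg_inner(q: np.ndarray, t=target) -> float:
            norm = np.linalg.norm(q)
            if norm < 1e-12:
                return 2.0
            r = Rotation.from_quat(q / norm).as_matrix()
            return -float(np.einsum("ij,ij->", r, t))

        quats = Rotation.random(n_samples, rng=rng).as_quat()
        quats = np.vstack([quats, [[0.0, 0.0, 0.0, 1.0]]])  # always try identity
        mats = Rotation.from_quat(quats).as_matrix()
        scores = np.einsum("nij,ij->n", mats, target)
        for qi in np.argsort(scores)[::-1][: n_polish]:
            res = minimize(
                neg_inner,
                quats[qi],
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 5000},
            )
            best = max(best, -res.fun)
    return _angle(best)


def rd_table(
    parent: Molecule,
    variants: Iterable[tuple[str, Molecule, Optional[AtomMap]]],
    mode: str = "proper_rotation",
    refit: bool = True,
) -> pd.DataFrame:
    """One row of global + per-element distances per variant.

    Values are kept at full precision; use :func:`format_rd_table` for the
    3-decimal display convention.
    """
    rows = []
    for label, variant, atom_map in variants:
        sd = riemannian_distance(parent, variant, atom_map, mode=mode, refit=refit)
        row = {"label": label, "rd": sd.rd, "n_atoms": sd.n_atoms}
        for el, val in sd.by_element.items():
            row[f"rd_{el}"] = val
        rows.append(row)
    frame = pd.DataFrame(rows)
    lead = [c for c in ("label", "rd") if c in frame.columns]
    tail = [c for c in frame.columns if c not in lead + ["n_atoms"]] + ["n_atoms"]
    return frame[lead + tail]


def format_rd_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display copy with distances rounded to 3 decimals."""
    out = table.copy()
    for col in out.columns:
        if col == "rd" or col.startswith("rd_"):
            out[col] = out[col].map(lambda v: f"{v:.3f}" if pd.notna(v) else "")
    return out


def rd_table_to_json(table: pd.DataFrame) -> str:
    """Full-precision JSON export of an rd table."""
    return json.dumps(table.to_dict(orient="records"), indent=2)
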