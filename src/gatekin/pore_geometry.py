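"""Pore geometry of tetrameric channel structures.

Given a channel structure (PDB), this module finds the pore axis, computes
the pore-radius profile — at each axial position, the radius of the largest
probe sphere that fits between the van der Waals surfaces of the lining
atoms — locates constrictions, manipulates gate-residue side-chain rotamers
(rigid dihedral rotation applied symmetrically to all subunits), and applies
a simple permeation rule: the free aperture between opposed gate side chains,
after subtracting their effective surface radii, is compared with the
dehydrated ion diameter (Ca2+ ~ 0.99 A).

The profiler is a sphere-fitting re-implementation of the classic
pore-radius approach: at each z along the axis the probe centre is optimized
laterally to maximize min_a(|p - x_a| - r_a).  All lengths in Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "AtomRecord",
    "Structure",
    "PoreProfile",
    "GateGeometry",
    "BONDI_RADII",
    "TRP_ROTAMER_TABLE",
    "read_pdb",
    "write_pdb",
    "pore_axis",
    "radius_profile",
    "min_constriction",
    "set_symmetric_rotamer",
    "facing_distance",
    "gate_aperture",
    "permeation_feasibility",
    "make_toy_pore",
    "DEFAULT_R_EFF",
    "CA_DEHYDRATED_DIAMETER",
]

# Bondi van der Waals radii (A); unknown elements fall back to 1.7 A.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
}
_FALLBACK_VDW = 1.70

# Effective side-chain surface radius used to convert a facing distance into a
# free aperture: calibrated so that a 3.1 A inter-side-chain distance maps to
# a 0.8 A passage.  Configurable; not a claim of vdW equivalence.
DEFAULT_R_EFF = 1.15

# Dehydrated Ca2+ diameter (A)
CA_DEHYDRATED_DIAMETER = 0.99

# Built-in tryptophan rotamer classes (chi1, chi2 in degrees).  chi1 follows
# the t/m/p convention; chi2 = 90 is the canonical perpendicular ring.  On the
# tetramer_gate fixture chi1 = 180 points the side chains toward each other
# ("facing"), -60 points them up and +60 down.
TRP_ROTAMER_TABLE: dict[str, tuple[float, float]] = {
    "facing": (180.0, 90.0),
    "up": (-60.0, 90.0),
    "down": (60.0, 90.0),
}

_WATER_RESNAMES = {"HOH", "WAT", "DOD"}
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom with source numbering preserved and a vdW radius assigned."""

    serial: int
    name: str
    resname: str
    resnum: int
    chain: str
    xyz: np.ndarray  # (3,) A
    element: str
    vdw_radius: float

    def __post_init__(self) -> None:
        p = np.asarray(self.xyz, dtype=float)
        object.__setattr__(self, "xyz", p)
        if not np.all(np.isfinite(p)):
            raise ValueError("atom coordinates must be finite")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be > 0")


@dataclass(frozen=True)
class Structure:
    """Atom collection, optionally carrying a declared rotational symmetry."""

    atoms: tuple[AtomRecord, ...]
    symmetry_order: int | None = None
    symmetry_axis: tuple[np.ndarray, np.ndarray] | None = None  # (point, unit vector)

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("structure has no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    @property
    def vdw(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def select(
        self,
        chain: str | None = None,
        resnum: int | None = None,
        names: Iterable[str] | None = None,
    ) -> list[int]:
        names = set(names) if names is not None else None
        out = []
        for i, a in enumerate(self.atoms):
            if chain is not None and a.chain != chain:
                continue
            if resnum is not None and a.resnum != resnum:
                continue
            if names is not None and a.name not in names:
                continue
            out.append(i)
        return out

    def with_coords(self, coords: np.ndarray) -> "Structure":
        atoms = tuple(
            AtomRecord(a.serial, a.name, a.resname, a.resnum, a.chain,
                       coords[i], a.element, a.vdw_radius)
            for i, a in enumerate(self.atoms)
        )
        return Structure(atoms, self.symmetry_order, self.symmetry_axis)


@dataclass(frozen=True)
class PoreProfile:
    """Pore radius as a function of axial coordinate along a given axis."""

    z: np.ndarray  # A, strictly increasing
    radius: np.ndarray  # A, >= 0
    axis_point: np.ndarray
    axis_direction: np.ndarray
    open_flags: np.ndarray | None = None  # True where no atom bounded the probe

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        r = np.asarray(self.radius, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "radius", r)
        if np.any(np.diff(z) <= 0):
            raise ValueError("z must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("radii must be >= 0")

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"z_A": self.z, "radius_A": self.radius}).to_csv(
            path, index=False, float_format="%.4f"
        )


@dataclass(frozen=True)
class GateGeometry:
    """Gate-residue rotamer summary and the permeation verdict it implies."""

    resnum: int
    chi1: float
    chi2: float
    facing_distance: float  # A, min distance between opposed side chains
    aperture: float  # A, free passage diameter
    verdict: Literal["permeable", "blocked"]

    def __post_init__(self) -> None:
        if self.aperture > self.facing_distance + 1e-9:
            raise ValueError("aperture cannot exceed the facing distance")


# ---------------------------------------------------------------------------
# PDB I/O (via Biopython)


def _assign_vdw(element: str) -> float:
    r = BONDI_RADII.get(element.upper())
    if r is None:
        warnings.warn(
            f"unknown element {element!r}: using fallback vdW radius "
            f"{_FALLBACK_VDW} A",
            stacklevel=3,
        )
        return _FALLBACK_VDW
    return r


def read_pdb(
    path: str | Path,
    skip_waters: bool = True,
    vdw_table: dict[str, float] | None = None,
) -> Structure:
    """Read ATOM/HETATM records from a PDB file into a :class:`Structure`.

    For disordered atoms the highest-occupancy alternate location is kept
    (altloc A on ties); waters are skipped by default; vdW radii are assigned
    from the Bondi table by element (unknown element -> 1.7 A with a warning).
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        model = parser.get_structure("s", str(path))[0]
    except PDBConstructionException as exc:
        raise ValueError(f"unparseable PDB file {path}: {exc}") from exc
    table = dict(BONDI_RADII)
    if vdw_table:
        table.update({k.upper(): v for k, v in vdw_table.items()})
    records: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            if skip_waters and residue.get_resname().strip() in _WATER_RESNAMES:
                continue
            for atom in residue:
                elem = (atom.element or atom.get_name()[0]).strip().upper()
                r = table.get(elem)
                if r is None:
                    warnings.warn(
                        f"unknown element {elem!r} (atom {atom.get_serial_number()}): "
                        f"using fallback vdW radius {_FALLBACK_VDW} A",
                        stacklevel=2,
                    )
                    r = _FALLBACK_VDW
                records.append(
                    AtomRecord(
                        serial=int(atom.get_serial_number() or 0),
                        name=atom.get_name().strip(),
                        resname=residue.get_resname().strip(),
                        resnum=int(residue.get_id()[1]),
                        chain=chain.get_id(),
                        xyz=atom.get_coord().astype(float),
                        element=elem,
                        vdw_radius=float(r),
                    )
                )
    if not records:
        raise ValueError(f"no atoms parsed from {path}")
    return Structure(tuple(records))


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure as a PDB file (one model, author numbering kept)."""
    from Bio.PDB.StructureBuilder import StructureBuilder
    from Bio.PDB import PDBIO

    sb = StructureBuilder()
    sb.init_structure("s")
    sb.init_model(0)
    current_chain = None
    current_res = None
    for a in structure.atoms:
        if a.chain != current_chain:
            sb.init_chain(a.chain)
            sb.init_seg("    ")
            current_chain = a.chain
            current_res = None
        if a.resnum != current_res:
            sb.init_residue(a.resname, " ", a.resnum, " ")
            current_res = a.resnum
        sb.init_atom(
            a.name, np.asarray(a.xyz, dtype=float), 0.0, 1.0, " ",
            a.name.center(4) if len(a.name) < 4 else a.name,
            a.serial, a.element.capitalize(),
        )
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# Axis and radius profile


def _lateral_spread(u: np.ndarray, pts: np.ndarray) -> float:
    u = u / np.linalg.norm(u)
    proj = pts @ u
    lateral = pts - np.outer(proj, u)
    r = np.linalg.norm(lateral, axis=1)
    return float(np.var(r))


def pore_axis(
    structure: Structure, selection: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pore axis: centroid of selected atoms + direction of least lateral spread.

    The direction minimizes the variance of the atoms' perpendicular distances
    to the axis (for a ring or cylinder of pore-lining atoms this is exact).
    A declared symmetry axis on the structure takes precedence.
    """
    if structure.symmetry_axis is not None:
        point, direction = structure.symmetry_axis
        return np.asarray(point, dtype=float), _unit(np.asarray(direction, dtype=float))
    idx = list(selection) if selection is not None else list(range(len(structure.atoms)))
    if len(idx) < 3:
        raise ValueError("need at least 3 atoms to define a pore axis")
    pts = structure.coords[idx]
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    # candidate starts: the three principal axes
    _, _, Vt = np.linalg.svd(centred, full_matrices=False)
    best_u, best_val = None, np.inf
    for u0 in Vt:
        res = minimize(
            lambda ang: _lateral_spread(_from_angles(ang), centred),
            _to_angles(u0),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
        )
        if res.fun < best_val:
            best_val = res.fun
            best_u = _from_angles(res.x)
    u = _unit(best_u)
    if u[np.argmax(np.abs(u))] < 0:  # orient deterministically
        u = -u
    return centroid, u


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _to_angles(u: np.ndarray) -> np.ndarray:
    u = _unit(u)
    return np.array([np.arccos(np.clip(u[2], -1, 1)), np.arctan2(u[1], u[0])])


def _from_angles(ang: np.ndarray) -> np.ndarray:
    th, ph = ang
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def _axis_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = _unit(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, u)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(u, helper))
    e2 = np.cross(u, e1)
    return e1, e2


def _probe_radius(p: np.ndarray, coords: np.ndarray, vdw: np.ndarray) -> float:
    d = np.linalg.norm(coords - p, axis=1) - vdw
    return float(d.min())


def radius_profile(
    structure: Structure,
    axis: tuple[np.ndarray, np.ndarray] | None = None,
    z_range: tuple[float, float] | None = None,
    z_step: float = 0.25,
    lateral_bound: float = 10.0,
    grid_step: float = 0.25,
) -> PoreProfile:
    """Pore-radius profile by probe-sphere fitting along the axis.

    At each axial position z the probe centre is optimized over lateral
    offsets within ``lateral_bound`` to maximize
    ``min_a(|p - x_a| - r_a)`` (coarse grid of ``grid_step`` plus local
    Nelder-Mead refinement); the result, clamped at zero, is the pore radius.
    Positions where even the best probe is bounded only by the lateral bound
    are flagged open.
    """
    if z_step <= 0 or lateral_bound <= 0:
        raise ValueError("z_step and lateral_bound must be > 0")
    if axis is None:
        axis = pore_axis(structure)
    point, u = np.asarray(axis[0], dtype=float), _unit(np.asarray(axis[1], dtype=float))
    coords = structure.coords
    vdw = structure.vdw
    zproj = (coords - point) @ u
    if z_range is None:
        z_range = (float(zproj.min()), float(zproj.max()))
    z_vals = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)
    e1, e2 = _axis_frame(u)

    # local search grid around the running probe centre (path-following: the
    # probe never jumps to a disconnected cavity outside the pore line)
    local_r = min(lateral_bound, max(4 * grid_step, 1.0))
    g = np.arange(-local_r, local_r + 0.5 * grid_step, grid_step)
    gx, gy = np.meshgrid(g, g)
    in_disc = gx**2 + gy**2 <= local_r**2
    offsets = np.stack([gx[in_disc], gy[in_disc]], axis=1)  # (m, 2)

    radii = np.empty(len(z_vals))
    open_flags = np.zeros(len(z_vals), dtype=bool)
    max_vdw = vdw.max()
    prev_xy = np.zeros(2)  # start on the axis
    for i, z in enumerate(z_vals):
        centre = point + z * u
        # atoms whose spheres can intrude into this slab's search disc
        reach = lateral_bound + max_vdw + 2.0
        near = np.abs(zproj - z) <= reach
        if not near.any():
            radii[i] = lateral_bound
            open_flags[i] = True
            prev_xy = np.zeros(2)
            continue
        A = coords[near]
        R = vdw[near]

        def neg_f(xy: np.ndarray) -> float:
            if xy[0] ** 2 + xy[1] ** 2 > lateral_bound**2:
                return 1e6
            p = centre + xy[0] * e1 + xy[1] * e2
            return -_probe_radius(p, A, R)

        # coarse local grids around the previous optimum and the axis
        best_xy, best_val = prev_xy, -neg_f(prev_xy)
        for anchor in (prev_xy, np.zeros(2)):
            cand = anchor + offsets
            inside = np.einsum("ij,ij->i", cand, cand) <= lateral_bound**2
            cand = cand[inside]
            pts = centre + cand[:, :1] * e1 + cand[:, 1:] * e2
            d = np.linalg.norm(A[None, :, :] - pts[:, None, :], axis=2) - R[None, :]
            f = d.min(axis=1)
            j = int(np.argmax(f))
            if f[j] > best_val:
                best_val, best_xy = float(f[j]), cand[j]
        res = minimize(
            neg_f, best_xy, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 500},
        )
        if -res.fun > best_val:
            best_val, best_xy = -res.fun, res.x
        prev_xy = np.asarray(best_xy, dtype=float)
        r = best_val
        if r >= lateral_bound:
            r = lateral_bound
            open_flags[i] = True
        radii[i] = max(r, 0.0)
    return PoreProfile(
        z=z_vals, radius=radii, axis_point=point, axis_direction=u,
        open_flags=open_flags,
    )


def min_constriction(
    profile: PoreProfile, z_window: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """Narrowest point of a profile: (z, radius, diameter).

    Restricted to ``z_window`` if given; ties break toward the smallest z.
    """
    mask = (
        np.ones(len(profile.z), dtype=bool)
        if z_window is None
        else (profile.z >= z_window[0]) & (profile.z <= z_window[1])
    )
    if not mask.any():
        raise ValueError("z window does not overlap the profile")
    z = profile.z[mask]
    r = profile.radius[mask]
    i = int(np.argmin(r))  # argmin returns first minimum -> smallest z on ties
    return float(z[i]), float(r[i]), float(2.0 * r[i])


# ---------------------------------------------------------------------------
# Rotamers and the gate rule


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, _unit(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def _rotate_about(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
                  angle_deg: float) -> np.ndarray:
    u = _unit(axis)
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    p = points - origin
    # Rodrigues rotation
    rot = p * c + np.cross(u, p) * s + np.outer(p @ u, u) * (1 - c)
    return rot + origin


def set_symmetric_rotamer(
    structure: Structure,
    resnum: int,
    chains: Sequence[str],
    chi1: float,
    chi2: float | None = None,
) -> Structure:
    """Set the side-chain rotamer of one residue identically in every chain.

    The side chain beyond C-beta is rigidly rotated so that the dihedral
    N-CA-CB-CG equals ``chi1`` and (if given) CA-CB-CG-CD1 equals ``chi2``.
    Bond lengths and angles are preserved exactly.
    """
    coords = structure.coords.copy()
    for chain in chains:
        res_idx = structure.select(chain=chain, resnum=resnum)
        if not res_idx:
            raise ValueError(f"residue {resnum} not found in chain {chain}")
        by_name = {structure.atoms[i].name: i for i in res_idx}
        for needed in ("N", "CA", "CB", "CG"):
            if needed not in by_name:
                raise ValueError(
                    f"atom {needed} missing in residue {resnum} chain {chain}"
                )
        n_i, ca_i, cb_i, cg_i = (by_name[a] for a in ("N", "CA", "CB", "CG"))
        side = [i for i in res_idx
                if structure.atoms[i].name not in _BACKBONE_NAMES
                and structure.atoms[i].name != "CB"]
        cur = dihedral(coords[n_i], coords[ca_i], coords[cb_i], coords[cg_i])
        coords[side] = _rotate_about(
            coords[side], coords[cb_i], coords[ca_i] - coords[cb_i], chi1 - cur
        )
        if chi2 is not None:
            if "CD1" not in by_name:
                raise ValueError(
                    f"atom CD1 missing in residue {resnum} chain {chain}"
                )
            cd1_i = by_name["CD1"]
            beyond_cg = [i for i in side if i != cg_i]
            cur2 = dihedral(coords[ca_i], coords[cb_i], coords[cg_i], coords[cd1_i])
            coords[beyond_cg] = _rotate_about(
                coords[beyond_cg], coords[cg_i], coords[cb_i] - coords[cg_i],
                chi2 - cur2,
            )
    return structure.with_coords(coords)


def facing_distance(
    structure: Structure,
    resnum: int,
    atom_names: Iterable[str] | None = None,
    chains: Sequence[str] | None = None,
) -> float:
    """Minimum distance between the side chains of opposing subunits (A).

    For a four-chain structure, opposing means diagonal pairs (1st-3rd and
    2nd-4th chain); with fewer chains, all inter-chain pairs are scanned.
    ``atom_names`` restricts the comparison (default: side-chain atoms beyond
    C-beta).
    """
    chains = list(chains) if chains is not None else structure.chains
    if len(chains) < 2:
        raise ValueError("need the residue in at least 2 chains")
    if atom_names is None:
        sel_names = None
    else:
        sel_names = set(atom_names)

    def side_atoms(ch: str) -> np.ndarray:
        idx = [
            i
            for i in structure.select(chain=ch, resnum=resnum)
            if (sel_names is not None and structure.atoms[i].name in sel_names)
            or (
                sel_names is None
                and structure.atoms[i].name not in _BACKBONE_NAMES
                and structure.atoms[i].name != "CB"
            )
        ]
        if not idx:
            raise ValueError(f"no selected atoms for residue {resnum} chain {ch}")
        return structure.coords[idx]

    if len(chains) == 4:
        pairs = [(chains[0], chains[2]), (chains[1], chains[3])]
    else:
        pairs = [(a, b) for i, a in enumerate(chains) for b in chains[i + 1:]]
    best = np.inf
    for ca, cb in pairs:
        A, B = side_atoms(ca), side_atoms(cb)
        d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2).min()
        best = min(best, float(d))
    return best


def gate_aperture(d: float, r_eff: float = DEFAULT_R_EFF) -> float:
    """Free passage diameter between opposed side chains.

    aperture = max(0, d - 2 * r_eff): the facing distance minus both
    effective surface radii, clamped at zero.  The default r_eff = 1.15 A is
    calibrated so a 3.1 A facing distance yields a 0.8 A passage.
    """
    if d < 0 or r_eff < 0:
        raise ValueError("distance and r_eff must be >= 0")
    return max(0.0, d - 2.0 * r_eff)


def permeation_feasibility(
    aperture: float, ion_diameter: float = CA_DEHYDRATED_DIAMETER
) -> Literal["permeable", "blocked"]:
    """Classify ion passage: permeable iff aperture >= ion diameter.

    The boundary case counts as permeable.  Default ion: dehydrated Ca2+
    (0.99 A diameter).
    """
    if aperture < 0 or ion_diameter < 0:
        raise ValueError("aperture and ion_diameter must be >= 0")
    return "permeable" if aperture >= ion_diameter else "blocked"


# ---------------------------------------------------------------------------
# Toy structure factory


def _ring_atoms(
    n: int, ring_radius: float, z: float, element: str, vdw: float,
    start_serial: int, chain: str, resnum: int, phase: float = 0.0,
) -> list[AtomRecord]:
    out = []
    for i in range(n):
        th = phase + 2.0 * np.pi * i / n
        out.append(
            AtomRecord(
                serial=start_serial + i,
                name=f"C{i + 1}",
                resname="TOY",
                resnum=resnum,
                chain=chain,
                xyz=np.array([ring_radius * np.cos(th), ring_radius * np.sin(th), z]),
                element=element,
                vdw_radius=vdw,
            )
        )
    return out


def _toy_trp_subunit(
    chain: str, theta: float, ca_radius: float, resnum: int, serial0: int,
    n_tilt_deg: float = 10.0,
) -> list[AtomRecord]:
    """One pseudo-tryptophan subunit of the tetramer_gate fixture.

    Backbone N/CA sit on the pore wall with CA-CB tangential, so that chi1
    swings the side chain through the radial-axial plane: chi1 = 180 points
    it toward the axis, -60 up and +60 down.  ``n_tilt_deg`` offsets the N
    reference out of plane so the up and down classes are inequivalent, as
    they are on a real helix.
    """
    r_hat = np.array([np.cos(theta), np.sin(theta), 0.0])
    t_hat = np.array([-np.sin(theta), np.cos(theta), 0.0])
    z_hat = np.array([0.0, 0.0, 1.0])
    ca = ca_radius * r_hat
    cb = ca + 1.53 * t_hat
    # N at tetrahedral angle from the CA->CB bond, tilted out of plane
    tilt = np.radians(n_tilt_deg)
    n_dir = -0.342 * t_hat + 0.940 * (np.cos(tilt) * r_hat + np.sin(tilt) * z_hat)
    n_pos = ca + 1.46 * _unit(n_dir)
    c_pos = ca + 1.52 * _unit(-0.4 * t_hat - 0.9 * z_hat)
    # side chain built at chi1 = 180 (facing): CG on the tetrahedral cone
    # around CB->(away from CA), azimuth opposite the N offset
    def cone_dir(axis: np.ndarray, ref_perp: np.ndarray, half_deg: float,
                 azimuth_deg: float) -> np.ndarray:
        a = _unit(axis)
        e1 = _unit(ref_perp - np.dot(ref_perp, a) * a)
        e2 = np.cross(a, e1)
        half = np.radians(half_deg)
        az = np.radians(azimuth_deg)
        return np.cos(half) * a + np.sin(half) * (np.cos(az) * e1 + np.sin(az) * e2)

    cg = cb + 1.51 * cone_dir(t_hat, -r_hat, 66.4, 0.0)
    atoms_xyz = {"N": n_pos, "CA": ca, "C": c_pos, "CB": cb, "CG": cg}
    # extend CD1 and NE1 along the CB->CG direction with a slight kink
    d = _unit(cg - cb)
    perp = _unit(np.cross(d, t_hat))
    cd1 = cg + 1.37 * _unit(d + 0.45 * perp)
    ne1 = cd1 + 1.37 * _unit(d - 0.35 * perp)
    atoms_xyz["CD1"] = cd1
    atoms_xyz["NE1"] = ne1
    elements = {"N": "N", "CA": "C", "C": "C", "CB": "C", "CG": "C",
                "CD1": "C", "NE1": "N"}
    out = []
    for k, (name, xyz) in enumerate(atoms_xyz.items()):
        elem = elements[name]
        out.append(
            AtomRecord(
                serial=serial0 + k, name=name, resname="TRP", resnum=resnum,
                chain=chain, xyz=xyz, element=elem,
                vdw_radius=BONDI_RADII[elem],
            )
        )
    return out


def make_toy_pore(
    kind: Literal["ring", "cylinder", "hourglass", "tetramer_gate"],
    *,
    ring_radius: float = 5.0,
    n_atoms: int = 12,
    vdw: float = 1.70,
    n_rings: int = 5,
    z_spacing: float = 2.0,
    waist_radius: float = 3.0,
    half_length: float = 6.0,
    facing_target: float = 3.1,
    resnum: int = 583,
    path: str | Path | None = None,
    seed: int = 0,
) -> Structure:
    """Deterministic synthetic structures with known analytic pore geometry.

    kinds
    -----
    ring
        ``n_atoms`` carbon-like atoms on a circle of ``ring_radius``; the pore
        radius at the ring plane is analytically ring_radius - vdw.
    cylinder
        ``n_rings`` stacked copies of the ring: a constant profile.
    hourglass
        stacked rings whose radius varies as r(z) = waist + (R - waist) *
        (z / half_length)^2: the analytic waist sits at z = 0.
    tetramer_gate
        four pseudo-tryptophan subunits in exact C4 symmetry around z; in the
        built facing rotamer (chi1 = 180) the minimum side-chain distance
        between opposing subunits equals ``facing_target`` (default 3.1 A).

    If ``path`` is given the structure is also written as a PDB file.
    """
    if kind == "ring":
        atoms = _ring_atoms(n_atoms, ring_radius, 0.0, "C", vdw, 1, "A", 1)
        struct = Structure(
            tuple(atoms), symmetry_order=n_atoms,
            symmetry_axis=(np.zeros(3), np.array([0.0, 0.0, 1.0])),
        )
    elif kind == "cylinder":
        atoms = []
        for j in range(n_rings):
            z = (j - (n_rings - 1) / 2) * z_spacing
            atoms += _ring_atoms(n_atoms, ring_radius, z, "C", vdw,
                                 1 + j * n_atoms, "A", j + 1)
        struct = Structure(
            tuple(atoms), symmetry_order=n_atoms,
            symmetry_axis=(np.zeros(3), np.array([0.0, 0.0, 1.0])),
        )
    elif kind == "hourglass":
        atoms = []
        z_vals = np.arange(-half_length, half_length + 1e-9, z_spacing / 2)
        for j, z in enumerate(z_vals):
            r = waist_radius + (ring_radius - waist_radius) * (z / half_length) ** 2
            atoms += _ring_atoms(n_atoms, r, float(z), "C", vdw,
                                 1 + j * n_atoms, "A", j + 1)
        struct = Structure(
            tuple(atoms), symmetry_order=n_atoms,
            symmetry_axis=(np.zeros(3), np.array([0.0, 0.0, 1.0])),
        )
    elif kind == "tetramer_gate":
        # Build one subunit in the facing rotamer, re-orient it so the
        # side-chain tip points at the pore axis, replicate with exact C4
        # symmetry, then solve the radial placement so that the
        # opposing-subunit side-chain distance equals facing_target.
        trial_R = 9.0
        chains = ["A", "B", "C", "D"]
        sub = Structure(
            tuple(_toy_trp_subunit("A", 0.0, trial_R, resnum, 1)),
        )
        chi1, chi2 = TRP_ROTAMER_TABLE["facing"]
        sub = set_symmetric_rotamer(sub, resnum, ["A"], chi1, chi2)
        by_name = {a.name: a for a in sub.atoms}
        ca, tip = by_name["CA"].xyz, by_name["NE1"].xyz
        v = tip[:2] - ca[:2]
        # rotate about the vertical through CA so v aligns with -r_hat = (-1, 0)
        ang = np.degrees(np.arctan2(v[1], v[0])) - 180.0
        coords = _rotate_about(
            sub.coords, np.array([ca[0], ca[1], 0.0]),
            np.array([0.0, 0.0, 1.0]), -ang,
        )
        sub = sub.with_coords(coords)

        def _assemble(radial: float) -> Structure:
            delta = radial - trial_R
            atoms = []
            for k, ch in enumerate(chains):
                rot = _rotate_about(
                    sub.coords + np.array([delta, 0.0, 0.0]),
                    np.zeros(3), np.array([0.0, 0.0, 1.0]), 90.0 * k,
                )
                for j, a in enumerate(sub.atoms):
                    atoms.append(
                        AtomRecord(7 * k + j + 1, a.name, a.resname, a.resnum,
                                   ch, rot[j], a.element, a.vdw_radius)
                    )
            return Structure(
                tuple(atoms), symmetry_order=4,
                symmetry_axis=(np.zeros(3), np.array([0.0, 0.0, 1.0])),
            )

        from scipy.optimize import brentq

        def gap(radial: float) -> float:
            return facing_distance(_assemble(radial), resnum) - facing_target

        # tips cross the axis when the CA radius equals the lateral
        # CA-to-tip reach |v|; stay on the near side of that point
        lo = float(np.linalg.norm(v)) + 0.3
        hi = trial_R + 10.0
        radial = brentq(gap, lo, hi, xtol=1e-12)
        struct = _assemble(radial)
    else:
        raise ValueError(f"unknown toy pore kind {kind!r}")
    if path is not None:
        write_pdb(struct, path)
    return struct
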