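"""Reading, writing and preparing SAXS profiles and atomic models.

Profiles use the SASBDB ``.dat`` dialect: whitespace-delimited columns
q [1/A], I(q) [arbitrary units], sigma(q), with ``#``/non-numeric header and
footer lines ignored.  Structures are read from PDB files via gemmi; waters
and hetero ligands are stripped, alternate locations are resolved, and every
heavy atom is assigned a united-atom group, radius and implicit-hydrogen
count so the model is ready for scattering calculations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._chem import GROUP_TABLE, assign_group, group_electrons, group_radius

log = logging.getLogger(__name__)

EXPERIMENTAL_MODES = ("sec", "batch", "consensus")
MODES = EXPERIMENTAL_MODES + ("model",)


@dataclass
class SASProfile:
    """One scattering curve: strictly increasing q grid with I and sigma.

    ``sigma`` is strictly positive for experimental modes; model profiles may
    carry sigma = 0 and profiles read from 2-column files carry NaN sigma
    (flagged; refused by consensus operations).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    label: str = ""
    mode: str = "batch"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.q.size
        if n < 2:
            raise ValueError("profile needs at least 2 points")
        if self.I.size != n or self.sigma.size != n:
            raise ValueError("q, I, sigma must have equal length")
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.has_sigma:
            if self.mode in EXPERIMENTAL_MODES and not np.all(self.sigma > 0):
                raise ValueError("experimental profiles require sigma > 0")
            if self.mode == "model" and not np.all(self.sigma >= 0):
                raise ValueError("model sigma must be >= 0")

    @property
    def n_points(self) -> int:
        return self.q.size

    @property
    def has_sigma(self) -> bool:
        """False for profiles read from 2-column files (sigma missing)."""
        return not np.any(np.isnan(self.sigma))

    def copy(self, **changes) -> "SASProfile":
        out = replace(self, **changes)
        out.meta = dict(changes.get("meta", self.meta))
        return out


@dataclass
class AtomicModel:
    """Heavy-atom coordinates with united-atom annotation.

    ``s`` (solvent-accessible-surface fractions) is NaN until filled by
    :func:`saxsbench.profile_predictor.sasa_fractions`.
    """

    coords: np.ndarray          # (N, 3) [A]
    element: np.ndarray         # (N,) str
    group: np.ndarray           # (N,) united-atom class
    radius: np.ndarray          # (N,) group radius [A]
    h_count: np.ndarray         # (N,) implicit hydrogens
    s: np.ndarray               # (N,) SASA fraction in [0, 1] (NaN = unset)
    res_name: np.ndarray | None = None
    atom_name: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        for name in ("element", "group"):
            setattr(self, name, np.asarray(getattr(self, name)))
        self.radius = np.asarray(self.radius, dtype=float)
        self.h_count = np.asarray(self.h_count, dtype=int)
        self.s = np.asarray(self.s, dtype=float)
        for name in ("element", "group", "radius", "h_count", "s"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length mismatch")
        if n and not np.all(self.radius > 0):
            raise ValueError("group radii must be positive")

    @classmethod
    def from_groups(cls, coords, groups, label: str = "") -> "AtomicModel":
        """Build a model from coordinates and united-atom group labels."""
        groups = np.asarray(groups)
        elements, radii, h_counts = [], [], []
        for g in groups:
            elem, n_h, _ = GROUP_TABLE[str(g)]
            elements.append(elem)
            h_counts.append(n_h)
            radii.append(group_radius(str(g)))
        n = len(groups)
        return cls(coords=np.asarray(coords, float), element=np.array(elements),
                   group=groups, radius=np.array(radii),
                   h_count=np.array(h_counts), s=np.full(n, np.nan),
                   label=label)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def electrons(self) -> np.ndarray:
        """Electron count per united-atom group (heavy atom + implicit H)."""
        return np.array([group_electrons(g) if g in GROUP_TABLE else 0
                         for g in self.group], dtype=float)

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            coords=self.coords.copy(), element=self.element.copy(),
            group=self.group.copy(), radius=self.radius.copy(),
            h_count=self.h_count.copy(), s=self.s.copy(),
            res_name=None if self.res_name is None else self.res_name.copy(),
            atom_name=None if self.atom_name is None else self.atom_name.copy(),
            label=self.label)

    def transformed(self, rotation=None, translation=None) -> "AtomicModel":
        """Rigid-body transformed copy (rotation about origin, then shift)."""
        out = self.copy()
        if rotation is not None:
            out.coords = out.coords @ np.asarray(rotation, float).T
        if translation is not None:
            out.coords = out.coords + np.asarray(translation, float)
        return out


def read_profile(path, dialect: str = "dat", label: str | None = None,
                 mode: str = "batch") -> SASProfile:
    """Read a 1-D SAXS profile from a SASBDB-style text file.

    Comment (``#``) and non-numeric header/footer lines are skipped.  Rows
    with non-positive sigma are dropped with a logged count (inverse-variance
    weights require sigma > 0).  2-column files are readable but the sigma
    column is filled with NaN and the profile is flagged.
    """
    path = Path(path)
    delim = "," if dialect == "csv" else None
    rows2, rows3 = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delim)
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                continue
            if len(vals) == 2:
                rows2.append(vals)
            elif len(vals) >= 3:
                rows3.append(vals[:3])
    if rows3 and not rows2:
        arr = np.array(rows3)
        if mode == "model":
            bad = (arr[:, 2] < 0) | ~np.isfinite(arr).all(axis=1)
        else:
            bad = ~(arr[:, 2] > 0) | ~np.isfinite(arr).all(axis=1)
        if bad.any():
            log.info("%s: dropped %d rows with non-positive/missing sigma",
                     path.name, int(bad.sum()))
        arr = arr[~bad]
        two_col = False
    elif rows2 and not rows3:
        arr = np.array(rows2)
        arr = arr[np.isfinite(arr).all(axis=1)]
        arr = np.column_stack([arr, np.full(arr.shape[0], np.nan)])
        two_col = True
    elif rows2 and rows3:
        raise ValueError(f"{path}: mixed 2- and 3-column rows")
    else:
        raise ValueError(f"{path}: no numeric data rows")
    if arr.shape[0] < 2:
        raise ValueError(f"{path}: fewer than 2 usable data rows")
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    keep = np.concatenate([[True], np.diff(arr[:, 0]) > 0])
    arr = arr[keep]
    if arr.shape[0] < 2:
        raise ValueError(f"{path}: q grid degenerate after deduplication")
    meta = {"source": str(path)}
    if two_col:
        meta["no_sigma"] = "true"
    return SASProfile(q=arr[:, 0], I=arr[:, 1], sigma=arr[:, 2],
                      label=label or path.stem, mode=mode, meta=meta)


def write_profile(profile: SASProfile, path) -> None:
    """Write a profile as 3-column text with metadata header comments.

    The format is bit-stable: 12 significant digits in scientific notation.
    Model profiles without statistical errors write a zero sigma column;
    flagged 2-column profiles write NaN.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# label: {profile.label}\n# mode: {profile.mode}\n")
        for key, val in sorted(profile.meta.items()):
            fh.write(f"# {key}: {val}\n")
        fh.write("# columns: q[1/A] I[a.u.] sigma\n")
        for q, i, s in zip(profile.q, profile.I, profile.sigma):
            fh.write(f"{q:.12e} {i:.12e} {s:.12e}\n")


def read_structure(path, keep_altloc: str = "A") -> AtomicModel:
    """Read a PDB file into a prepared heavy-atom united-atom model.

    Waters and HETATM ligands are removed (they are not part of the solution
    scattering model), hydrogens are dropped (implicit in the united-atom
    groups), and alternate locations are resolved to the highest-occupancy
    conformer with ties broken in favour of ``keep_altloc``.  Unknown
    residue/atom names fall back to the bare-element group with a warning.
    """
    import gemmi

    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    st.remove_ligands_and_waters()
    st.remove_hydrogens()
    coords, elements, groups, radii, h_counts = [], [], [], [], []
    res_names, atom_names = [], []
    unknown = set()
    model = st[0]
    for chain in model:
        for res in chain:
            # resolve altlocs: group atoms by name, keep best occupancy
            by_name: dict[str, object] = {}
            for atom in res:
                prev = by_name.get(atom.name)
                if prev is None:
                    by_name[atom.name] = atom
                elif atom.occ > prev.occ or (
                        atom.occ == prev.occ and atom.altloc == keep_altloc):
                    by_name[atom.name] = atom
            for name, atom in by_name.items():
                elem = atom.element.name.upper()
                if elem == "H":
                    continue
                grp = assign_group(res.name, name, elem)
                if grp is None:
                    unknown.add((res.name, name))
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(elem)
                groups.append(grp)
                radii.append(group_radius(grp))
                h_counts.append(GROUP_TABLE[grp][1])
                res_names.append(res.name)
                atom_names.append(name)
    if unknown:
        log.warning("%s: %d atom types without element fallback skipped: %s",
                    path, len(unknown), sorted(unknown)[:5])
    if not coords:
        raise ValueError(f"{path}: no usable ATOM records")
    n = len(coords)
    return AtomicModel(
        coords=np.array(coords), element=np.array(elements),
        group=np.array(groups), radius=np.array(radii),
        h_count=np.array(h_counts), s=np.full(n, np.nan),
        res_name=np.array(res_names), atom_name=np.array(atom_names),
        label=Path(path).stem)
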