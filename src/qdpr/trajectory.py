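"""Trajectory ensemble container and I/O adapters.

The in-memory container is a plain (frames, atoms, 3) coordinate array in
Angstroms plus a light topology (atom names, elements, van der Waals radii,
1-based residue assignment). Independent trajectories of the same variant are
carried as segments of the frame axis so per-segment operations (e.g.
equilibration discard) can act on each run separately while downstream
featurization pools them.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["Topology", "TrajectoryEnsemble", "DEFAULT_VDW_RADII"]

# element -> van der Waals radius, Angstrom
DEFAULT_VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


@dataclasses.dataclass(frozen=True)
class Topology:
    """Per-atom metadata; ``residue_indices`` are 1-based and contiguous."""

    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    radii: np.ndarray
    residue_indices: np.ndarray
    residue_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        if not (len(self.elements) == len(self.radii) == len(self.residue_indices) == n):
            raise ValueError("topology arrays disagree on atom count")
        if n and self.residue_indices.min() < 1:
            raise ValueError("residue indices must be 1-based")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return int(self.residue_indices.max()) if self.n_atoms else 0

    def atom_index(self, residue: int, name: str) -> int | None:
        """0-based index of atom ``name`` in 1-based ``residue`` (or None)."""
        hits = np.flatnonzero(
            (self.residue_indices == residue)
            & (np.asarray(self.atom_names) == name)
        )
        return int(hits[0]) if hits.size else None

    def atoms_named(self, name: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.atom_names) == name)


@dataclasses.dataclass
class TrajectoryEnsemble:
    """Frames x atoms x 3 coordinates (Angstrom) + topology + frame segments."""

    coordinates: np.ndarray
    topology: Topology
    frame_spacing: float | None = None
    segments: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be (frames, atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate atom axis disagrees with topology")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates contain NaN/inf")
        if self.segments is None:
            self.segments = ((0, self.n_frames),)
        self.segments = tuple((int(a), int(b)) for a, b in self.segments)
        covered = 0
        for a, b in self.segments:
            if a != covered or b <= a:
                raise ValueError("segments must partition the frame axis in order")
            covered = b
        if covered != self.n_frames:
            raise ValueError("segments must partition the frame axis")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    # ---------------------------------------------------------------- HDF5
    def to_hdf5(self, path) -> None:
        """Portable array layout: /coordinates plus /topology/* tables."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("coordinates", data=self.coordinates)
            f.create_dataset("segments", data=np.asarray(self.segments))
            if self.frame_spacing is not None:
                f.attrs["frame_spacing"] = self.frame_spacing
            g = f.create_group("topology")
            str_dt = h5py.string_dtype()
            g.create_dataset(
                "atom_name", data=np.asarray(self.topology.atom_names, dtype=object),
                dtype=str_dt,
            )
            g.create_dataset(
                "element", data=np.asarray(self.topology.elements, dtype=object),
                dtype=str_dt,
            )
            g.create_dataset("radius", data=self.topology.radii)
            g.create_dataset("residue_index", data=self.topology.residue_indices)
            if self.topology.residue_names is not None:
                g.create_dataset(
                    "residue_name",
                    data=np.asarray(self.topology.residue_names, dtype=object),
                    dtype=str_dt,
                )

    @classmethod
    def from_hdf5(cls, path) -> "TrajectoryEnsemble":
        import h5py

        with h5py.File(path, "r") as f:
            g = f["topology"]
            res_names = None
            if "residue_name" in g:
                res_names = tuple(s.decode() for s in g["residue_name"][()])
            top = Topology(
                atom_names=tuple(s.decode() for s in g["atom_name"][()]),
                elements=tuple(s.decode() for s in g["element"][()]),
                radii=g["radius"][()],
                residue_indices=g["residue_index"][()],
                residue_names=res_names,
            )
            return cls(
                coordinates=f["coordinates"][()],
                topology=top,
                frame_spacing=f.attrs.get("frame_spacing"),
                segments=tuple(map(tuple, f["segments"][()])),
            )

    # -------------------------------------------------------------- mdtraj
    @classmethod
    def from_mdtraj(cls, traj, radii: dict[str, float] | None = None):
        """Adapt an ``mdtraj.Trajectory`` (nm) to this container (Angstrom)."""
        radii = DEFAULT_VDW_RADII if radii is None else radii
        names, elements, res_idx, res_names_by_res = [], [], [], {}
        for atom in traj.topology.atoms:
            names.append(atom.name)
            elements.append(atom.element.symbol if atom.element else "C")
            res_idx.append(atom.residue.index + 1)
            res_names_by_res[atom.residue.index + 1] = atom.residue.name
        res_idx = np.asarray(res_idx)
        top = Topology(
            atom_names=tuple(names),
            elements=tuple(elements),
            radii=np.array([radii.get(e, 1.7) for e in elements]),
            residue_indices=res_idx,
            residue_names=tuple(
                res_names_by_res[i] for i in range(1, int(res_idx.max()) + 1)
            ),
        )
        spacing = float(traj.timestep) if traj.n_frames > 1 else None
        return cls(coordinates=traj.xyz * 10.0, topology=top, frame_spacing=spacing)

    def to_mdtraj(self):
        """Build an ``mdtraj.Trajectory`` (for interop and cross-checks)."""
        import mdtraj as md

        top = md.Topology()
        chain = top.add_chain()
        residues = {}
        rnames = self.topology.residue_names
        for i in range(1, self.topology.n_residues + 1):
            rname = rnames[i - 1] if rnames is not None else "ALA"
            residues[i] = top.add_residue(rname, chain)
        for name, element, ri in zip(
            self.topology.atom_names, self.topology.elements, self.topology.residue_indices
        ):
            top.add_atom(name, md.element.get_by_symbol(element), residues[int(ri)])
        top.create_standard_bonds()
        return md.Trajectory(xyz=self.coordinates / 10.0, topology=top)
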