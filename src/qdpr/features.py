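"""Per-residue biophysical feature extraction from trajectory ensembles.

Five feature families are provided, mirroring the labels used to train
sequence-to-feature surrogate networks:

* ``rmsf`` — by-residue root-mean-square fluctuation of alpha-carbons after
  two-pass least-squares superposition onto the mean structure (Angstrom).
* ``ks_hbond`` — by-residue Kabsch-Sander backbone hydrogen-bond energy
  (kcal/mol): the DSSP electrostatic model, bonds accepted below -0.5
  kcal/mol, each residue credited with the energies of bonds it participates
  in as donor or acceptor, averaged over frames.
* ``wn_hbond`` — by-residue Wernet-Nilsson hydrogen-bond participation: mean
  bonds per frame under the angle-dependent distance cutoff
  r_DA < 3.3 A - 0.00044 * delta^2 (delta in degrees). The criterion is
  geometric, so the family reports occupancy counts, not energies.
* ``sasa`` — by-residue Shrake-Rupley solvent-accessible surface area with a
  deterministic golden-spiral sphere lattice (Angstrom^2), probe 1.4 A.
* ``pca_weight`` — relative variance weights of the trajectory projected
  onto an essential-dynamics PCA basis fitted to a reference trajectory.

The first 10% of each trajectory segment is discarded as equilibration
before extraction (configurable).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import superpose
from .trajectory import TrajectoryEnsemble

__all__ = [
    "FeatureEntry",
    "FeatureSchema",
    "FeatureTable",
    "PCABasis",
    "BY_RESIDUE_FAMILIES",
    "discard_equilibration",
    "compute_rmsf",
    "compute_ks_hbond",
    "compute_wn_hbond",
    "compute_sasa",
    "fit_pca_basis",
    "project_weights",
    "extract_features",
    "by_residue_schema",
    "gb1_schema",
]

BY_RESIDUE_FAMILIES = ("rmsf", "ks_hbond", "wn_hbond", "sasa")
KS_COUPLING = 0.084 * 332.0  # kcal/mol * Angstrom, DSSP electrostatic constant
KS_CUTOFF = -0.5  # kcal/mol


@dataclasses.dataclass(frozen=True)
class FeatureEntry:
    feature_id: str
    family: str
    residue: int | None  # 1-based; None for pca_weight / global features


@dataclasses.dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature definitions; the contract for every feature vector."""

    entries: tuple[FeatureEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.feature_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("feature ids must be unique")
        for e in self.entries:
            if e.family == "pca_weight" and e.residue is not None:
                raise ValueError("pca_weight features carry no residue assignment")
        for fam in BY_RESIDUE_FAMILIES:
            residues = [e.residue for e in self.entries if e.family == fam]
            if len(set(residues)) != len(residues):
                raise ValueError(f"family {fam} repeats a residue")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(e.feature_id for e in self.entries)

    @property
    def families(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.entries:
            if e.family not in seen:
                seen.append(e.family)
        return tuple(seen)

    def family_slice(self, family: str) -> np.ndarray:
        """Indices (into the feature vector) of one family, schema order."""
        return np.array([i for i, e in enumerate(self.entries) if e.family == family])

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                [dataclasses.asdict(e) for e in self.entries], f, indent=1
            )

    @classmethod
    def from_json(cls, path) -> "FeatureSchema":
        with open(path) as f:
            return cls(tuple(FeatureEntry(**d) for d in json.load(f)))


def by_residue_schema(
    families: Sequence[str], n_residues: int, n_pca: int = 0
) -> FeatureSchema:
    """Schema with one entry per residue for each by-residue family, plus
    ``n_pca`` trailing PCA-weight entries."""
    entries = [
        FeatureEntry(f"{fam}_{r}", fam, r)
        for fam in families
        for r in range(1, n_residues + 1)
    ]
    entries += [FeatureEntry(f"pca_weight_{k}", "pca_weight", None) for k in range(1, n_pca + 1)]
    return FeatureSchema(tuple(entries))


def gb1_schema() -> FeatureSchema:
    """The GB1 label layout: four by-residue families over 56 residues plus
    70 PCA projection weights — 294 labels per variant."""
    return by_residue_schema(BY_RESIDUE_FAMILIES, 56, n_pca=70)


@dataclasses.dataclass
class FeatureTable:
    """Variants x features label matrix with its schema and optional [0,1]
    rescaling bounds."""

    schema: FeatureSchema
    values: pd.DataFrame  # index: variant_id, columns: schema.feature_ids
    scaling: pd.DataFrame | None = None  # columns: min, max per feature

    def __post_init__(self) -> None:
        if tuple(self.values.columns) != self.schema.feature_ids:
            raise ValueError("feature table columns must match schema order")

    def to_csv(self, path, schema_path=None) -> None:
        self.values.to_csv(path, index_label="variant_id")
        if schema_path is not None:
            self.schema.to_json(schema_path)

    @classmethod
    def from_csv(cls, path, schema_path) -> "FeatureTable":
        schema = FeatureSchema.from_json(schema_path)
        values = pd.read_csv(path, index_col="variant_id")
        return cls(schema=schema, values=values)


@dataclasses.dataclass(frozen=True)
class PCABasis:
    """Essential-dynamics basis from a reference trajectory's alpha-carbons."""

    mean_structure: np.ndarray  # (n_ca, 3)
    components: np.ndarray  # (k, 3 * n_ca), orthonormal rows
    component_variances: np.ndarray  # non-increasing
    ca_atom_names: tuple[str, ...] = ("CA",)

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(len(self.components)), atol=1e-8):
            raise ValueError("components must be orthonormal")
        if np.any(np.diff(self.component_variances) > 1e-12):
            raise ValueError("component variances must be non-increasing")


# --------------------------------------------------------------------------
# equilibration
# --------------------------------------------------------------------------

def discard_equilibration(
    traj: TrajectoryEnsemble, fraction: float = 0.1
) -> TrajectoryEnsemble:
    """Drop the first ``floor(fraction * n)`` frames of each segment."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    keep_blocks, new_segments, cursor = [], [], 0
    for a, b in traj.segments:
        n_drop = int(np.floor(fraction * (b - a)))
        kept = b - a - n_drop
        if kept <= 0:
            raise ValueError(
                f"segment ({a}, {b}) has no frames left after discarding {n_drop}"
            )
        keep_blocks.append(traj.coordinates[a + n_drop : b])
        new_segments.append((cursor, cursor + kept))
        cursor += kept
    return TrajectoryEnsemble(
        coordinates=np.concatenate(keep_blocks),
        topology=traj.topology,
        frame_spacing=traj.frame_spacing,
        segments=tuple(new_segments),
    )


# --------------------------------------------------------------------------
# backbone atom lookup helpers
# --------------------------------------------------------------------------

def _ca_indices(traj: TrajectoryEnsemble) -> np.ndarray:
    top = traj.topology
    idx = np.full(top.n_residues, -1)
    for r in range(1, top.n_residues + 1):
        a = top.atom_index(r, "CA")
        if a is None:
            raise ValueError(f"residue {r} has no alpha-carbon")
        idx[r - 1] = a
    return idx


def _backbone_indices(traj: TrajectoryEnsemble, names: Sequence[str]) -> dict:
    """Per-name arrays of atom indices by residue; -1 where absent."""
    top = traj.topology
    out = {}
    for name in names:
        arr = np.full(top.n_residues, -1)
        for r in range(1, top.n_residues + 1):
            a = top.atom_index(r, name)
            arr[r - 1] = -1 if a is None else a
        out[name] = arr
    return out


def _reconstruct_amide_h(
    coords: np.ndarray, n_idx, ca_idx, c_idx, residue: np.ndarray
) -> np.ndarray:
    """Amide H for each residue in ``residue`` (0-based, >=1): 1.01 A from N
    along the bisector of (N-CA) and (N-C_prev). Shape (F, len(residue), 3)."""
    n = coords[:, n_idx[residue]]
    ca = coords[:, ca_idx[residue]]
    c_prev = coords[:, c_idx[residue - 1]]
    u1 = n - ca
    u1 /= np.linalg.norm(u1, axis=-1, keepdims=True)
    u2 = n - c_prev
    u2 /= np.linalg.norm(u2, axis=-1, keepdims=True)
    bis = u1 + u2
    bis /= np.linalg.norm(bis, axis=-1, keepdims=True)
    return n + 1.01 * bis


# --------------------------------------------------------------------------
# RMSF
# --------------------------------------------------------------------------

def _superpose_on_mean(traj: TrajectoryEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass superposition on alpha-carbons.

    Returns (superposed coordinates, alpha-carbon mean structure).
    """
    ca = _ca_indices(traj)
    coords = superpose(traj.coordinates, traj.coordinates[0], fit_atoms=ca)
    mean = coords.mean(axis=0)
    coords = superpose(coords, mean, fit_atoms=ca)
    return coords, coords[:, ca].mean(axis=0)


def compute_rmsf(traj: TrajectoryEnsemble) -> np.ndarray:
    """Per-residue alpha-carbon RMSF (Angstrom) about the mean structure."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    coords, _ = _superpose_on_mean(traj)
    ca = coords[:, _ca_indices(traj)]
    dev = ca - ca.mean(axis=0)
    return np.sqrt((dev**2).sum(axis=-1).mean(axis=0))


# --------------------------------------------------------------------------
# Kabsch-Sander hydrogen-bond energies
# --------------------------------------------------------------------------

def kabsch_sander_energy(r_on, r_ch, r_oh, r_cn) -> np.ndarray:
    """DSSP electrostatic hydrogen-bond energy (kcal/mol) from the four
    donor/acceptor inter-atomic distances (Angstrom)."""
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _ks_frame_energies(
    coords: np.ndarray, traj: TrajectoryEnsemble
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Energy matrix E[f, donor, acceptor] plus donor/acceptor residue ids."""
    top = traj.topology
    bb = _backbone_indices(traj, ("N", "CA", "C", "O", "H"))
    res_names = top.residue_names or tuple("UNK" for _ in range(top.n_residues))

    acceptors = np.flatnonzero((bb["C"] >= 0) & (bb["O"] >= 0))  # 0-based residues
    donor_mask = (bb["N"] >= 0) & (np.arange(top.n_residues) >= 1)
    donor_mask &= np.array([not rn.startswith("PRO") for rn in res_names])
    donors = np.flatnonzero(donor_mask)
    missing = np.flatnonzero(bb["N"] < 0)
    if missing.size:
        raise ValueError(f"residue {missing[0] + 1} lacks backbone N")

    n_xyz = coords[:, bb["N"][donors]]
    have_h = bb["H"][donors] >= 0
    h_xyz = np.empty_like(n_xyz)
    if have_h.any():
        h_xyz[:, have_h] = coords[:, bb["H"][donors[have_h]]]
    if (~have_h).any():
        rebuildable = donors[~have_h]
        ok = (bb["CA"][rebuildable] >= 0) & (bb["C"][rebuildable - 1] >= 0)
        if not ok.all():
            raise ValueError(
                f"cannot reconstruct amide H for residue {rebuildable[~ok][0] + 1}"
            )
        h_xyz[:, ~have_h] = _reconstruct_amide_h(
            coords, bb["N"], bb["CA"], bb["C"], rebuildable
        )
    c_xyz = coords[:, bb["C"][acceptors]]
    o_xyz = coords[:, bb["O"][acceptors]]

    def dist(a, b):  # (F, D, 3) x (F, A, 3) -> (F, D, A)
        return np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)

    e = kabsch_sander_energy(
        dist(n_xyz, o_xyz), dist(h_xyz, c_xyz), dist(h_xyz, o_xyz), dist(n_xyz, c_xyz)
    )
    # exclude self pairs and the covalently linked C(i-1)=O ... H-N(i) pair
    d_res = donors[:, None]
    a_res = acceptors[None, :]
    e[:, (d_res == a_res) | (a_res == d_res - 1)] = 0.0
    return e, donors, acceptors


def compute_ks_hbond(
    traj: TrajectoryEnsemble, chunk_frames: int = 500
) -> np.ndarray:
    """Per-residue Kabsch-Sander energy (kcal/mol), frame-averaged.

    Each accepted bond (E < -0.5 kcal/mol) contributes its energy to both the
    donor and the acceptor residue, preserving total-energy bookkeeping.
    """
    top = traj.topology
    totals = np.zeros(top.n_residues)
    for start in range(0, traj.n_frames, chunk_frames):
        coords = traj.coordinates[start : start + chunk_frames]
        e, donors, acceptors = _ks_frame_energies(coords, traj)
        e = np.where(e < KS_CUTOFF, e, 0.0)
        totals[donors] += e.sum(axis=2).sum(axis=0)
        totals[acceptors] += e.sum(axis=1).sum(axis=0)
    return totals / traj.n_frames


# --------------------------------------------------------------------------
# Wernet-Nilsson hydrogen bonds
# --------------------------------------------------------------------------

def compute_wn_hbond(
    traj: TrajectoryEnsemble, chunk_frames: int = 500
) -> np.ndarray:
    """Per-residue mean hydrogen-bond participation count per frame under the
    Wernet-Nilsson cone criterion r_DA < 3.3 - 0.00044 * delta^2 (A, deg)."""
    top = traj.topology
    bb = _backbone_indices(traj, ("N", "CA", "C", "O", "H"))
    donors = np.flatnonzero(bb["H"] >= 0)  # residues with an explicit polar H
    acceptors = np.flatnonzero(bb["O"] >= 0)
    counts = np.zeros(top.n_residues)
    if donors.size == 0:
        warnings.warn("no polar hydrogens in topology; Wernet-Nilsson counts are zero")
        return counts
    d_res = donors[:, None]
    a_res = acceptors[None, :]
    excluded = (d_res == a_res) | (a_res == d_res - 1)
    for start in range(0, traj.n_frames, chunk_frames):
        coords = traj.coordinates[start : start + chunk_frames]
        d_xyz = coords[:, bb["N"][donors]]
        h_xyz = coords[:, bb["H"][donors]]
        a_xyz = coords[:, bb["O"][acceptors]]
        da = a_xyz[:, None, :, :] - d_xyz[:, :, None, :]
        r_da = np.linalg.norm(da, axis=-1)
        dh = h_xyz - d_xyz
        dh /= np.linalg.norm(dh, axis=-1, keepdims=True)
        cos_delta = np.einsum("fdai,fdi->fda", da / np.maximum(r_da[..., None], 1e-12), dh)
        delta = np.degrees(np.arccos(np.clip(cos_delta, -1.0, 1.0)))
        bonded = (r_da < 3.3 - 0.00044 * delta**2) & ~excluded
        counts[donors] += bonded.sum(axis=2).sum(axis=0)
        counts[acceptors] += bonded.sum(axis=1).sum(axis=0)
    return counts / traj.n_frames


# --------------------------------------------------------------------------
# Shrake-Rupley SASA
# --------------------------------------------------------------------------

def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def compute_sasa(
    traj: TrajectoryEnsemble,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-residue Shrake-Rupley SASA (Angstrom^2), frame-averaged."""
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if n_sphere_points < 60:
        raise ValueError("need at least 60 sphere points")
    top = traj.topology
    radii = np.asarray(top.radii, float) + probe_radius
    if np.any(np.asarray(top.radii) <= 0):
        raise ValueError("atomic radii must be positive")
    sphere = golden_spiral_points(n_sphere_points)
    per_res = np.zeros(top.n_residues)
    res_of_atom = top.residue_indices - 1
    for f in range(traj.n_frames):
        xyz = traj.coordinates[f]
        diff = xyz[:, None, :] - xyz[None, :, :]
        d2 = (diff**2).sum(-1)
        cut = (radii[:, None] + radii[None, :]) ** 2
        np.fill_diagonal(d2, np.inf)
        neighbor_lists = [np.flatnonzero(d2[i] < cut[i]) for i in range(top.n_atoms)]
        for i in range(top.n_atoms):
            pts = xyz[i] + radii[i] * sphere
            nb = neighbor_lists[i]
            # exactly coincident atoms are duplicates: only the first of a
            # coincident group contributes surface
            dupes = nb[d2[i, nb] < 1e-12]
            if (dupes < i).any():
                continue
            nb = nb[d2[i, nb] >= 1e-12]
            if nb.size:
                dist2 = ((pts[:, None, :] - xyz[nb][None, :, :]) ** 2).sum(-1)
                exposed = (dist2 >= (radii[nb] ** 2)[None, :]).all(axis=1)
                frac = exposed.mean()
            else:
                frac = 1.0
            per_res[res_of_atom[i]] += 4.0 * np.pi * radii[i] ** 2 * frac
    return per_res / traj.n_frames


# --------------------------------------------------------------------------
# essential-dynamics PCA
# --------------------------------------------------------------------------

def fit_pca_basis(
    reference_traj: TrajectoryEnsemble, n_components: int = 70
) -> PCABasis:
    """PCA of alpha-carbon motion in a reference trajectory."""
    coords, ca_mean = _superpose_on_mean(reference_traj)
    ca = coords[:, _ca_indices(reference_traj)]
    n_max = min(ca.shape[0] - 1, 3 * ca.shape[1])
    if n_components > n_max:
        raise ValueError(
            f"n_components={n_components} exceeds rank bound {n_max} "
            f"({ca.shape[0]} frames, {ca.shape[1]} alpha-carbons)"
        )
    x = ca.reshape(ca.shape[0], -1)
    x = x - x.mean(axis=0)
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x)
    return PCABasis(
        mean_structure=ca_mean,
        components=pca.components_,
        component_variances=pca.explained_variance_,
    )


def project_weights(traj: TrajectoryEnsemble, basis: PCABasis) -> np.ndarray:
    """Relative variance weights of the trajectory on the basis components.

    Frames are superposed onto the basis mean structure; the projection
    variance on each component is normalized by the sum over the retained
    components, so the weights form a distribution summing to 1.
    """
    ca_idx = _ca_indices(traj)
    if len(ca_idx) != len(basis.mean_structure):
        raise ValueError(
            f"trajectory has {len(ca_idx)} alpha-carbons, basis expects "
            f"{len(basis.mean_structure)}"
        )
    full_ref = np.zeros((traj.n_atoms, 3))
    full_ref[ca_idx] = basis.mean_structure
    coords = superpose(traj.coordinates, full_ref, fit_atoms=ca_idx)
    x = coords[:, ca_idx].reshape(traj.n_frames, -1)
    proj = (x - x.mean(axis=0)) @ basis.components.T
    var = proj.var(axis=0)
    total = var.sum()
    if total <= 0:
        raise ValueError("trajectory has no variance on the basis components")
    return var / total


# --------------------------------------------------------------------------
# schema-driven extraction
# --------------------------------------------------------------------------

_FAMILY_EXTRACTORS: dict[str, Callable] = {}


def register_family(name: str, fn: Callable[[TrajectoryEnsemble], np.ndarray]) -> None:
    """Register a custom by-residue extractor (signature: traj -> vector)."""
    _FAMILY_EXTRACTORS[name] = fn


def extract_features(
    traj: TrajectoryEnsemble,
    schema: FeatureSchema,
    basis: PCABasis | None = None,
    equilibration_fraction: float = 0.1,
    sasa_probe_radius: float = 1.4,
    sasa_points: int = 960,
) -> np.ndarray:
    """Extract the feature vector defined by ``schema`` from one ensemble."""
    traj = discard_equilibration(traj, equilibration_fraction)
    per_family: dict[str, np.ndarray] = {}
    for fam in schema.families:
        if fam == "rmsf":
            per_family[fam] = compute_rmsf(traj)
        elif fam == "ks_hbond":
            per_family[fam] = compute_ks_hbond(traj)
        elif fam == "wn_hbond":
            per_family[fam] = compute_wn_hbond(traj)
        elif fam == "sasa":
            per_family[fam] = compute_sasa(traj, sasa_probe_radius, sasa_points)
        elif fam == "pca_weight":
            if basis is None:
                raise ValueError("schema includes pca_weight but no basis given")
            per_family[fam] = project_weights(traj, basis)
        elif fam in _FAMILY_EXTRACTORS:
            per_family[fam] = np.asarray(_FAMILY_EXTRACTORS[fam](traj), float)
        else:
            raise ValueError(f"no extractor registered for family {fam!r}")

    out = np.empty(len(schema))
    cursors: dict[str, int] = {}
    for i, e in enumerate(schema.entries):
        vec = per_family[e.family]
        if e.residue is not None:
            out[i] = vec[e.residue - 1]
        else:  # residue-free entries consume the family vector in order
            j = cursors.get(e.family, 0)
            out[i] = vec[j]
            cursors[e.family] = j + 1
    return out
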