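"""Synthetic study system: toy proteins, mutation-responsive pseudo-dynamics,
and epistatic fitness landscapes with known ground truth.

The generator stands in for expensive all-atom simulation and deep
mutational scanning. A toy helix-loop-helix chain carries a Gaussian-network
dynamics model: residues are nodes, spatial contacts are springs, and each
amino acid contributes a stiffness multiplier to the springs incident on its
residue (hydrophobic, bulky residues stiffen their neighborhood). Trajectory
frames are i.i.d. samples from the Gaussian ensemble whose displacement
covariance is the pseudo-inverse of the spring (Kirchhoff) matrix — so every
downstream extractor has a closed-form oracle, and a mutation perturbs
dynamics locally but measurably, propagating through the contact network.

Fitness landscapes are explicit functions of a few residues' extracted
dynamic features plus an optional pairwise epistatic term and observation
noise; the ground truth is recorded so recovery can be tested end to end.
Frames are independent rather than time-ordered, which is immaterial here
because no in-scope extractor uses temporal ordering.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._aa import AA_ALPHABET, AA_INDEX, descriptor_table, DESCRIPTOR_NAMES
from .features import (
    FeatureSchema,
    FeatureTable,
    PCABasis,
    by_residue_schema,
    extract_features,
    fit_pca_basis,
)
from .geometry import build_backbone
from .sequences import MutationSamplerConfig, Variant, sample_variants
from .campaign import LabeledPool
from .trajectory import DEFAULT_VDW_RADII, Topology, TrajectoryEnsemble

__all__ = [
    "ToyProtein",
    "DynamicsModel",
    "GroundTruthConfig",
    "PoolSpec",
    "make_toy_protein",
    "simulate_trajectory",
    "make_landscape",
    "default_synthetic_schema",
    "default_ground_truth",
]

_HELIX = (-57.0, -47.0)
_TURN = (55.0, 45.0)  # left-handed turn dihedrals for the loop

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclasses.dataclass(frozen=True)
class ToyProtein:
    """A folded toy chain: sequence, backbone coordinates, contact graph."""

    sequence: str
    backbone: dict  # atom name -> (n_residues, 3) arrays; H has NaN at Nterm
    contacts: tuple[tuple[int, int], ...]  # 0-based residue pairs, i < j
    ss: str = ""  # per-residue secondary structure: H (helix) / L (loop)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def ca_coords(self) -> np.ndarray:
        return self.backbone["CA"]

    def topology(self) -> Topology:
        names, elements, res_idx = [], [], []
        for i in range(self.n_residues):
            atom_list = ["N", "CA", "C", "O"]
            if i > 0 and not np.isnan(self.backbone["H"][i]).any():
                atom_list.append("H")
            for nm in atom_list:
                names.append(nm)
                elements.append(nm[0] if nm[0] in "HNCO" else "C")
                res_idx.append(i + 1)
        return Topology(
            atom_names=tuple(names),
            elements=tuple(elements),
            radii=np.array([DEFAULT_VDW_RADII[e] for e in elements]),
            residue_indices=np.asarray(res_idx),
            residue_names=tuple(_AA3[aa] for aa in self.sequence),
        )

    def reference_coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array matching :meth:`topology` atom order."""
        rows = []
        for i in range(self.n_residues):
            for nm in ("N", "CA", "C", "O"):
                rows.append(self.backbone[nm][i])
            if i > 0 and not np.isnan(self.backbone["H"][i]).any():
                rows.append(self.backbone["H"][i])
        return np.asarray(rows)

    def to_pdb(self, path) -> None:
        top = self.topology()
        coords = self.reference_coordinates()
        with open(path, "w") as f:
            serial = 0
            for (name, element, ri, xyz) in zip(
                top.atom_names, top.elements, top.residue_indices, coords
            ):
                serial += 1
                rname = _AA3[self.sequence[ri - 1]]
                pad = "" if len(name) >= 4 else " "
                f.write(
                    f"ATOM  {serial:5d} {pad}{name:<3s} {rname} A{ri:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
                )
            f.write("END\n")


def make_toy_protein(
    n_residues: int,
    seed: int = 0,
    contact_cutoff: float = 8.0,
    loop_length: int = 4,
) -> ToyProtein:
    """Build a helix-loop-helix toy protein with a seeded random sequence.

    Prolines are excluded from the sequence so every residue past the
    N-terminus carries an amide hydrogen-bond donor.
    """
    if not 10 <= n_residues <= 500:
        raise ValueError("n_residues must be in [10, 500]")
    rng = np.random.default_rng(seed)
    alphabet = [aa for aa in AA_ALPHABET if aa != "P"]
    sequence = "".join(alphabet[int(i)] for i in rng.integers(len(alphabet), size=n_residues))

    h1 = (n_residues - loop_length) // 2
    phis, psis, ss = [], [], []
    for i in range(n_residues):
        if i < h1:
            phi, psi = _HELIX
            ss.append("H")
        elif i < h1 + loop_length:
            phi, psi = _TURN
            ss.append("L")
        else:
            phi, psi = _HELIX
            ss.append("H")
        phis.append(phi)
        psis.append(psi)
    backbone = dict(build_backbone(np.array(phis), np.array(psis)))

    ca = backbone["CA"]
    diff = ca[:, None] - ca[None, :]
    dist = np.linalg.norm(diff, axis=-1)
    contacts = []
    for i in range(n_residues):
        for j in range(i + 1, n_residues):
            if j == i + 1 or dist[i, j] < contact_cutoff:
                contacts.append((i, j))
    return ToyProtein(
        sequence=sequence, backbone=backbone, contacts=tuple(contacts),
        ss="".join(ss),
    )


def _default_stiffness_table() -> dict[str, float]:
    """Per-amino-acid spring multipliers: exp(standardized hydropathy).

    Hydrophobic, tightly packed residues stiffen their local contacts,
    flexible polar ones soften them; multipliers span roughly [0.2, 5] so a
    single substitution produces a clearly resolvable local dynamics change
    against the frame-sampling noise of a short ensemble.
    """
    table = descriptor_table()
    col = DESCRIPTOR_NAMES.index("hydropathy")
    return {aa: float(np.exp(table[AA_INDEX[aa], col])) for aa in AA_ALPHABET}


@dataclasses.dataclass
class DynamicsModel:
    """Gaussian-network dynamics for a toy protein.

    ``noise_scale`` (Angstrom) sets the overall fluctuation amplitude: the
    per-axis displacement covariance is noise_scale^2 * pinv(Kirchhoff).
    """

    protein: ToyProtein
    spring_constant: float = 1.0
    tether_spring: float = 1.0
    noise_scale: float = 0.55
    conserve_total_stiffness: bool = True
    stiffness_table: dict[str, float] = dataclasses.field(
        default_factory=_default_stiffness_table
    )

    def kirchhoff(self, sequence: str | None = None) -> np.ndarray:
        """Spring (Kirchhoff) matrix of the contact network for a sequence.

        With ``conserve_total_stiffness`` (default) the matrix is rescaled to
        the wild-type trace, so mutations redistribute stiffness locally
        rather than changing overall rigidity — otherwise a single
        hydropathy-shifting substitution moves every residue's fluctuation
        through one collective softness mode, which would dominate the
        mutation response."""
        seq = self.protein.sequence if sequence is None else sequence
        n = self.protein.n_residues
        if len(seq) != n:
            raise ValueError("sequence length mismatch")
        gamma = self._raw_kirchhoff(seq)
        if self.conserve_total_stiffness and seq != self.protein.sequence:
            gamma = gamma * (
                np.trace(self._raw_kirchhoff(self.protein.sequence)) / np.trace(gamma)
            )
        return gamma

    def _raw_kirchhoff(self, seq: str) -> np.ndarray:
        n = self.protein.n_residues
        s = np.array([self.stiffness_table[aa] for aa in seq])
        gamma = np.zeros((n, n))
        for i, j in self.protein.contacts:
            k = self.spring_constant * np.sqrt(s[i] * s[j])
            gamma[i, j] -= k
            gamma[j, i] -= k
            gamma[i, i] += k
            gamma[j, j] += k
        # per-residue tether: local packing restraint, incident only to i, so
        # a substitution changes its own site's restraint directly
        gamma[np.diag_indices(n)] += self.tether_spring * s
        return gamma

    def _modes(self, sequence: str | None = None):
        gamma = self.kirchhoff(sequence)
        evals, evecs = np.linalg.eigh(gamma)
        tol = 1e-9 * max(evals.max(), 1.0)
        n_zero = int((evals < tol).sum())
        if n_zero > 1:
            raise ValueError(
                f"connectivity has {n_zero} zero modes; at most the global "
                "mode is allowed (disconnected contact graph?)"
            )
        return evals[n_zero:], evecs[:, n_zero:]

    def covariance(self, sequence: str | None = None) -> np.ndarray:
        """Per-axis residue displacement covariance (pseudo-inverse form)."""
        evals, evecs = self._modes(sequence)
        return self.noise_scale**2 * (evecs / evals) @ evecs.T

    def analytic_msf(
        self, sequence: str | None = None, superposed: bool = False
    ) -> np.ndarray:
        """Expected 3-D mean-square fluctuation per residue (Angstrom^2).

        With ``superposed=True`` the six rigid-body modes (translations and
        infinitesimal rotations about the mean structure) are projected out
        of the covariance first — the closed-form limit of what a
        least-squares superposition leaves behind, and the correct oracle
        for RMSF computed on superposed frames.
        """
        c = self.covariance(sequence)
        if not superposed:
            return 3.0 * np.diag(c)
        x = self.protein.ca_coords - self.protein.ca_coords.mean(axis=0)
        n = len(x)
        basis = np.zeros((3 * n, 6))
        for a in range(3):  # uniform translations
            basis[a::3, a] = 1.0
        eye = np.eye(3)
        for a in range(3):  # infinitesimal rotations about the centroid
            basis[:, 3 + a] = np.cross(np.broadcast_to(eye[a], (n, 3)), x).ravel()
        q, _ = np.linalg.qr(basis)
        c3 = np.kron(c, np.eye(3))
        proj = np.eye(3 * n) - q @ q.T
        m = proj @ c3 @ proj
        return np.diag(m).reshape(n, 3).sum(axis=1)

    def analytic_rmsf(
        self, sequence: str | None = None, superposed: bool = False
    ) -> np.ndarray:
        return np.sqrt(self.analytic_msf(sequence, superposed=superposed))


def simulate_trajectory(
    protein: ToyProtein,
    variant: Variant | None,
    model: DynamicsModel,
    n_frames: int = 300,
    seed: int = 0,
    n_segments: int = 2,
) -> TrajectoryEnsemble:
    """Sample a trajectory ensemble for a variant from the GNM ensemble.

    Each frame displaces every residue (rigidly, all its backbone atoms) by
    a correlated Gaussian draw with covariance noise_scale^2 * pinv(Gamma).
    The ensemble is split into ``n_segments`` equal independent segments.
    """
    seq = protein.sequence if variant is None else variant.sequence
    evals, evecs = model._modes(seq)
    amp = model.noise_scale / np.sqrt(evals)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, len(evals), 3))
    disp = np.einsum("rm,fmx->frx", evecs * amp, z)  # (F, n_res, 3)

    ref = protein.reference_coordinates()
    res_of_atom = protein.topology().residue_indices - 1
    coords = ref[None, :, :] + disp[:, res_of_atom, :]
    seg = max(1, n_frames // max(1, n_segments))
    bounds = []
    start = 0
    while start < n_frames:
        end = min(start + seg, n_frames)
        if n_frames - end < seg:
            end = n_frames
        bounds.append((start, end))
        start = end
    return TrajectoryEnsemble(
        coordinates=coords, topology=protein.topology(), segments=tuple(bounds)
    )


def default_synthetic_schema(n_residues: int, n_pca: int = 10) -> FeatureSchema:
    """Per-residue RMSF plus essential-dynamics PCA weights.

    RMSF responds to spring rescaling at first order, so it is the family a
    sequence model can actually learn from short ensembles; hydrogen-bond
    and surface-area families stay available for explicit schemas (their
    mutation response in this generator is second-order and frame-noise
    dominated, which makes them realistic distractors but poor ground-truth
    carriers).
    """
    return by_residue_schema(("rmsf",), n_residues, n_pca=n_pca)


def default_ground_truth(
    protein: ToyProtein,
    coefficients: tuple[float, float] = (1.0, 1.0),
    epistasis_coeff: float = 0.5,
    noise_sigma: float = 0.03,
) -> GroundTruthConfig:
    """Ground truth on the RMSF of one residue in each helix.

    Within the central portion of each helix (and at least four residues
    from either chain terminus) the residue whose wild-type amino acid has
    the most neutral hydropathy is chosen, so substitutions can both stiffen
    and soften the site and mutation effects are roughly sign-balanced.
    Fitness rewards flexibility at both sites — the saturating direction
    (rigidification) would otherwise give the two targets very different
    effect tails — plus a mild synergistic epistatic product term.
    """
    table = descriptor_table()
    col = DESCRIPTOR_NAMES.index("hydropathy")
    helices: list[list[int]] = []
    current: list[int] = []
    for i, s in enumerate(protein.ss or "H" * protein.n_residues):
        if s == "H":
            current.append(i)
        elif current:
            helices.append(current)
            current = []
    if current:
        helices.append(current)
    if len(helices) < 2:
        raise ValueError("default ground truth expects at least two helices")

    n = protein.n_residues

    def pick(helix: list[int]) -> int:
        core = helix[2:-2] if len(helix) > 6 else helix
        core = [i for i in core if 4 <= i < n - 4] or core
        return min(
            core, key=lambda i: abs(table[AA_INDEX[protein.sequence[i]], col])
        ) + 1  # 1-based

    r_a, r_b = pick(helices[0]), pick(helices[-1])
    return GroundTruthConfig(
        targets=(("rmsf", r_a, coefficients[0]), ("rmsf", r_b, coefficients[1])),
        epistasis=((0, 1, epistasis_coeff),),
        noise_sigma=noise_sigma,
    )


@dataclasses.dataclass(frozen=True)
class GroundTruthConfig:
    """Fitness = sum of coefficients on standardized deviations of target
    features from wild type, plus bounded pairwise epistatic interactions
    (tanh(z_i) * tanh(z_j)), plus noise.

    With ``standardize_targets`` (default) each target's deviation is scaled
    by its standard deviation across the generated pool, so every target
    contributes comparably regardless of how responsive its residue happens
    to be; the scales used are recorded in the truth record. Otherwise the
    fixed per-family ``feature_scales`` apply.
    """

    targets: tuple[tuple[str, int, float], ...]  # (family, residue 1-based, coeff)
    epistasis: tuple[tuple[int, int, float], ...] = ()  # target-index pairs
    noise_sigma: float = 0.05
    standardize_targets: bool = True
    feature_scales: dict = dataclasses.field(
        default_factory=lambda: {"rmsf": 0.03, "ks_hbond": 0.4}
    )

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("need at least one target feature")

    @property
    def target_residues(self) -> tuple[int, ...]:
        return tuple(sorted({res for _, res, _ in self.targets}))


@dataclasses.dataclass(frozen=True)
class PoolSpec:
    n_variants: int = 350
    min_mutations: int = 1
    max_mutations: int = 3
    excluded_positions: frozenset[int] = frozenset()


def _target_columns(schema: FeatureSchema, truth: GroundTruthConfig) -> list[int]:
    idx = {(e.family, e.residue): i for i, e in enumerate(schema.entries)}
    cols = []
    for family, residue, _ in truth.targets:
        key = (family, residue)
        if key not in idx:
            raise ValueError(f"target {key} not in schema")
        cols.append(idx[key])
    return cols


def _truth_fitness_batch(
    feats: np.ndarray,
    wt_feats: np.ndarray,
    schema: FeatureSchema,
    truth: GroundTruthConfig,
    scales: np.ndarray,
) -> np.ndarray:
    """Noiseless fitness for a (n_variants, |schema|) feature block.

    The epistatic interaction is a bounded product, tanh(z_i) * tanh(z_j):
    mutation-effect distributions here are strongly skewed (softening is
    unbounded, rigidification saturates), and an unbounded product of
    anticorrelated skewed deviations can cancel a target's main effect
    outright — which would make the ground-truth residue unrecoverable by
    construction. Saturating the interaction keeps the landscape
    nonadditive while guaranteeing the main effects stay visible.
    """
    cols = _target_columns(schema, truth)
    z = (feats[:, cols] - wt_feats[cols]) / scales
    fitness = z @ np.array([c for _, _, c in truth.targets])
    for i, j, c in truth.epistasis:
        fitness = fitness + c * np.tanh(z[:, i]) * np.tanh(z[:, j])
    return fitness


def make_landscape(
    protein: ToyProtein,
    model: DynamicsModel,
    truth: GroundTruthConfig,
    pool_spec: PoolSpec,
    seed: int = 0,
    n_frames: int = 1000,
    schema: FeatureSchema | None = None,
    basis: PCABasis | None = None,
    equilibration_fraction: float = 0.1,
):
    """Sample a labeled variant pool with simulated per-variant features.

    Every pool variant gets a simulated trajectory; its fitness label is the
    recorded ground-truth function of its extracted features plus noise.
    Returns ``(pool, feature_table, basis, truth_record)`` where the feature
    table holds the simulated ("true") features used both as surrogate
    training labels and to define fitness.
    """
    ref = protein.sequence
    n_mutable = protein.n_residues - len(pool_spec.excluded_positions)
    if pool_spec.min_mutations == pool_spec.max_mutations == 1:
        space = 19 * n_mutable
        if pool_spec.n_variants > space:
            raise ValueError(
                f"pool of {pool_spec.n_variants} exceeds the {space} single mutants"
            )
    schema = default_synthetic_schema(protein.n_residues) if schema is None else schema
    root = np.random.SeedSequence([int(seed) % 2**31])
    s_sample, s_wt, s_noise, *s_var = root.spawn(3 + pool_spec.n_variants)

    cfg = MutationSamplerConfig(
        min_mutations=pool_spec.min_mutations,
        max_mutations=pool_spec.max_mutations,
        excluded_positions=pool_spec.excluded_positions,
    )
    variants = sample_variants(
        ref, cfg, pool_spec.n_variants, np.random.default_rng(s_sample), unique=True
    )

    n_pca = int((np.asarray([e.family == "pca_weight" for e in schema.entries])).sum())
    wt_traj = simulate_trajectory(
        protein, None, model, n_frames=n_frames, seed=int(s_wt.generate_state(1)[0] % 2**31)
    )
    if basis is None and n_pca:
        from .features import discard_equilibration

        basis = fit_pca_basis(
            discard_equilibration(wt_traj, equilibration_fraction), n_components=n_pca
        )
    wt_feats = extract_features(
        wt_traj, schema, basis=basis, equilibration_fraction=equilibration_fraction
    )

    vids = [f"v{k:05d}" for k in range(len(variants))]
    feats = np.empty((len(variants), len(schema)))
    for k, variant in enumerate(variants):
        traj = simulate_trajectory(
            protein,
            variant,
            model,
            n_frames=n_frames,
            seed=int(s_var[k].generate_state(1)[0] % 2**31),
        )
        feats[k] = extract_features(
            traj, schema, basis=basis, equilibration_fraction=equilibration_fraction
        )

    cols = _target_columns(schema, truth)
    if truth.standardize_targets:
        scales = feats[:, cols].std(axis=0)
        if np.any(scales <= 0):
            raise ValueError("a target feature has zero variance across the pool")
    else:
        scales = np.array(
            [truth.feature_scales.get(fam, 1.0) for fam, _, _ in truth.targets]
        )
    noise_rng = np.random.default_rng(s_noise)
    fitness = _truth_fitness_batch(feats, wt_feats, schema, truth, scales)
    labels_arr = fitness + noise_rng.normal(0.0, truth.noise_sigma, size=len(variants))

    import pandas as pd

    table = FeatureTable(
        schema=schema,
        values=pd.DataFrame(feats, index=vids, columns=schema.feature_ids),
    )
    pool = LabeledPool(
        variants=dict(zip(vids, variants)),
        labels=dict(zip(vids, labels_arr.tolist())),
    )
    truth_record = {
        "targets": [list(t) for t in truth.targets],
        "epistasis": [list(t) for t in truth.epistasis],
        "noise_sigma": truth.noise_sigma,
        "target_scales": scales.tolist(),
        "wt_features": {
            fid: float(v) for fid, v in zip(schema.feature_ids, wt_feats)
        },
        "seed": seed,
    }
    return pool, table, basis, truth_record
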