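"""Synthetic conformational ensembles with known ground truth.

Every downstream stage of the pipeline (covariance PCA, RMSIP, crossing-over,
persistence, MSA mapping) depends only on second-order statistics and
per-frame geometry, so Gaussian ensembles with a prescribed eigen-spectrum are
a faithful stand-in for equilibrated molecular-dynamics fluctuations.  The
generator builds:

* toy self-avoiding structures (Cα trace plus one pseudo side-chain atom),
* Gaussian ensembles sampling ``mean + Σ_i sqrt(λ_i) z_i v_i``,
* variant families whose essential subspaces are rotated/permuted copies of a
  reference subspace, with the expected RMSIP emitted as ground truth,
* pure-cosine trajectories for sampling-convergence (cosine content) checks,
* two-atom contact series with designed occupancy patterns,
* homolog sets with insertions/deletions for MSA-mapping tests.

Mode vectors are constructed orthogonal to the six rigid-body modes of the
mean structure, so prescribed spectra are preserved by the superposition step
of the covariance analysis (internal motions only, as in fitted MD frames).

All randomness flows through one explicit integer seed per operation; there is
no global random state.  Units are nanometres.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MSA, AlignmentMap, Structure, TrajectoryEnsemble
from .errors import InvalidArgumentError
from .essential import rigid_body_modes

_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "X": "UNK",
}
_AA_LETTERS = "ARNDCQEGHILKMFPSTWYV"

#: Cα-Cα spacing of the toy trace (nm), the canonical trans peptide value.
CA_SPACING = 0.38

#: Wider spacing used when pseudo side chains are present, so that the
#: constant diagonal CB offset can never clash with lattice neighbours.
TOY_SPACING = 0.55


def _serpentine(n: int, spacing: float) -> np.ndarray:
    """A self-avoiding boustrophedon walk on a cubic lattice, (n, 3) in nm.

    Consecutive points are lattice neighbours, so the trace is chain-like, yet
    the walk fills a compact 3-D volume: all three principal dimensions are
    comparable, which keeps the rigid-body fit well conditioned (a straight
    chain would leave rotation about its axis nearly unconstrained).
    """
    side = int(np.ceil(n ** (1.0 / 3.0)))
    pts: list[tuple[int, int, int]] = []
    for z in range(side):
        ys = range(side) if z % 2 == 0 else range(side - 1, -1, -1)
        for y in ys:
            xs = range(side) if (y + z) % 2 == 0 else range(side - 1, -1, -1)
            for x in xs:
                pts.append((x, y, z))
                if len(pts) == n:
                    return spacing * np.asarray(pts, dtype=np.float64)
    return spacing * np.asarray(pts[:n], dtype=np.float64)


@dataclass
class SpectrumSpec:
    """A prescribed eigen-spectrum for a Gaussian ensemble.

    ``eigenvalues`` are variances (nm²) in descending order, one per mode;
    ``n_atoms`` fixes the configuration-space dimension 3·n_atoms.
    """

    eigenvalues: np.ndarray
    n_atoms: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64).ravel()
        if np.any(self.eigenvalues < 0):
            raise InvalidArgumentError("eigenvalues must be non-negative")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise InvalidArgumentError("eigenvalues must be in descending order")
        if self.eigenvalues.size > 3 * self.n_atoms:
            raise InvalidArgumentError("more eigenvalues than coordinate dimensions")

    @property
    def n_modes(self) -> int:
        return int(self.eigenvalues.size)


@dataclass
class PerturbationSpec:
    """How a variant's essential subspace differs from the reference.

    ``angle`` rotates every ground-truth mode by the same angle into a partner
    direction outside the reference essential subspace; ``swap_map`` then
    interchanges pairs of PC indices (1-based, disjoint pairs).  Angle 0 with
    no swaps reproduces the reference exactly.
    """

    angle: float = 0.0
    swap_map: tuple[tuple[int, int], ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle <= np.pi / 2:
            raise InvalidArgumentError("angle must lie in [0, pi/2]")
        seen: set[int] = set()
        for pair in self.swap_map:
            a, b = pair
            if a < 1 or b < 1 or a == b:
                raise InvalidArgumentError(f"bad swap pair {pair} (1-based, distinct)")
            if a in seen or b in seen:
                raise InvalidArgumentError("swap pairs must be disjoint")
            seen.update(pair)


@dataclass
class FamilyMember:
    """One variant of a synthetic family, with its ground truth."""

    label: str
    replicates: list[TrajectoryEnsemble]
    modes: np.ndarray            # (3N, K) ground-truth essential modes
    expected_rmsip: float        # vs the reference member, over D = K PCs
    perturbation: PerturbationSpec | None = None


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def make_toy_structure(n_residues: int, seed: int, sequence: str | None = None) -> Structure:
    """Self-avoiding toy protein: one Cα and one pseudo side-chain atom per residue.

    The Cα trace runs along x at the canonical 0.38 nm spacing with a small
    seeded jitter; CB atoms alternate sides of the trace.  Deterministic for a
    given seed; minimum inter-atom distance stays well above 0.2 nm.
    """
    if n_residues < 2:
        raise InvalidArgumentError("n_residues must be >= 2")
    if sequence is not None and len(sequence) != n_residues:
        raise InvalidArgumentError("sequence length must equal n_residues")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.01, 0.01, size=(2 * n_residues, 3))
    ca = _serpentine(n_residues, TOY_SPACING)
    cb_offset = 0.28 / np.sqrt(3.0) * np.ones(3)   # constant diagonal offset
    coords = np.empty((2 * n_residues, 3))
    coords[0::2] = ca + jitter[0::2]
    coords[1::2] = ca + cb_offset + jitter[1::2]
    letters = sequence.upper() if sequence else "A" * n_residues
    res_names = [_AA1TO3.get(ch, "UNK") for ch in letters]
    return Structure(
        serial=np.arange(1, 2 * n_residues + 1),
        name=np.array(["CA", "CB"] * n_residues),
        element=np.array(["C"] * 2 * n_residues),
        res_name=np.repeat(res_names, 2),
        res_id=np.repeat(np.arange(1, n_residues + 1), 2),
        chain_id=np.array(["A"] * 2 * n_residues),
        coords=coords,
    )


def make_ca_chain(n_atoms: int, seed: int = 0) -> Structure:
    """A Cα-only chain of ``n_atoms`` residues (used as ensemble topology)."""
    if n_atoms < 3:
        raise InvalidArgumentError("n_atoms must be >= 3")
    rng = np.random.default_rng(seed)
    coords = _serpentine(n_atoms, CA_SPACING)
    coords += rng.uniform(-0.01, 0.01, size=(n_atoms, 3))
    return Structure(
        serial=np.arange(1, n_atoms + 1),
        name=np.array(["CA"] * n_atoms),
        element=np.array(["C"] * n_atoms),
        res_name=np.array(["ALA"] * n_atoms),
        res_id=np.arange(1, n_atoms + 1),
        chain_id=np.array(["A"] * n_atoms),
        coords=coords,
    )


def internal_mode_basis(structure: Structure, n_modes: int, seed: int) -> np.ndarray:
    """Random orthonormal modes (3N, n_modes) orthogonal to rigid-body motion."""
    n3 = 3 * structure.n_atoms
    rigid = rigid_body_modes(structure.coords)
    if n_modes > n3 - rigid.shape[1]:
        raise InvalidArgumentError(
            f"at most {n3 - rigid.shape[1]} internal modes available, requested {n_modes}"
        )
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n3, n_modes))
    raw -= rigid @ (rigid.T @ raw)
    q, _ = np.linalg.qr(raw)
    return q[:, :n_modes]


# ---------------------------------------------------------------------------
# Gaussian ensembles
# ---------------------------------------------------------------------------

def sample_gaussian_ensemble(
    mean: Structure,
    spectrum: SpectrumSpec,
    eigenvectors: np.ndarray,
    n_frames: int,
    seed: int,
    system_id: str = "synthetic",
    replicate_id: int = 1,
) -> TrajectoryEnsemble:
    """Sample frames ``mean + Σ_i sqrt(λ_i)·z_i·v_i`` with z standard normal."""
    if n_frames < 1:
        raise InvalidArgumentError("n_frames must be >= 1")
    v = np.asarray(eigenvectors, dtype=np.float64)
    k = spectrum.n_modes
    if v.shape != (3 * mean.n_atoms, k):
        raise InvalidArgumentError(
            f"eigenvectors must have shape ({3 * mean.n_atoms}, {k}), got {v.shape}"
        )
    gram = v.T @ v
    if np.abs(gram - np.eye(k)).max() > 1e-8:
        raise InvalidArgumentError("eigenvectors are not orthonormal (deviation > 1e-8)")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, k))
    disp = (z * np.sqrt(spectrum.eigenvalues)) @ v.T
    coords = mean.coords.ravel() + disp
    return TrajectoryEnsemble(
        topology=mean,
        coords=coords.reshape(n_frames, mean.n_atoms, 3),
        system_id=system_id,
        replicate_ids=np.full(n_frames, replicate_id, dtype=int),
    )


def make_variant_family(
    reference_spectrum: SpectrumSpec,
    perturbations: list[PerturbationSpec],
    n_frames: int,
    n_replicates: int,
    seed: int,
    base_structure: Structure | None = None,
) -> list[FamilyMember]:
    """A reference ensemble plus variants with rotated/permuted essential modes.

    The first returned member is the unperturbed reference.  Each variant's
    mode *i* is ``cos(a)·v_i + sin(a)·u_i`` with ``u_i`` a partner direction
    orthogonal to the whole reference essential subspace, then ``swap_map``
    permutes mode indices.  ``expected_rmsip`` is the exact subspace overlap of
    the constructed bases versus the reference over D = K modes (|cos a| for a
    pure rotation), computed directly from inner products of the bases.
    """
    if len(perturbations) < 1:
        raise InvalidArgumentError("at least one perturbation is required")
    if n_replicates < 1:
        raise InvalidArgumentError("n_replicates must be >= 1")
    k = reference_spectrum.n_modes
    for p in perturbations:
        for pair in p.swap_map:
            if max(pair) > k:
                raise InvalidArgumentError(
                    f"swap index {max(pair)} beyond spectrum length {k}"
                )
    structure = base_structure if base_structure is not None else make_ca_chain(
        reference_spectrum.n_atoms, seed=seed
    )
    if structure.n_atoms != reference_spectrum.n_atoms:
        raise InvalidArgumentError("base structure atom count must match spectrum n_atoms")
    basis = internal_mode_basis(structure, 2 * k, seed=seed)
    ref_modes, partners = basis[:, :k], basis[:, k:]

    def sample_member(label: str, modes: np.ndarray, member_index: int) -> list[TrajectoryEnsemble]:
        reps = []
        for r in range(n_replicates):
            rep_seed = (seed + 100003 * member_index + 1009 * (r + 1)) % (2**31)
            reps.append(
                sample_gaussian_ensemble(
                    structure, reference_spectrum, modes, n_frames, rep_seed,
                    system_id=label, replicate_id=r + 1,
                )
            )
        return reps

    members = [
        FamilyMember(
            label="reference",
            replicates=sample_member("reference", ref_modes, 0),
            modes=ref_modes,
            expected_rmsip=_direct_rmsip(ref_modes, ref_modes),
        )
    ]
    for m, pert in enumerate(perturbations, start=1):
        modes = np.cos(pert.angle) * ref_modes + np.sin(pert.angle) * partners
        for a, b in pert.swap_map:
            modes[:, [a - 1, b - 1]] = modes[:, [b - 1, a - 1]]
        label = pert.label or f"variant{m}"
        members.append(
            FamilyMember(
                label=label,
                replicates=sample_member(label, modes, m),
                modes=modes,
                expected_rmsip=_direct_rmsip(ref_modes, modes),
                perturbation=pert,
            )
        )
    return members


def _direct_rmsip(v: np.ndarray, w: np.ndarray) -> float:
    """Ground-truth RMSIP by explicit double loop over the constructed bases."""
    d = v.shape[1]
    total = 0.0
    for i in range(d):
        for j in range(d):
            total += float(v[:, i] @ w[:, j]) ** 2
    return float(np.sqrt(total / d))


# ---------------------------------------------------------------------------
# special-purpose fixtures
# ---------------------------------------------------------------------------

def make_cosine_trajectory(
    mode: np.ndarray,
    amplitude: float,
    n_frames: int,
    mean: Structure | None = None,
) -> TrajectoryEnsemble:
    """An ensemble whose only motion is ``amplitude·cos(πt/T)`` along one mode.

    The projection of frame *t* (t = 0..T with T = n_frames-1) onto the mode
    is exactly the half-period cosine — the ideal positive control for the
    cosine-content diagnostic.
    """
    if n_frames < 4:
        raise InvalidArgumentError("n_frames must be >= 4")
    mode = np.asarray(mode, dtype=np.float64).ravel()
    norm = np.linalg.norm(mode)
    if norm == 0:
        raise InvalidArgumentError("mode vector must be non-zero")
    if mode.size % 3 != 0:
        raise InvalidArgumentError("mode length must be a multiple of 3")
    mode = mode / norm
    n_atoms = mode.size // 3
    if mean is None:
        mean = make_ca_chain(max(n_atoms, 3), seed=0)
        if mean.n_atoms != n_atoms:
            raise InvalidArgumentError("mode too short for a chain topology (need >= 9 components)")
    if 3 * mean.n_atoms != mode.size:
        raise InvalidArgumentError("mode length must equal 3 x mean atom count")
    t = np.arange(n_frames, dtype=np.float64)
    proj = amplitude * np.cos(np.pi * t / (n_frames - 1))
    coords = mean.coords.ravel() + proj[:, None] * mode
    return TrajectoryEnsemble(
        topology=mean,
        coords=coords.reshape(n_frames, mean.n_atoms, 3),
        system_id="cosine",
    )


def make_contact_series(
    occupancy_pattern: list[bool],
    bound_distance: float,
    unbound_distance: float,
) -> TrajectoryEnsemble:
    """Two-residue, two-atom ensemble with a designed per-frame contact pattern.

    A Lys NZ sits at the origin; an Asp OD1 sits on the x axis at
    ``bound_distance`` where the pattern is true and ``unbound_distance``
    elsewhere, so persistence at any cutoff between the two distances equals
    the designed occupancy fraction exactly.
    """
    if len(occupancy_pattern) == 0:
        raise InvalidArgumentError("occupancy pattern must be non-empty")
    if not bound_distance < unbound_distance:
        raise InvalidArgumentError("bound_distance must be < unbound_distance")
    topo = Structure(
        serial=np.array([1, 2]),
        name=np.array(["NZ", "OD1"]),
        element=np.array(["N", "O"]),
        res_name=np.array(["LYS", "ASP"]),
        res_id=np.array([1, 2]),
        chain_id=np.array(["A", "A"]),
        coords=np.array([[0.0, 0.0, 0.0], [unbound_distance, 0.0, 0.0]]),
    )
    n = len(occupancy_pattern)
    coords = np.zeros((n, 2, 3))
    dist = np.where(np.asarray(occupancy_pattern, dtype=bool), bound_distance, unbound_distance)
    coords[:, 1, 0] = dist
    return TrajectoryEnsemble(topology=topo, coords=coords, system_id="contact")


# ---------------------------------------------------------------------------
# homolog sets
# ---------------------------------------------------------------------------

@dataclass
class IndelSpec:
    """Per-system edits relative to the shared core sequence.

    ``deletions`` lists 0-based core-column indices the system lacks;
    ``insertions`` lists ``(after_core_column, length)`` pairs — extra residues
    the system carries after that core column (-1 inserts before the start).
    """

    deletions: tuple[int, ...] = ()
    insertions: tuple[tuple[int, int], ...] = ()


@dataclass
class HomologSet:
    """A synthetic homolog family: alignment, structures and mapping ground truth."""

    msa: MSA
    structures: dict[str, Structure]
    ground_truth: AlignmentMap
    shared_core_columns: list[int] = field(default_factory=list)


def make_homolog_set(
    n_systems: int,
    indel_spec: dict[int, IndelSpec] | None,
    seed: int,
    core_length: int = 10,
) -> HomologSet:
    """Homologous toy systems related through a constructed MSA.

    All systems share a random core sequence of ``core_length`` residues; the
    per-system :class:`IndelSpec` deletes core columns or inserts extra
    residues.  The emitted ground truth maps every core column present in all
    systems to the Cα atom indices of the generated structures.
    """
    if n_systems < 2:
        raise InvalidArgumentError("n_systems must be >= 2")
    if core_length < 2:
        raise InvalidArgumentError("core_length must be >= 2")
    spec = dict(indel_spec or {})
    for s, isp in spec.items():
        if not 0 <= s < n_systems:
            raise InvalidArgumentError(f"indel spec for unknown system index {s}")
        if any(not 0 <= c < core_length for c in isp.deletions):
            raise InvalidArgumentError("deletion column out of range")
        if any(not -1 <= pos < core_length or ln < 1 for pos, ln in isp.insertions):
            raise InvalidArgumentError("insertion position out of range")
    deleted_any = set().union(*(set(isp.deletions) for isp in spec.values()), set())
    shared_core = [c for c in range(core_length) if c not in deleted_any]
    if len(shared_core) < 2:
        raise InvalidArgumentError("indels leave fewer than 2 shared columns")

    rng = np.random.default_rng(seed)
    core_letters = rng.choice(list(_AA_LETTERS), size=core_length)

    # MSA columns: slot -1 insertions, then for each core column the column
    # itself followed by its insertion columns. Insertions never align across
    # systems (each gets its own column block per system).
    ins_blocks: dict[tuple[int, int], int] = {}  # (core_col, system) -> length
    for s, isp in spec.items():
        for pos, ln in isp.insertions:
            ins_blocks[(pos, s)] = ins_blocks.get((pos, s), 0) + ln

    column_plan: list[tuple[str, int, int]] = []  # (kind, core_col, system)
    for pos in range(-1, core_length):
        if pos >= 0:
            column_plan.append(("core", pos, -1))
        for s in range(n_systems):
            ln = ins_blocks.get((pos, s), 0)
            column_plan.extend(("ins", pos, s) for _ in range(ln))

    ids = [f"sys{s + 1}" for s in range(n_systems)]
    rows: list[list[str]] = []
    for s in range(n_systems):
        isp = spec.get(s, IndelSpec())
        row = []
        for kind, pos, owner in column_plan:
            if kind == "core":
                row.append("-" if pos in isp.deletions else str(core_letters[pos]))
            else:
                row.append(str(rng.choice(list(_AA_LETTERS))) if owner == s else "-")
        rows.append(row)
    msa = MSA(ids=ids, sequences=["".join(r) for r in rows])

    structures: dict[str, Structure] = {}
    atom_indices: dict[str, np.ndarray] = {}
    core_msa_columns = [
        i for i, (kind, pos, _) in enumerate(column_plan)
        if kind == "core" and pos in shared_core
    ]
    for s, sid in enumerate(ids):
        seq = msa.sequences[s]
        ungapped = seq.replace("-", "")
        st = make_toy_structure(len(ungapped), seed=seed + 7 * s + 1, sequence=ungapped)
        structures[sid] = st
        ca = st.ca_indices()
        ordinal = -1
        idx = []
        wanted = set(core_msa_columns)
        for col, ch in enumerate(seq):
            if ch != "-":
                ordinal += 1
                if col in wanted:
                    idx.append(int(ca[ordinal]))
        atom_indices[sid] = np.asarray(idx, dtype=int)

    gt = AlignmentMap(columns=core_msa_columns, atom_indices=atom_indices)
    return HomologSet(msa=msa, structures=structures, ground_truth=gt,
                      shared_core_columns=shared_core)
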