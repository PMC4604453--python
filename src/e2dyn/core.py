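"""Core in-memory containers shared by every stage.

Coordinates are in nanometres everywhere inside the library; the PDB layer
converts to/from ångström at the file boundary.  Residue numbering is 1-based
(PDB convention).  Atom selections address atoms by ``(chain, residue number,
atom name)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, SelectionError

#: Atomic masses (unified amu) for the elements the pipeline handles.
ATOMIC_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008, "P": 30.974}

#: Backbone atom names excluded when selecting a side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"})


@dataclass
class Structure:
    """A single conformation: parallel per-atom annotation arrays plus coordinates (nm)."""

    serial: np.ndarray        # (N,) int
    name: np.ndarray          # (N,) str, PDB atom names
    element: np.ndarray       # (N,) str
    res_name: np.ndarray      # (N,) str, 3-letter residue names
    res_id: np.ndarray        # (N,) int, 1-based residue numbers
    chain_id: np.ndarray      # (N,) str
    coords: np.ndarray        # (N, 3) float64, nm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidArgumentError("coords must have shape (N, 3)")
        for attr in ("serial", "name", "element", "res_name", "res_id", "chain_id"):
            arr = np.asarray(getattr(self, attr))
            if arr.shape != (n,):
                raise InvalidArgumentError(f"annotation '{attr}' must have length {n}")
            setattr(self, attr, arr)
        if not np.all(np.isfinite(self.coords)):
            raise InvalidArgumentError("coordinates must be finite")
        for ch in np.unique(self.chain_id):
            rid = self.res_id[self.chain_id == ch]
            if np.any(np.diff(rid.astype(int)) < 0):
                raise InvalidArgumentError(f"residue numbers decrease within chain {ch!r}")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        keys = list(zip(self.chain_id.tolist(), self.res_id.tolist()))
        return len(dict.fromkeys(keys))

    def ca_indices(self) -> np.ndarray:
        """Indices of Cα atoms, in structure order."""
        return np.flatnonzero(self.name == "CA")

    def residue_sequence(self) -> list[tuple[str, int, str]]:
        """Ordered unique ``(chain, res_id, res_name)`` triples."""
        seen: dict[tuple[str, int], str] = {}
        for ch, rid, rn in zip(self.chain_id, self.res_id, self.res_name):
            seen.setdefault((str(ch), int(rid)), str(rn))
        return [(ch, rid, rn) for (ch, rid), rn in seen.items()]

    def atom_index(self, chain: str, res_id: int, atom_name: str) -> int:
        """Index of the unique atom ``chain/res_id/atom_name``."""
        hits = np.flatnonzero(
            (self.chain_id == chain) & (self.res_id == int(res_id)) & (self.name == atom_name)
        )
        if hits.size == 0:
            raise SelectionError(f"no atom {chain}/{res_id}/{atom_name}")
        if hits.size > 1:
            raise SelectionError(f"ambiguous atom {chain}/{res_id}/{atom_name}")
        return int(hits[0])

    def residue_atom_indices(self, chain: str, res_id: int, sidechain_only: bool = False) -> np.ndarray:
        """All atom indices of one residue, optionally side chain only."""
        mask = (self.chain_id == chain) & (self.res_id == int(res_id))
        if sidechain_only:
            mask &= ~np.isin(self.name, list(BACKBONE_ATOMS))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(f"selection {chain}/{res_id} is empty")
        return idx

    def masses(self) -> np.ndarray:
        from .errors import ConfigurationError

        unknown = sorted({str(e) for e in self.element} - ATOMIC_MASSES.keys())
        if unknown:
            raise ConfigurationError(f"no mass for element(s): {', '.join(unknown)}")
        return np.array([ATOMIC_MASSES[str(e)] for e in self.element])


@dataclass
class TrajectoryEnsemble:
    """A conformational ensemble: ``(frames, atoms, 3)`` coordinates (nm) over one topology.

    ``replicate_ids`` records, per frame, which independent replicate the frame
    came from (1-based; a single-replicate ensemble is all ones).
    """

    topology: Structure
    coords: np.ndarray               # (F, N, 3) nm
    system_id: str = "system"
    replicate_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InvalidArgumentError("ensemble coords must have shape (F, N, 3)")
        if self.coords.shape[0] < 1:
            raise InvalidArgumentError("ensemble must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise InvalidArgumentError(
                f"frame atom count {self.coords.shape[1]} != topology atom count "
                f"{self.topology.n_atoms}"
            )
        if self.replicate_ids is None:
            self.replicate_ids = np.ones(self.coords.shape[0], dtype=int)
        else:
            self.replicate_ids = np.asarray(self.replicate_ids, dtype=int)
            if self.replicate_ids.shape != (self.coords.shape[0],):
                raise InvalidArgumentError("replicate_ids must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Structure:
        """Frame *i* as a standalone :class:`Structure`."""
        t = self.topology
        return Structure(t.serial, t.name, t.element, t.res_name, t.res_id, t.chain_id,
                         self.coords[i].copy())


@dataclass
class MSA:
    """An aligned set of sequences: parallel id and gapped-sequence lists."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise InvalidArgumentError("ids and sequences must have equal length")
        if len(self.ids) == 0:
            raise InvalidArgumentError("alignment must contain at least one record")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InvalidArgumentError(f"duplicate sequence id(s): {', '.join(dupes)}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise InvalidArgumentError(f"ragged alignment: lengths {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def sequence(self, seq_id: str) -> str:
        try:
            return self.sequences[self.ids.index(seq_id)]
        except ValueError:
            raise InvalidArgumentError(f"id {seq_id!r} not in alignment") from None


@dataclass
class AlignmentMap:
    """Cα correspondence across systems through ungapped MSA columns.

    ``columns`` are the 0-based MSA column indices shared (ungapped) by every
    mapped system; ``atom_indices[system]`` lists, in the same order, the Cα
    atom index in that system's structure for each shared column.
    """

    columns: list[int]
    atom_indices: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        ncol = len(self.columns)
        if sorted(self.columns) != self.columns or len(set(self.columns)) != ncol:
            raise InvalidArgumentError("columns must be strictly increasing")
        self.atom_indices = {k: np.asarray(v, dtype=int) for k, v in self.atom_indices.items()}
        for sys_id, idx in self.atom_indices.items():
            if idx.shape != (ncol,):
                raise InvalidArgumentError(f"atom list for {sys_id!r} has wrong length")
            if ncol > 1 and np.any(np.diff(idx) <= 0):
                raise InvalidArgumentError(f"atom indices for {sys_id!r} must be increasing")

    @property
    def n_columns(self) -> int:
        return len(self.columns)


@dataclass
class EssentialSubspace:
    """Result of a PCA of positional fluctuations.

    ``eigenvectors`` has orthonormal columns sorted by descending eigenvalue;
    ``mean`` is the flattened (3M,) mean conformation of the fitted frames.
    """

    mean: np.ndarray          # (3M,) nm
    eigenvectors: np.ndarray  # (3M, K) orthonormal columns
    eigenvalues: np.ndarray   # (K,) nm^2, descending, >= 0
    atom_map: np.ndarray | None = None  # atom indices this subspace was built on

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        if self.eigenvectors.shape[0] != self.mean.shape[0]:
            raise InvalidArgumentError("eigenvector dimension must match mean length")
        if self.eigenvalues.shape[0] != self.eigenvectors.shape[1]:
            raise InvalidArgumentError("one eigenvalue per eigenvector required")
        if np.any(np.diff(self.eigenvalues) > 0):
            raise InvalidArgumentError("eigenvalues must be sorted descending")
        if np.any(self.eigenvalues < 0):
            raise InvalidArgumentError("eigenvalues must be non-negative")

    @property
    def dim(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    def variance_fractions(self) -> np.ndarray:
        tot = self.total_variance
        if tot == 0.0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / tot


@dataclass
class ProjectionSeries:
    """Per-frame scalar projections of an ensemble onto one PC (1-based index)."""

    pc_index: int
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]
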