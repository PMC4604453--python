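"""Per-frame structural measurements.

Equilibration trimming and macro-trajectory assembly, solvent accessible
surface area (sphere-point algorithm with a deterministic golden-spiral point
set), inter-group distance series, and contact/H-bond persistence fractions.

The SASA routine rolls a probe of radius 0.14 nm (water) over van der Waals
spheres; the radii table is deliberately small and explicit (C/N/O/S/H/P) —
an unknown element is a configuration error, never a silent default.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Structure, TrajectoryEnsemble
from .errors import ConfigurationError, InvalidArgumentError, SelectionError

#: van der Waals radii (nm) used for surface computation.
VDW_RADII = {"C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180, "H": 0.120, "P": 0.180}

#: Water-probe radius (nm).
DEFAULT_PROBE_RADIUS = 0.14

#: Ion-pair / side-chain interaction distance threshold (nm).
DEFAULT_CONTACT_CUTOFF = 0.48

#: Hydrogen-bond geometric criterion: donor-acceptor cutoff (nm), D-H-A angle (deg).
HBOND_DISTANCE_CUTOFF = 0.35
HBOND_ANGLE_MIN = 120.0


@dataclass
class ContactSeries:
    """Distance series between two atom groups, optionally with a contact criterion."""

    distances: np.ndarray                   # (F,) nm
    replicate_ids: np.ndarray | None = None
    mode: str = "min-heavy"
    cutoff: float | None = None
    contacts: np.ndarray | None = None      # (F,) bool once a criterion is applied
    persistence: float | None = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64).ravel()
        if np.any(self.distances < 0):
            raise InvalidArgumentError("distances must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]


@dataclass
class SasaSeries:
    """Per-frame SASA (nm²) of a selection, with per-replicate mean and sd."""

    values: np.ndarray
    replicate_ids: np.ndarray
    per_replicate_mean: dict[int, float] = field(default_factory=dict)
    per_replicate_sd: dict[int, float] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=0))


# ---------------------------------------------------------------------------
# macro-trajectory assembly
# ---------------------------------------------------------------------------

def preprocess_macro_trajectory(
    replicates: list[TrajectoryEnsemble],
    trim: int | float = 0,
) -> TrajectoryEnsemble:
    """Drop the equilibration head of each replicate and concatenate the rest.

    ``trim`` is either a frame count (int) or a fraction of each replicate's
    length (float < 1).  Frames keep 1-based replicate provenance in
    concatenation order.  The macro-trajectory is the per-system input for the
    covariance analysis: independent sampling directions around one starting
    structure, joined.
    """
    if len(replicates) < 1:
        raise InvalidArgumentError("at least one replicate is required")
    topo = replicates[0].topology
    system_id = replicates[0].system_id
    blocks = []
    rep_ids = []
    for r, rep in enumerate(replicates, start=1):
        if rep.n_atoms != topo.n_atoms:
            raise InvalidArgumentError(f"replicate {r} atom count differs from replicate 1")
        if isinstance(trim, float) and not float(trim).is_integer():
            if not 0.0 <= trim < 1.0:
                raise InvalidArgumentError("fractional trim must lie in [0, 1)")
            n_trim = int(np.floor(trim * rep.n_frames))
        else:
            n_trim = int(trim)
            if n_trim < 0:
                raise InvalidArgumentError("trim must be non-negative")
        if n_trim >= rep.n_frames:
            raise InvalidArgumentError(
                f"trim of {n_trim} frames removes all {rep.n_frames} frames of replicate {r}"
            )
        kept = rep.coords[n_trim:]
        blocks.append(kept)
        rep_ids.append(np.full(kept.shape[0], r, dtype=int))
    return TrajectoryEnsemble(
        topology=topo,
        coords=np.concatenate(blocks, axis=0),
        system_id=system_id,
        replicate_ids=np.concatenate(rep_ids),
    )


# ---------------------------------------------------------------------------
# solvent accessible surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=np.float64) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def _radii_for(elements: np.ndarray) -> np.ndarray:
    unknown = sorted({str(e) for e in elements} - VDW_RADII.keys())
    if unknown:
        raise ConfigurationError(f"no van der Waals radius for element(s): {', '.join(unknown)}")
    return np.array([VDW_RADII[str(e)] for e in elements])


def sasa_shrake_rupley(
    frame: Structure,
    selection: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
) -> float:
    """SASA (nm²) of the selected atoms in one conformation.

    For each selected atom, test points on its probe-expanded sphere are
    checked against the probe-expanded spheres of *all* other atoms of the
    structure (every atom occludes, selected or not); the accessible fraction
    times the expanded-sphere area is summed over the selection.  Points
    exactly on an occluder's surface count as buried, so coincident identical
    atoms fully bury one another.
    """
    selection = np.asarray(selection)
    if selection.dtype == bool:
        selection = np.flatnonzero(selection)
    if selection.size == 0:
        raise SelectionError("SASA selection is empty")
    coords = frame.coords
    radii = _radii_for(frame.element) + probe_radius
    unit = _sphere_points(int(n_points))
    total = 0.0
    for a in np.asarray(selection, dtype=int):
        r_a = radii[a]
        # neighbour prefilter: only atoms whose expanded spheres can reach ours
        delta = coords - coords[a]
        d2 = np.einsum("ij,ij->i", delta, delta)
        near = np.flatnonzero(d2 <= (r_a + radii) ** 2)
        near = near[near != a]
        pts = coords[a] + r_a * unit
        accessible = np.ones(pts.shape[0], dtype=bool)
        for b in near:
            db = pts - coords[b]
            # closed ball with a relative tolerance: points on an occluder's
            # surface count as buried (coincident identical atoms bury fully)
            accessible &= np.einsum("ij,ij->i", db, db) > radii[b] ** 2 * (1 + 1e-9)
            if not accessible.any():
                break
        total += accessible.mean() * 4.0 * np.pi * r_a**2
    return float(total)


def sasa_series(
    ensemble: TrajectoryEnsemble,
    selection: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
) -> SasaSeries:
    """Per-frame SASA of a selection, summarised per replicate (mean ± sd)."""
    values = np.array([
        sasa_shrake_rupley(ensemble.frame(f), selection, probe_radius, n_points)
        for f in range(ensemble.n_frames)
    ])
    series = SasaSeries(values=values, replicate_ids=ensemble.replicate_ids.copy())
    for rep in np.unique(ensemble.replicate_ids):
        sub = values[ensemble.replicate_ids == rep]
        series.per_replicate_mean[int(rep)] = float(sub.mean())
        series.per_replicate_sd[int(rep)] = float(sub.std(ddof=0))
    return series


# ---------------------------------------------------------------------------
# distances and persistence
# ---------------------------------------------------------------------------

def distance_series(
    ensemble: TrajectoryEnsemble,
    group_a: np.ndarray,
    group_b: np.ndarray,
    mode: str = "min-heavy",
) -> ContactSeries:
    """Per-frame distance between two atom groups.

    ``mode='min-heavy'`` takes the minimum distance over all heavy-atom pairs
    (hydrogens excluded); ``mode='named-pair'`` requires single-atom groups
    and measures that one pair.
    """
    a = np.asarray(group_a, dtype=int).ravel()
    b = np.asarray(group_b, dtype=int).ravel()
    if a.size == 0 or b.size == 0:
        raise SelectionError("distance groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise SelectionError("distance groups overlap")
    if mode == "min-heavy":
        heavy = ensemble.topology.element != "H"
        a = a[heavy[a]]
        b = b[heavy[b]]
        if a.size == 0 or b.size == 0:
            raise SelectionError("a group contains no heavy atoms")
    elif mode == "named-pair":
        if a.size != 1 or b.size != 1:
            raise SelectionError("named-pair mode requires exactly one atom per group")
    else:
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    diff = ensemble.coords[:, a, None, :] - ensemble.coords[:, None, b, :]
    dist = np.sqrt(np.einsum("fabx,fabx->fab", diff, diff))
    return ContactSeries(
        distances=dist.min(axis=(1, 2)),
        replicate_ids=ensemble.replicate_ids.copy(),
        mode=mode,
    )


def contact_persistence(
    series: ContactSeries,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    hbond: tuple[int, int, int] | None = None,
    ensemble: TrajectoryEnsemble | None = None,
    hbond_distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
    hbond_angle_min: float = HBOND_ANGLE_MIN,
) -> ContactSeries:
    """Apply a contact criterion to a distance series; persistence = true fraction.

    The plain criterion is ``distance < cutoff`` (the ion-pair threshold, by
    default 0.48 nm on charged-group heavy atoms).  When ``hbond`` names
    ``(donor, hydrogen, acceptor)`` atom indices, the frame must additionally
    satisfy the geometric hydrogen-bond criterion: donor–acceptor distance
    below ``hbond_distance_cutoff`` and D-H-A angle >= ``hbond_angle_min``
    degrees, evaluated on ``ensemble``.
    """
    if cutoff <= 0:
        raise InvalidArgumentError("cutoff must be positive")
    contacts = series.distances < cutoff
    if hbond is not None:
        if ensemble is None:
            raise ConfigurationError("hydrogen-bond criterion requires the ensemble")
        donor, hydrogen, acceptor = (int(i) for i in hbond)
        if ensemble.topology.element[hydrogen] != "H":
            raise ConfigurationError(
                f"atom {hydrogen} ({ensemble.topology.name[hydrogen]}) is not a hydrogen"
            )
        if ensemble.n_frames != series.n_frames:
            raise InvalidArgumentError("ensemble frame count does not match the series")
        d = ensemble.coords[:, donor]
        h = ensemble.coords[:, hydrogen]
        a = ensemble.coords[:, acceptor]
        da = np.linalg.norm(d - a, axis=1)
        v1 = d - h
        v2 = a - h
        cosang = np.einsum("fx,fx->f", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        contacts &= (da < hbond_distance_cutoff) & (angle >= hbond_angle_min)
    return ContactSeries(
        distances=series.distances.copy(),
        replicate_ids=None if series.replicate_ids is None else series.replicate_ids.copy(),
        mode=series.mode,
        cutoff=cutoff,
        contacts=contacts,
        persistence=float(contacts.mean()),
    )
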