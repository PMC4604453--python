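"""Configuration-driven orchestration of the full comparison analysis.

One :func:`run_pipeline` call reproduces the whole chain on any input set:
per-replicate trajectory reading, equilibration trimming and macro-trajectory
assembly, MSA-based Cα mapping, per-system essential-dynamics PCA, the
crossing-over diagnostic and RMSIP class comparison, per-replicate cosine
content, catalytic-site SASA, substrate-lysine distances and contact
persistence, the CES/D motif scan, and the exponential activity-distance fit.

The run is deterministic: identical configuration and inputs produce a
byte-identical report bundle (no timestamps enter any output file).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import activity as activity_mod
from . import compare as compare_mod
from . import essential as essential_mod
from . import geometry as geometry_mod
from . import mapping as mapping_mod
from . import structure_io
from .core import EssentialSubspace, Structure, TrajectoryEnsemble
from .errors import ConfigurationError, InvalidArgumentError, PipelineError

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AtomSelection:
    """An atom or residue address: chain / residue number [/ atom name]."""

    chain: str
    res_id: int
    atom: str | None = None        # None selects the residue's side chain

    @classmethod
    def parse(cls, text: str) -> "AtomSelection":
        parts = text.split("/")
        if len(parts) == 2:
            return cls(parts[0], int(parts[1]))
        if len(parts) == 3:
            atom = parts[2] if parts[2].lower() != "sidechain" else None
            return cls(parts[0], int(parts[1]), atom)
        raise InvalidArgumentError(f"bad selection {text!r}; expected chain/resid[/atom]")

    def resolve(self, structure: Structure) -> np.ndarray:
        if self.atom is None:
            return structure.residue_atom_indices(self.chain, self.res_id, sidechain_only=True)
        return np.array([structure.atom_index(self.chain, self.res_id, self.atom)])


@dataclass
class SystemConfig:
    id: str
    trajectories: list[str]
    class_label: str
    activity: float | None = None


@dataclass
class RunConfig:
    """Everything one analysis run needs; loadable from YAML."""

    systems: list[SystemConfig]
    reference_id: str
    msa_path: str | None = None
    ces_residue_number: int | None = None
    catalytic_cys: AtomSelection | None = None
    substrate_lys: AtomSelection | None = None
    ces_site: AtomSelection | None = None
    partners: list[AtomSelection] = field(default_factory=list)
    d: int = 20
    k_max: int = 10
    trim: int | float = 0.1
    contact_cutoff: float = geometry_mod.DEFAULT_CONTACT_CUTOFF
    sasa_probe_radius: float = geometry_mod.DEFAULT_PROBE_RADIUS
    sasa_points: int = 960
    distance_mode: str = "named-pair"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.systems:
            raise ConfigurationError("at least one system is required")
        ids = [s.id for s in self.systems]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("system ids must be unique")
        if self.reference_id not in ids:
            raise ConfigurationError(f"reference id {self.reference_id!r} is not a system")

    @classmethod
    def from_dict(cls, data: dict[str, Any], base_dir: Path | None = None) -> "RunConfig":
        def path_of(p: str) -> str:
            return str((base_dir / p) if base_dir and not Path(p).is_absolute() else Path(p))

        def sel(key: str) -> AtomSelection | None:
            raw = data.get(key)
            return AtomSelection.parse(raw) if raw else None

        systems = [
            SystemConfig(
                id=s["id"],
                trajectories=[path_of(t) for t in s["trajectories"]],
                class_label=s.get("class", s["id"]),
                activity=s.get("activity"),
            )
            for s in data["systems"]
        ]
        return cls(
            systems=systems,
            reference_id=data["reference_id"],
            msa_path=path_of(data["msa"]) if data.get("msa") else None,
            ces_residue_number=data.get("ces_residue_number"),
            catalytic_cys=sel("catalytic_cys"),
            substrate_lys=sel("substrate_lys"),
            ces_site=sel("ces_site"),
            partners=[AtomSelection.parse(p) for p in data.get("partners", [])],
            d=int(data.get("D", 20)),
            k_max=int(data.get("k_max", 10)),
            trim=data.get("trim", 0.1),
            contact_cutoff=float(data.get("contact_cutoff", geometry_mod.DEFAULT_CONTACT_CUTOFF)),
            sasa_probe_radius=float(
                data.get("sasa_probe_radius", geometry_mod.DEFAULT_PROBE_RADIUS)
            ),
            sasa_points=int(data.get("sasa_points", 960)),
            distance_mode=data.get("distance_mode", "named-pair"),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data, base_dir=path.parent)


@dataclass
class ComparisonReport:
    """In-memory result bundle of one pipeline run."""

    subspaces: dict[str, EssentialSubspace]
    macro_trajectories: dict[str, TrajectoryEnsemble]
    rmsip: dict[tuple[str, str], float]
    crossing: dict[str, compare_mod.CrossingTable]
    class_stats: list[compare_mod.BoxplotStats]
    cosine: list[dict[str, Any]]
    sasa: dict[str, geometry_mod.SasaSeries]
    distances: dict[str, dict[str, geometry_mod.ContactSeries]]
    persistence: dict[str, dict[str, geometry_mod.ContactSeries]]
    ces_calls: list[mapping_mod.CesSiteCall]
    activity_fit: activity_mod.ActivityFit | None
    written_files: list[Path] = field(default_factory=list)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir: str | Path) -> ComparisonReport:
    """Execute every analysis stage and write the TSV/JSON report bundle.

    Stage failures are re-raised as :class:`PipelineError` naming the stage
    and system; partially written outputs are removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def note(stage: str, message: str) -> None:
        line = f"[{stage}] {message}"
        log_lines.append(line)
        logger.info("%s", line)

    def emit(name: str, rows: list[dict], schema: list[str]) -> None:
        path = structure_io.write_report_table(rows, schema, out / name)
        written.append(path)

    try:
        report = _run_stages(config, note, emit, out, written)
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        written.append(out / "run_log.txt")
        report.written_files = list(written)
        return report
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("pipeline", None, exc) from exc


def _stage(stage: str, system: str | None = None):
    """Context manager translating stage failures into PipelineError."""
    import contextlib

    @contextlib.contextmanager
    def ctx():
        try:
            yield
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, system, exc) from exc

    return ctx()


def _run_stages(config, note, emit, out: Path, written: list[Path]) -> ComparisonReport:
    # --- stage 1: read trajectories, trim, concatenate -----------------------
    macro: dict[str, TrajectoryEnsemble] = {}
    replicates: dict[str, list[TrajectoryEnsemble]] = {}
    for sys_cfg in config.systems:
        with _stage("read-trajectories", sys_cfg.id):
            reps = [
                structure_io.read_pdb_models(p, system_id=sys_cfg.id)
                for p in sys_cfg.trajectories
            ]
        with _stage("macro-trajectory", sys_cfg.id):
            macro[sys_cfg.id] = geometry_mod.preprocess_macro_trajectory(reps, config.trim)
            replicates[sys_cfg.id] = [
                geometry_mod.preprocess_macro_trajectory([r], config.trim) for r in reps
            ]
        note("macro-trajectory",
             f"{sys_cfg.id}: {len(reps)} replicate(s), trim={config.trim}, "
             f"{macro[sys_cfg.id].n_frames} frames kept")

    system_ids = [s.id for s in config.systems]
    multi_system = len(system_ids) > 1

    # --- stage 2: MSA mapping ------------------------------------------------
    msa = None
    atom_maps: dict[str, np.ndarray] = {}
    if config.msa_path is not None:
        with _stage("msa-mapping"):
            msa = structure_io.read_msa_fasta(config.msa_path)
            amap = mapping_mod.common_core_map(
                msa, {sid: macro[sid].topology for sid in system_ids}, system_ids
            )
            atom_maps = dict(amap.atom_indices)
            note("msa-mapping", f"{amap.n_columns} shared columns across {len(system_ids)} systems")
    else:
        for sid in system_ids:
            atom_maps[sid] = macro[sid].topology.ca_indices()
        note("msa-mapping", "no MSA configured; using all CA atoms per system")

    # --- stage 3: per-system PCA --------------------------------------------
    subspaces: dict[str, EssentialSubspace] = {}
    eig_rows = []
    for sid in system_ids:
        with _stage("pca", sid):
            sub = essential_mod.essential_subspace(macro[sid], atom_maps[sid])
            subspaces[sid] = sub
            note("pca", f"{sid}: {sub.n_modes} modes, "
                        f"var(first {min(config.d, sub.n_modes)} PCs)="
                        f"{essential_mod.variance_explained(sub, min(config.d, sub.n_modes)):.4f}")
            for i in range(min(config.d, sub.n_modes)):
                eig_rows.append({
                    "system": sid, "pc": i + 1,
                    "eigenvalue_nm2": sub.eigenvalues[i],
                    "variance_fraction": sub.variance_fractions()[i],
                })
    emit("eigenvalues.tsv", eig_rows, ["system", "pc", "eigenvalue_nm2", "variance_fraction"])

    # --- stage 4: subspace comparison ---------------------------------------
    rmsip_values: dict[tuple[str, str], float] = {}
    crossing: dict[str, compare_mod.CrossingTable] = {}
    class_stats: list[compare_mod.BoxplotStats] = []
    if multi_system:
        with _stage("subspace-comparison"):
            d = min([config.d] + [subspaces[s].n_modes for s in system_ids])
            if d < config.d:
                note("subspace-comparison", f"D reduced from {config.d} to {d} (rank limit)")
            rows = []
            for i, sa in enumerate(system_ids):
                for sb in system_ids[i + 1:]:
                    value = compare_mod.rmsip(subspaces[sa], subspaces[sb], d)
                    rmsip_values[(sa, sb)] = value
                    rows.append({"system_a": sa, "system_b": sb, "D": d, "rmsip": value})
            emit("rmsip.tsv", rows, ["system_a", "system_b", "D", "rmsip"])

            ref_pc1 = subspaces[config.reference_id].eigenvectors[:, 0]
            cross_rows = []
            for sid in system_ids:
                if sid == config.reference_id:
                    continue
                k = min(config.k_max, subspaces[sid].n_modes)
                table = compare_mod.best_match_pc(ref_pc1, subspaces[sid], k)
                crossing[sid] = table
                for j, ov in enumerate(table.overlaps, start=1):
                    cross_rows.append({
                        "system": sid, "reference_pc": 1, "variant_pc": j,
                        "overlap": ov, "best": j == table.best_match,
                    })
            emit("crossing.tsv", cross_rows,
                 ["system", "reference_pc", "variant_pc", "overlap", "best"])

            # class comparison: reference-class systems pairwise, then
            # reference-class vs each other class
            ref_class = next(s.class_label for s in config.systems
                             if s.id == config.reference_id)
            wt_ids = [s.id for s in config.systems if s.class_label == ref_class]
            values: dict[str, float] = {}
            grouping: dict[str, str] = {}
            for (sa, sb), val in rmsip_values.items():
                ca = next(s.class_label for s in config.systems if s.id == sa)
                cb = next(s.class_label for s in config.systems if s.id == sb)
                label = f"{sa}|{sb}"
                if ca == ref_class and cb == ref_class:
                    values[label] = val
                    grouping[label] = ref_class
                elif ca == ref_class or cb == ref_class:
                    values[label] = val
                    grouping[label] = cb if ca == ref_class else ca
            class_stats = compare_mod.group_boxplot_stats(values, grouping)
            emit("class_stats.tsv", [
                {"class": st.label, "n": st.n, "median": st.median, "q25": st.q25,
                 "q75": st.q75, "whisker_low": st.whisker_low,
                 "whisker_high": st.whisker_high, "n_outliers": int(st.outliers.size)}
                for st in class_stats
            ], ["class", "n", "median", "q25", "q75", "whisker_low", "whisker_high",
                "n_outliers"])
            note("subspace-comparison",
                 f"{len(rmsip_values)} pairwise RMSIP values, {len(class_stats)} classes")
    else:
        note("subspace-comparison", "skipped: single system (nothing to compare)")
        logger.warning("single-system run: comparison stages skipped")

    # --- stage 5: cosine content per replicate ------------------------------
    cosine_rows: list[dict[str, Any]] = []
    with _stage("cosine-content"):
        for sid in system_ids:
            for rep in replicates[sid]:
                if rep.n_frames < 4:
                    continue
                sub = essential_mod.essential_subspace(rep, atom_maps[sid])
                k = min(config.d, sub.n_modes, rep.n_frames - 1)
                series = essential_mod.project_onto(rep, sub, k)
                for p in series:
                    if np.allclose(p.values, 0.0):
                        continue
                    cosine_rows.append({
                        "system": sid, "replicate": int(rep.replicate_ids[0]),
                        "pc": p.pc_index,
                        "cosine_content": compare_mod.cosine_content(p),
                    })
        emit("cosine_content.tsv", cosine_rows, ["system", "replicate", "pc", "cosine_content"])
        note("cosine-content", f"{len(cosine_rows)} replicate PCs evaluated")

    # --- stage 6: geometry ---------------------------------------------------
    sasa: dict[str, geometry_mod.SasaSeries] = {}
    distances: dict[str, dict[str, geometry_mod.ContactSeries]] = {}
    persistence: dict[str, dict[str, geometry_mod.ContactSeries]] = {}
    if config.catalytic_cys is not None:
        sasa_rows = []
        for sid in system_ids:
            with _stage("sasa", sid):
                sel = config.catalytic_cys.resolve(macro[sid].topology)
                series = geometry_mod.sasa_series(
                    macro[sid], sel, config.sasa_probe_radius, config.sasa_points
                )
                sasa[sid] = series
                for rep, mean in series.per_replicate_mean.items():
                    sasa_rows.append({
                        "system": sid, "replicate": rep, "mean_nm2": mean,
                        "sd_nm2": series.per_replicate_sd[rep],
                    })
        emit("sasa.tsv", sasa_rows, ["system", "replicate", "mean_nm2", "sd_nm2"])
        note("sasa", f"catalytic-site SASA over {len(sasa)} systems")

    pair_specs: list[tuple[str, AtomSelection, AtomSelection]] = []
    if config.substrate_lys is not None and config.catalytic_cys is not None:
        pair_specs.append(("lys-cys", config.substrate_lys, config.catalytic_cys))
    if config.substrate_lys is not None and config.ces_site is not None:
        pair_specs.append(("lys-ces", config.substrate_lys, config.ces_site))
    for p, partner in enumerate(config.partners, start=1):
        if config.substrate_lys is not None:
            pair_specs.append((f"lys-partner{p}", config.substrate_lys, partner))
    if pair_specs:
        dist_rows, pers_rows = [], []
        for sid in system_ids:
            distances[sid] = {}
            persistence[sid] = {}
            for label, sel_a, sel_b in pair_specs:
                with _stage("distances", sid):
                    topo = macro[sid].topology
                    mode = ("named-pair"
                            if sel_a.atom is not None and sel_b.atom is not None
                            and config.distance_mode == "named-pair" else "min-heavy")
                    series = geometry_mod.distance_series(
                        macro[sid], sel_a.resolve(topo), sel_b.resolve(topo), mode
                    )
                    distances[sid][label] = series
                    pers = geometry_mod.contact_persistence(series, config.contact_cutoff)
                    persistence[sid][label] = pers
                    dist_rows.append({
                        "system": sid, "pair": label, "mode": mode,
                        "mean_nm": float(series.distances.mean()),
                        "sd_nm": float(series.distances.std(ddof=0)),
                        "min_nm": float(series.distances.min()),
                    })
                    pers_rows.append({
                        "system": sid, "pair": label,
                        "cutoff_nm": config.contact_cutoff,
                        "persistence": pers.persistence,
                    })
        emit("distances.tsv", dist_rows, ["system", "pair", "mode", "mean_nm", "sd_nm", "min_nm"])
        emit("persistence.tsv", pers_rows, ["system", "pair", "cutoff_nm", "persistence"])
        note("distances", f"{len(pair_specs)} pair(s) over {len(system_ids)} systems")

    # --- stage 7: CES/D motif scan ------------------------------------------
    ces_calls: list[mapping_mod.CesSiteCall] = []
    if msa is not None and config.ces_residue_number is not None:
        with _stage("ces-scan"):
            ces_calls = mapping_mod.classify_ces_site(
                msa, config.reference_id, config.ces_residue_number
            )
            emit("ces_calls.tsv", [
                {"sequence_id": c.sequence_id, "site": c.site_residue,
                 "plus1": c.plus1_residue, "motif_class": c.motif_class,
                 "cdk_consensus": c.cdk_consensus}
                for c in ces_calls
            ], ["sequence_id", "site", "plus1", "motif_class", "cdk_consensus"])
            note("ces-scan", f"{len(ces_calls)} sequences classified")

    # --- stage 8: activity fit ----------------------------------------------
    activity_fit = None
    with_activity = [
        s for s in config.systems
        if s.activity is not None and s.id in distances and "lys-cys" in distances[s.id]
    ]
    if len(with_activity) >= 3:
        with _stage("activity-fit"):
            xs = np.array([
                float(distances[s.id]["lys-cys"].distances.mean()) for s in with_activity
            ])
            sds = np.array([
                float(distances[s.id]["lys-cys"].distances.std(ddof=0))
                for s in with_activity
            ])
            ys = np.array([float(s.activity) for s in with_activity])
            activity_fit = activity_mod.fit_exponential_activity(xs, ys, sds)
            payload = {
                "b": activity_fit.b, "c": activity_fit.c,
                "correlation": activity_fit.correlation,
                "degenerate": activity_fit.degenerate,
                "points": [
                    {"system": s.id, "distance_nm": float(x), "distance_sd_nm": float(sd),
                     "activity": float(y), "fitted": float(f)}
                    for s, x, sd, y, f in zip(with_activity, xs, sds, ys,
                                              activity_fit.fitted)
                ],
            }
            path = out / "activity_fit.json"
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
            written.append(path)
            note("activity-fit",
                 f"b={activity_fit.b:.6g}, c={activity_fit.c:.6g}, "
                 f"r={activity_fit.correlation:.4f} over {len(with_activity)} variants")

    # --- report summary ------------------------------------------------------
    summary = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "systems": system_ids,
        "reference": config.reference_id,
        "D": config.d,
        "k_max": config.k_max,
        "trim": config.trim,
        "contact_cutoff_nm": config.contact_cutoff,
        "seed": config.seed,
        "n_rmsip_pairs": len(rmsip_values),
        "n_classes": len(class_stats),
        "n_ces_calls": len(ces_calls),
        "activity_fit": (
            None if activity_fit is None
            else {"b": activity_fit.b, "c": activity_fit.c,
                  "correlation": activity_fit.correlation}
        ),
    }
    path = out / "report.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(path)

    return ComparisonReport(
        subspaces=subspaces, macro_trajectories=macro, rmsip=rmsip_values,
        crossing=crossing, class_stats=class_stats, cosine=cosine_rows, sasa=sasa,
        distances=distances, persistence=persistence, ces_calls=ces_calls,
        activity_fit=activity_fit,
    )
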