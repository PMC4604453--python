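"""Shared world for the numbered analysis drivers.

The synthetic study mirrors the comparison design: one wild-type-like
reference plus three variants whose essential subspaces are rotated away from
the reference by increasing angles (the stand-in for mutations that perturb
native dynamics more and more).  Trajectories are written once under
``scratch/synthetic/`` and reused by later drivers; tables land in
``results/``.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

REPO = Path(__file__).resolve().parent.parent
SCRATCH = REPO / "scratch" / "synthetic"
RESULTS = REPO / "results"

SEED = 1
N_ATOMS = 40
N_FRAMES = 500
N_REPLICATES = 2
SPECTRUM = 0.004 * 0.6 ** np.arange(10)
ANGLES = {"mild": 0.3, "moderate": 0.7, "strong": 1.2}
TRIM = 0.1
D = 10
K_MAX = 10

#: relative conjugation activities used in the worked activity-fit example
ACTIVITIES = {"reference": 100.0, "mild": 35.0, "moderate": 10.0, "strong": 2.0}


def ensure_world(seed: int = SEED) -> dict[str, list[Path]]:
    """Generate (or reuse) the on-disk synthetic family; returns PDB paths."""
    import e2dyn as ed
    from e2dyn.core import MSA
    from e2dyn.synthetic import PerturbationSpec, SpectrumSpec, make_variant_family

    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    labels = ["reference"] + list(ANGLES)
    paths = {
        lbl: [SCRATCH / f"{lbl}_rep{r + 1}.pdb" for r in range(N_REPLICATES)]
        for lbl in labels
    }
    marker = SCRATCH / f"seed_{seed}.ok"
    if marker.exists() and all(p.exists() for ps in paths.values() for p in ps):
        return paths

    spectrum = SpectrumSpec(eigenvalues=SPECTRUM, n_atoms=N_ATOMS)
    family = make_variant_family(
        spectrum,
        [PerturbationSpec(angle=a, label=lbl) for lbl, a in ANGLES.items()],
        n_frames=N_FRAMES,
        n_replicates=N_REPLICATES,
        seed=seed,
    )
    rows = []
    for member in family:
        for rep in member.replicates:
            ed.write_pdb_models(rep, SCRATCH / f"{member.label}_rep{rep.replicate_ids[0]}.pdb")
        rows.append({"system": member.label,
                     "perturbation_angle_rad": (member.perturbation.angle
                                                if member.perturbation else 0.0),
                     "expected_rmsip_vs_reference": member.expected_rmsip})
    ed.write_msa_fasta(MSA(ids=labels, sequences=["A" * N_ATOMS] * len(labels)),
                       SCRATCH / "family.fasta")
    ed.write_report_table(rows, ["system", "perturbation_angle_rad",
                                 "expected_rmsip_vs_reference"],
                          RESULTS / "01_family_ground_truth.tsv")
    marker.write_text("")
    return paths


def load_macro_trajectories(paths: dict[str, list[Path]]):
    """Read every system's replicates and assemble trimmed macro-trajectories."""
    import e2dyn as ed

    macro = {}
    replicates = {}
    for lbl, files in paths.items():
        reps = [ed.read_pdb_models(p, system_id=lbl) for p in files]
        macro[lbl] = ed.preprocess_macro_trajectory(reps, TRIM)
        replicates[lbl] = [ed.preprocess_macro_trajectory([r], TRIM) for r in reps]
    return macro, replicates
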