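"""File formats: multi-model PDB, aligned FASTA, delimited report tables.

PDB parsing and writing delegate to biotite; FASTA reading delegates to
Biopython.  Coordinates are ångström in PDB files and nanometres in memory;
the conversion happens here and nowhere else.  Reading never silently drops
atoms: model/atom counts and discarded alternate locations are logged.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import MSA, Structure, TrajectoryEnsemble
from .errors import FormatError, InvalidArgumentError

logger = logging.getLogger(__name__)

NM_PER_ANGSTROM = 0.1


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _to_atom_array_stack(ensemble: TrajectoryEnsemble):
    import biotite.structure as struc

    topo = ensemble.topology
    n = topo.n_atoms
    stack = struc.AtomArrayStack(ensemble.n_frames, n)
    stack.coord = np.asarray(ensemble.coords / NM_PER_ANGSTROM, dtype=np.float32)
    stack.chain_id = topo.chain_id.astype("U4")
    stack.res_id = topo.res_id.astype(int)
    stack.res_name = topo.res_name.astype("U5")
    stack.atom_name = topo.name.astype("U6")
    stack.element = topo.element.astype("U2")
    stack.hetero = np.zeros(n, dtype=bool)
    return stack


def write_pdb_models(ensemble: TrajectoryEnsemble, path: str | Path) -> Path:
    """Write an ensemble as a fixed-column multi-model PDB (one MODEL per frame)."""
    from biotite.structure.io import pdb

    path = Path(path)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(_to_atom_array_stack(ensemble))
    try:
        pdb_file.write(str(path))
    except OSError as exc:
        raise OSError(f"cannot write PDB to {path}: {exc}") from exc
    if ensemble.n_frames == 1:
        # biotite writes a bare coordinate set for a single model; the format
        # contract is one MODEL/ENDMDL block per frame
        body = path.read_text()
        if "MODEL" not in body:
            path.write_text("MODEL        1\n" + body + "ENDMDL\n")
    return path


def read_pdb_models(path: str | Path, system_id: str | None = None) -> TrajectoryEnsemble:
    """Read a (multi-model) PDB file into an ensemble; models become frames."""
    from biotite.structure.io import pdb

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    n_altloc_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise FormatError(f"{path}:{lineno}: truncated ATOM record")
                altloc = line[16]
                if altloc not in (" ", "A"):
                    n_altloc_dropped += 1
    if n_altloc_dropped:
        logger.info("%s: dropped %d non-primary alternate locations", path, n_altloc_dropped)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None, altloc="first")
    except Exception as exc:  # biotite raises library-specific parse errors
        raise FormatError(f"cannot parse PDB {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise FormatError(f"{path}: no atoms found")
    first = stack[0]
    topo = Structure(
        serial=np.arange(1, stack.array_length() + 1),
        name=np.asarray(first.atom_name, dtype=str),
        element=np.asarray(first.element, dtype=str),
        res_name=np.asarray(first.res_name, dtype=str),
        res_id=np.asarray(first.res_id, dtype=int),
        chain_id=np.asarray(first.chain_id, dtype=str),
        coords=np.asarray(first.coord, dtype=np.float64) * NM_PER_ANGSTROM,
    )
    coords = np.asarray(stack.coord, dtype=np.float64) * NM_PER_ANGSTROM
    logger.info("%s: read %d models x %d atoms", path, coords.shape[0], coords.shape[1])
    return TrajectoryEnsemble(
        topology=topo,
        coords=coords,
        system_id=system_id or path.stem,
    )


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_msa_fasta(path: str | Path) -> MSA:
    """Read an aligned FASTA file; validates rectangular shape and unique ids."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    ids: list[str] = []
    seqs: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        seqs.append(str(record.seq).upper())
    if not ids:
        raise FormatError(f"{path}: no FASTA records found")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate record id(s): {', '.join(dupes)}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged alignment, record lengths {sorted(lengths)}")
    for rid, seq in zip(ids, seqs):
        if seq and set(seq) == {"-"}:
            logger.warning("%s: record %r is all gaps", path, rid)
    return MSA(ids=ids, sequences=seqs)


def write_msa_fasta(msa: MSA, path: str | Path, width: int = 60) -> Path:
    """Write an alignment as FASTA (fixed line width, deterministic)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in zip(msa.ids, msa.sequences):
            fh.write(f">{rid}\n")
            for start in range(0, len(seq), width):
                fh.write(seq[start:start + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def _format_cell(value: object) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return f"{float(value):.6g}"
    return str(value)


def write_report_table(
    rows: Iterable[Mapping[str, object]],
    schema: Sequence[str],
    path: str | Path,
    sep: str = "\t",
) -> Path:
    """Write rows as a delimited table with header; deterministic, 6 sig. digits.

    Every row must provide exactly the columns named in ``schema`` (order is
    taken from the schema, not the row).  Re-running on the same inputs yields
    a byte-identical file.
    """
    if len(schema) == 0 or len(set(schema)) != len(schema):
        raise InvalidArgumentError("schema must be a non-empty list of unique column names")
    path = Path(path)
    lines = [sep.join(schema)]
    for i, row in enumerate(rows):
        missing = [c for c in schema if c not in row]
        extra = [c for c in row if c not in schema]
        if missing or extra:
            raise InvalidArgumentError(
                f"row {i} does not conform to schema "
                f"(missing: {missing or '-'}, extra: {extra or '-'})"
            )
        lines.append(sep.join(_format_cell(row[c]) for c in schema))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
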