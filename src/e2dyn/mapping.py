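"""MSA-based residue correspondence and catalytic-site motif classification.

Cross-system essential-dynamics comparison requires a shared coordinate
dimension: the map keeps exactly the alignment columns that are ungapped in
every selected system and records, per system, the Cα atom carrying that
column.  The motif scanner locates the conserved catalytic-cleft Ser/Asp
position (the CES/D site, hHR6A Ser120 / Ube2I Asp127 in the E2 family) in an
alignment and classifies every sequence by the residue at the site and the
next residue in sequence space.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MSA, AlignmentMap, Structure
from .errors import ConsistencyError, EmptyCoreError, InvalidArgumentError

#: Motif classes at the CES/D site: residue at the site + following residue.
MOTIF_CLASSES = ("DP", "SP", "EP", "SA", "EA", "E", "other")


@dataclass
class CesSiteCall:
    """Per-sequence classification of the CES/D site.

    ``site_residue`` and ``plus1_residue`` are one-letter codes ('-' when the
    site column is a gap for the sequence or no residue follows).
    ``cdk_consensus`` is the minimal cyclin-dependent-kinase phosphorylation
    motif: Ser or Thr at the site immediately followed (in sequence space) by
    Pro.
    """

    sequence_id: str
    site_residue: str
    plus1_residue: str
    motif_class: str
    cdk_consensus: bool


def common_core_map(
    msa: MSA,
    structures: dict[str, Structure],
    id_subset: list[str] | None = None,
) -> AlignmentMap:
    """Map corresponding Cα atoms across systems through the alignment.

    Only columns ungapped in *all* selected systems are kept.  For each
    system, the sequence's non-gap residue count must equal its structure's
    residue count, and every residue must carry exactly one Cα.
    """
    ids = list(id_subset) if id_subset is not None else list(msa.ids)
    if len(ids) < 1:
        raise InvalidArgumentError("id subset must name at least one system")
    seqs: dict[str, str] = {}
    ca_by_ordinal: dict[str, np.ndarray] = {}
    for sid in ids:
        if sid not in structures:
            raise ConsistencyError(f"no structure provided for id {sid!r}")
        seq = msa.sequence(sid)
        st = structures[sid]
        n_res_seq = sum(1 for ch in seq if ch != "-")
        n_res_st = st.n_residues
        if n_res_seq != n_res_st:
            raise ConsistencyError(
                f"{sid!r}: sequence has {n_res_seq} residues but structure has {n_res_st}"
            )
        ca = st.ca_indices()
        if ca.size != n_res_st:
            raise ConsistencyError(
                f"{sid!r}: expected one CA per residue, found {ca.size} CA for "
                f"{n_res_st} residues"
            )
        seqs[sid] = seq
        ca_by_ordinal[sid] = ca

    ncol = msa.n_columns
    shared = [c for c in range(ncol) if all(seqs[sid][c] != "-" for sid in ids)]
    if not shared:
        raise EmptyCoreError("no alignment column is ungapped in all selected systems")

    atom_indices: dict[str, np.ndarray] = {}
    for sid in ids:
        seq = seqs[sid]
        ordinals = np.cumsum([ch != "-" for ch in seq]) - 1
        atom_indices[sid] = ca_by_ordinal[sid][[ordinals[c] for c in shared]]
    return AlignmentMap(columns=shared, atom_indices=atom_indices)


def _classify(site: str, plus1: str) -> str:
    site, plus1 = site.upper(), plus1.upper()
    if site == "D" and plus1 == "P":
        return "DP"
    if site == "S":
        if plus1 == "P":
            return "SP"
        if plus1 == "A":
            return "SA"
        return "other"
    if site == "E":
        if plus1 == "P":
            return "EP"
        if plus1 == "A":
            return "EA"
        return "E"
    return "other"


def classify_ces_site(
    msa: MSA,
    reference_id: str,
    reference_residue_number: int,
) -> list[CesSiteCall]:
    """Classify the CES/D-site motif of every sequence in the alignment.

    The site column is located as the alignment column holding residue number
    ``reference_residue_number`` (1-based, counting the reference's non-gap
    positions).  For each sequence the call reports the residue at that
    column, the next non-gap residue of that sequence (insertions do not break
    the +1 relation), the motif class, and whether the site conforms to the
    Cdk phosphorylation consensus (S/T followed by P).
    """
    ref_seq = msa.sequence(reference_id)
    if reference_residue_number < 1:
        raise InvalidArgumentError("reference residue number must be >= 1")
    ordinal = 0
    site_col = -1
    for col, ch in enumerate(ref_seq):
        if ch != "-":
            ordinal += 1
            if ordinal == reference_residue_number:
                site_col = col
                break
    if site_col < 0:
        raise InvalidArgumentError(
            f"reference {reference_id!r} has only {ordinal} residues; "
            f"residue {reference_residue_number} does not exist"
        )

    calls = []
    for sid, seq in zip(msa.ids, msa.sequences):
        site = seq[site_col]
        if site == "-":
            calls.append(CesSiteCall(sid, "-", "-", "other", False))
            continue
        plus1 = "-"
        for ch in seq[site_col + 1:]:
            if ch != "-":
                plus1 = ch
                break
        motif = _classify(site, plus1)
        cdk = site.upper() in ("S", "T") and plus1.upper() == "P"
        calls.append(CesSiteCall(sid, site.upper(), plus1.upper() if plus1 != "-" else "-",
                                 motif, cdk))
    return calls
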