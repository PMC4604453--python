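#!/usr/bin/env python
"""Catalytic-site motif scan on a miniature hand-written alignment.

The conserved catalytic-cleft position of Ub/Ubl-conjugating enzymes (the
CES/D site) holds an aspartate in constitutively active members, a
phosphorylatable serine in kinase-regulated ones, or a glutamate in two less
characterised families, and is almost always followed by a proline — so
serine-bearing members match the minimal Cdk phosphorylation consensus
(S/T followed by P).  This driver classifies a six-record alignment with one
representative per motif class and writes results/06_ces_calls.tsv.
"""
import argparse

import common

RECORDS = [
    ("hHR6A_like", "MAYSPGK"),   # Ser-Pro: phosphorylatable, Cdk consensus
    ("Ubc1_like",  "MAYDPGK"),   # Asp-Pro: constitutively acidic
    ("fam14_EP",   "MAYEPGK"),   # Glu-Pro
    ("fam15_EA",   "MAYEAGK"),   # Glu-Ala
    ("fam15_E",    "MAYEEGK"),   # bare Glu
    ("uev_like",   "MAYGPGK"),   # no acidic/phosphorylatable residue
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    import e2dyn as ed
    from e2dyn.core import MSA

    common.RESULTS.mkdir(parents=True, exist_ok=True)
    ids, seqs = zip(*RECORDS)
    msa = MSA(ids=list(ids), sequences=list(seqs))
    calls = ed.classify_ces_site(msa, "hHR6A_like", 4)
    rows = []
    print("CES/D-site calls (site = reference residue 4):")
    for call in calls:
        flag = " (Cdk consensus)" if call.cdk_consensus else ""
        print(f"  {call.sequence_id:12s} {call.site_residue}-{call.plus1_residue}"
              f" -> {call.motif_class}{flag}")
        rows.append({"sequence_id": call.sequence_id, "site": call.site_residue,
                     "plus1": call.plus1_residue, "motif_class": call.motif_class,
                     "cdk_consensus": call.cdk_consensus})
    out = common.RESULTS / "06_ces_calls.tsv"
    ed.write_report_table(rows, ["sequence_id", "site", "plus1", "motif_class",
                                 "cdk_consensus"], out)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
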