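"""Assemble the strain-specific draft model and audit it.

Reduces the first panel model through the BBH ortholog map, augments
from the remaining references in panel order (first-come provenance),
then runs the curation audits: duplicate reactions, mass/charge
balance, and energy-generating cycles.  Writes the draft model, the
provenance ledger and the audit reports, and verifies recovery against
the planted panel truth.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from gemforge.core import check_balance, find_duplicate_reactions
from gemforge.io import read_model, write_model
from gemforge.reconstruct import (
    augment_from_references,
    detect_energy_generating_cycles,
    reduce_base_model,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--orthology", type=Path, default=Path("results/orthology"))
    ap.add_argument("--out", type=Path, default=Path("results/draft"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    bbh = json.loads((args.orthology / "bbh_maps.json").read_text())
    truth = json.loads((args.inputs / "panel_truth.json").read_text())
    strains = sorted(bbh)
    panel = {s: read_model(args.inputs / "panel" / f"{s}.json") for s in strains}
    # BBH maps run target gene -> strain gene; translation needs the inverse
    inverse = {s: {sg: g for g, sg in bbh[s].items()} for s in strains}

    base = panel[strains[0]]
    reduced = reduce_base_model(base, inverse[strains[0]])
    draft, ledger, log = augment_from_references(
        reduced,
        [panel[s] for s in strains[1:]],
        {s: inverse[s] for s in strains[1:]},
        include_spontaneous=True,
    )
    write_model(draft, args.out / "draft.json", "json")
    ledger.table(draft).to_csv(args.out / "provenance.tsv", sep="\t", index=False)
    print(f"draft: {len(draft.reactions)} reactions "
          f"(base {strains[0]}: {len(reduced.reactions)}, "
          f"added from references: {len(log.added)})")
    print("origin counts:", dict(sorted(ledger.counts_by_origin().items())))

    planted = set().union(*(set(r) for r in truth["retained_reactions"].values()))
    false_rxns = set(draft.reactions) - planted
    missed = planted - set(draft.reactions)
    print(f"recovery vs planted union: {len(false_rxns)} false, {len(missed)} missed")

    dup_groups = find_duplicate_reactions(draft)
    pd.DataFrame(
        [{"reactions": ";".join(g.reaction_ids),
          "gpr_differs": g.gpr_differs, "bounds_differ": g.bounds_differ}
         for g in dup_groups]
    ).to_csv(args.out / "duplicates.tsv", sep="\t", index=False)

    # boundary (exchange) pseudo-reactions are one-sided by construction
    # and are not meaningful balance-audit subjects
    boundary = set(draft.exchanges)
    balance = [check_balance(r, draft) for r in draft.reactions.values()
               if r.id not in boundary]
    pd.DataFrame(
        [{"reaction": b.reaction_id, "status": b.status,
          "residual": ";".join(f"{e}:{v}" for e, v in sorted(b.element_residual.items()))}
         for b in balance]
    ).to_csv(args.out / "balance.tsv", sep="\t", index=False)
    by_status = pd.Series([b.status for b in balance]).value_counts().to_dict()
    print(f"audits: {len(dup_groups)} duplicate groups; balance {by_status}")

    egc = detect_energy_generating_cycles(draft)
    pd.DataFrame(
        [{"currency": r.currency, "optimum": r.optimum, "flagged": r.flagged}
         for r in egc]
    ).to_csv(args.out / "egc.tsv", sep="\t", index=False)
    print(f"energy-generating cycles flagged: {sum(r.flagged for r in egc)} "
          f"of {len(egc)} currencies probed")


if __name__ == "__main__":
    main()
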