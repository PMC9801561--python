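"""Generate every synthetic input the downstream analyses consume.

Writes under results/synthetic/: the template model (JSON + SBML), a
reference panel with planted dropout, forward/reverse alignment hit
tables per strain, a phenotype plate with a 20% label-flip rate, and a
13C-style flux-measurement table, all derived deterministically from
one seed.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from gemforge.io import write_model
from gemforge.orthology import write_hit_table
from gemforge.phenotype import write_plate
from gemforge.synth import (
    default_medium,
    make_flux_measurements,
    make_hit_tables,
    make_plate,
    make_reference_panel,
    make_template_model,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--n-strains", type=int, default=6)
    ap.add_argument("--dropout", type=float, default=0.3)
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    template = make_template_model(args.seed)
    write_model(template, out / "template.json", "json")
    write_model(template, out / "template.xml", "sbml")
    print(f"template model: {len(template.reactions)} reactions, "
          f"{len(template.genes)} genes -> {out/'template.json'}")

    panel, truth = make_reference_panel(template, args.n_strains, args.dropout,
                                        seed=args.seed)
    (out / "panel").mkdir(exist_ok=True)
    for strain, model in sorted(panel.items()):
        write_model(model, out / "panel" / f"{strain}.json", "json")
    truth_doc = {
        "seed": args.seed,
        "dropout": args.dropout,
        "retained_reactions": {s: sorted(r) for s, r in truth.retained_reactions.items()},
        "strain_genes": truth.strain_genes,
    }
    (out / "panel_truth.json").write_text(json.dumps(truth_doc, indent=1))
    print(f"panel: {len(panel)} strains at dropout {args.dropout}; union "
          f"{len(truth.reconstructable_reactions())} reactions")

    tables = make_hit_tables(truth, seed=args.seed)
    (out / "hits").mkdir(exist_ok=True)
    for strain, (fwd, rev) in sorted(tables.items()):
        write_hit_table(fwd, out / "hits" / f"{strain}_fwd.tsv")
        write_hit_table(rev, out / "hits" / f"{strain}_rev.tsv")
    print(f"hit tables: {sum(len(f)+len(r) for f, r in tables.values())} rows "
          f"across {len(tables)} strains")

    wells, plate_truth = make_plate(template, 200, flip_rate=0.2, seed=args.seed)
    write_plate(wells, out / "plate.tsv")
    pd.Series(plate_truth).rename("true_call").to_csv(out / "plate_truth.tsv", sep="\t")
    print(f"phenotype plate: {len(wells)} wells ({len(plate_truth)} mapped)")

    ms = make_flux_measurements(template, default_medium(), noise_cv=0.05,
                                seed=args.seed)
    pd.DataFrame(
        [{"reaction_id": m.reaction_id, "mean": m.mean, "sd": m.sd} for m in ms]
    ).to_csv(out / "flux_measurements.tsv", sep="\t", index=False)
    print(f"flux measurements: {len(ms)} reactions, normalised to glucose uptake 100")


if __name__ == "__main__":
    main()
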