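"""Best-bidirectional-hit orthology across the synthetic reference panel.

Reads the per-strain forward/reverse hit tables, filters at 80%
identity / 25% query coverage, intersects best hits mutually, and
writes the binary gene x strain orthology matrix plus per-strain
ortholog maps.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from gemforge.io import read_model
from gemforge.orthology import (
    build_orthology_matrix,
    orthology_from_tables,
    read_hit_table,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--inputs", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/orthology"))
    ap.add_argument("--pid", type=float, default=80.0)
    ap.add_argument("--cov", type=float, default=0.25)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    template = read_model(args.inputs / "template.json")
    strains = sorted({p.name.split("_")[0] for p in (args.inputs / "hits").glob("*.tsv")})
    bbh_maps = {}
    for strain in strains:
        fwd = read_hit_table(args.inputs / "hits" / f"{strain}_fwd.tsv")
        rev = read_hit_table(args.inputs / "hits" / f"{strain}_rev.tsv")
        bbh_maps[strain] = orthology_from_tables(fwd, rev, args.pid, args.cov)

    matrix = build_orthology_matrix(bbh_maps, sorted(template.genes))
    matrix.to_tsv(args.out / "matrix.tsv")
    (args.out / "bbh_maps.json").write_text(json.dumps(matrix.maps, indent=1))

    print(f"orthology matrix: {len(matrix.target_genes)} genes x "
          f"{len(matrix.strains)} strains -> {args.out/'matrix.tsv'}")
    print(f"genes shared with all strains: {len(matrix.shared_with_all())}")
    print(f"genes unique to the target (no ortholog anywhere): "
          f"{len(matrix.unique_genes())}")


if __name__ == "__main__":
    main()
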