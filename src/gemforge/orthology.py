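"""Best-bidirectional-hit orthology from pairwise protein alignment tables.

The input is the standard 12-column tabular alignment layout (query,
subject, percent identity, alignment length, mismatches, gap opens,
qstart, qend, sstart, send, e-value, bitscore), optionally extended with
two columns for query/subject sequence lengths.  Hits are filtered on
percent identity (default ≥ 80, inclusive) and alignment-length
coverage (default ≥ 25% of the query length, inclusive), the best hit
per query is taken by bitscore (ties: smaller e-value, then
lexicographically smaller subject id), and a pair is orthologous iff it
is the best hit in both directions.  Per-strain BBH maps are assembled
into a binary gene × strain orthology matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pid",
    "aln_len",
    "mismatches",
    "gap_opens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]
LENGTH_COLUMNS = ["query_len", "subject_len"]


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    pid: float
    aln_len: int
    query_len: int
    subject_len: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0 <= self.pid <= 100:
            raise ValueError(f"percent identity {self.pid} outside [0, 100]")
        if self.aln_len < 1 or self.query_len < 1 or self.subject_len < 1:
            raise ValueError("alignment and sequence lengths must be >= 1")
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")


def read_hit_table(
    path: str | Path,
    lengths: Mapping[str, int] | None = None,
) -> list[AlignmentHit]:
    """Read a 12- or 14-column tab-separated hit table.

    With 12 columns a ``lengths`` map (sequence id -> residues) must
    supply query/subject lengths; with 14 the extra columns are used.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == len(HIT_COLUMNS) + 2:
        df.columns = HIT_COLUMNS + LENGTH_COLUMNS
    elif df.shape[1] == len(HIT_COLUMNS):
        if lengths is None:
            raise ValueError(
                f"{path}: 12-column table requires a sequence-length map"
            )
        df.columns = HIT_COLUMNS
        df["query_len"] = df["query_id"].map(lengths)
        df["subject_len"] = df["subject_id"].map(lengths)
    else:
        raise ValueError(f"{path}: expected 12 or 14 columns, got {df.shape[1]}")
    return [
        AlignmentHit(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            pid=float(r.pid),
            aln_len=int(r.aln_len),
            query_len=int(r.query_len),
            subject_len=int(r.subject_len),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples(index=False)
    ]


def write_hit_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    rows = [
        (
            h.query_id, h.subject_id, h.pid, h.aln_len, 0, 0,
            1, h.aln_len, 1, h.aln_len, h.evalue, h.bitscore,
            h.query_len, h.subject_len,
        )
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS + LENGTH_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def _coverage(hit: AlignmentHit, denominator: str) -> float:
    if denominator == "query":
        denom = hit.query_len
    elif denominator == "subject":
        denom = hit.subject_len
    elif denominator == "shorter":
        denom = min(hit.query_len, hit.subject_len)
    else:
        raise ValueError(f"unknown coverage denominator {denominator!r}")
    return hit.aln_len / denom


def filter_hits(
    hits: Iterable[AlignmentHit],
    pid_min: float = 80.0,
    cov_min: float = 0.25,
    cov_denominator: str = "query",
    drop_self: bool = False,
) -> list[AlignmentHit]:
    """Keep hits with pid ≥ pid_min and coverage ≥ cov_min (both inclusive).

    Both thresholds follow the homology-call convention of the workflow
    (80% identity, 25% alignment length); the coverage denominator is
    the query length by default but configurable (query/subject/shorter).
    ``drop_self`` discards query == subject rows (same-organism tables).
    """
    return [
        h
        for h in hits
        if h.pid >= pid_min
        and _coverage(h, cov_denominator) >= cov_min
        and not (drop_self and h.query_id == h.subject_id)
    ]


def best_hit_map(hits: Iterable[AlignmentHit]) -> dict[str, str]:
    """Best subject per query: max bitscore, then min e-value, then
    lexicographically smallest subject id.  Expects pre-filtered hits."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def _hit_rank(h: AlignmentHit) -> tuple:
    return (-h.bitscore, h.evalue, h.subject_id)


def bidirectional_best_hits(
    fwd: Mapping[str, str], rev: Mapping[str, str]
) -> dict[str, str]:
    """Mutual best hits: (q, s) kept iff fwd[q] = s and rev[s] = q."""
    return {q: s for q, s in fwd.items() if rev.get(s) == q}


@dataclass
class OrthologyMatrix:
    """Binary gene × strain orthology membership with per-strain maps."""

    target_genes: list[str]
    strains: list[str]
    matrix: pd.DataFrame  # genes × strains, values 0/1
    maps: dict[str, dict[str, str]]  # strain -> {target gene -> reference gene}

    def row_sums(self) -> pd.Series:
        """Number of strains carrying an ortholog of each target gene."""
        return self.matrix.sum(axis=1)

    def column_sums(self) -> pd.Series:
        """Number of target genes shared with each strain."""
        return self.matrix.sum(axis=0)

    def unique_genes(self) -> list[str]:
        """Target genes with no ortholog in any strain (all-zero rows)."""
        sums = self.row_sums()
        return [g for g in self.target_genes if sums[g] == 0]

    def shared_with_all(self) -> list[str]:
        sums = self.row_sums()
        return [g for g in self.target_genes if sums[g] == len(self.strains)]

    def to_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="gene")


def build_orthology_matrix(
    bbh_maps: Mapping[str, Mapping[str, str]],
    target_genes: Sequence[str],
) -> OrthologyMatrix:
    """Assemble per-strain BBH maps into a binary orthology matrix.

    Matrix entry (g, s) is 1 iff strain s has a BBH partner for target
    gene g; genes never hit in any strain are the target's unique genes.
    """
    genes = list(target_genes)
    gene_set = set(genes)
    strains = list(bbh_maps)
    for strain, mapping in bbh_maps.items():
        unknown = set(mapping) - gene_set
        if unknown:
            raise ValueError(
                f"strain {strain!r}: BBH map contains unknown target gene(s) "
                f"{sorted(unknown)[:5]}"
            )
    data = {
        strain: [1 if g in bbh_maps[strain] else 0 for g in genes]
        for strain in strains
    }
    matrix = pd.DataFrame(data, index=genes, columns=strains, dtype=int)
    return OrthologyMatrix(
        target_genes=genes,
        strains=strains,
        matrix=matrix,
        maps={s: dict(m) for s, m in bbh_maps.items()},
    )


def orthology_from_tables(
    fwd_hits: Iterable[AlignmentHit],
    rev_hits: Iterable[AlignmentHit],
    pid_min: float = 80.0,
    cov_min: float = 0.25,
    cov_denominator: str = "query",
) -> dict[str, str]:
    """Filter both tables, take best hits each way, intersect mutually."""
    fwd = best_hit_map(filter_hits(fwd_hits, pid_min, cov_min, cov_denominator))
    rev = best_hit_map(filter_hits(rev_hits, pid_min, cov_min, cov_denominator))
    return bidirectional_best_hits(fwd, rev)
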