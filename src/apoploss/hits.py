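"""Parsing and reduction of tabular similarity-search results.

Two dialects are handled: the standard 12-column BLAST tabular format
(outfmt-6-style TSV) and HMMER's per-sequence tabular output (tblout).
Rows reduce to per-query best hits by minimum e-value, ties broken by
higher bit score, then lexicographic subject id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

__all__ = [
    "HitRecord",
    "BestHitPair",
    "DomainHit",
    "HitTableParseError",
    "read_hit_table",
    "write_hit_table",
    "best_hits",
    "pair_best_hits",
    "read_domain_table",
    "write_best_hits_tsv",
]


class HitTableParseError(ValueError):
    pass


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular hit file."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value} for query {self.query_id!r}")


@dataclass(frozen=True)
class BestHitPair:
    """Per-query best hits against the target-clade and contaminant databases."""

    query_id: str
    best_target: Optional[HitRecord] = None
    best_contam: Optional[HitRecord] = None


@dataclass(frozen=True)
class DomainHit:
    """One per-sequence domain-scan row (query protein vs profile)."""

    protein_id: str
    domain_acc: str
    domain_name: str
    e_value: float
    env_start: Optional[int] = None
    env_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value for protein {self.protein_id!r}")


def read_hit_table(path: Union[str, Path]) -> list[HitRecord]:
    """Read a 12-column tab-separated hit table ('#' comment lines allowed).

    Scientific-notation e-values are parsed; an e-value written as "0.0" is
    preserved as exact zero (downstream ratio arithmetic applies a floor).
    """
    path = Path(path)
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitTableParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                records.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_len=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise HitTableParseError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_hit_table(records: Iterable[HitRecord], dest: Union[str, Path, TextIO]) -> None:
    def _emit(fh: TextIO) -> None:
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.pct_identity:.2f}\t{r.aln_len}\t"
                f"{r.mismatches}\t{r.gap_opens}\t{r.q_start}\t{r.q_end}\t{r.s_start}\t"
                f"{r.s_end}\t{r.e_value:.3e}\t{r.bit_score:.1f}\n"
            )

    if hasattr(dest, "write"):
        _emit(dest)  # type: ignore[arg-type]
    else:
        with open(dest, "w") as fh:
            _emit(fh)


def _hit_rank(r: HitRecord) -> tuple[float, float, str]:
    # min e-value wins; ties by higher bit score, then subject id
    return (r.e_value, -r.bit_score, r.subject_id)


def best_hits(
    records: Iterable[HitRecord], queries: Iterable[str]
) -> dict[str, Optional[HitRecord]]:
    """Best hit per query id from a single database's rows.

    Queries with no rows map to None. The result is invariant to input row
    order (total tie-break: e-value, -bit_score, subject_id).
    """
    best: dict[str, Optional[HitRecord]] = {q: None for q in queries}
    for r in records:
        if r.query_id not in best:
            continue
        cur = best[r.query_id]
        if cur is None or _hit_rank(r) < _hit_rank(cur):
            best[r.query_id] = r
    return best


def pair_best_hits(
    target_records: Iterable[HitRecord],
    contam_records: Iterable[HitRecord],
    queries: Sequence[str],
) -> list[BestHitPair]:
    bt = best_hits(target_records, queries)
    bc = best_hits(contam_records, queries)
    return [BestHitPair(q, bt[q], bc[q]) for q in queries]


def read_domain_table(path: Union[str, Path]) -> list[DomainHit]:
    """Read a whitespace-delimited per-sequence domain table (tblout-style).

    Column mapping: target name -> domain_name, target accession ->
    domain_acc, query name -> protein_id, full-sequence E-value -> e_value.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise HitTableParseError(
                    f"{path}: line {lineno}: expected at least 5 whitespace-delimited "
                    f"columns, got {len(fields)}"
                )
            try:
                hits.append(
                    DomainHit(
                        protein_id=fields[2],
                        domain_acc=fields[1],
                        domain_name=fields[0],
                        e_value=float(fields[4]),
                    )
                )
            except ValueError as exc:
                raise HitTableParseError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_best_hits_tsv(
    pairs: Iterable[BestHitPair], dest: Union[str, Path, TextIO]
) -> None:
    """Export best-hit pairs as a long-format TSV (one row per query x db)."""

    def _emit(fh: TextIO) -> None:
        fh.write("query_id\tdb\tsubject_id\tpct_identity\te_value\tbit_score\n")
        for p in pairs:
            for db, hit in (("target", p.best_target), ("contaminant", p.best_contam)):
                if hit is None:
                    fh.write(f"{p.query_id}\t{db}\t.\t.\t.\t.\n")
                else:
                    fh.write(
                        f"{p.query_id}\t{db}\t{hit.subject_id}\t{hit.pct_identity:.2f}\t"
                        f"{hit.e_value:.3e}\t{hit.bit_score:.1f}\n"
                    )

    if hasattr(dest, "write"):
        _emit(dest)  # type: ignore[arg-type]
    else:
        with open(dest, "w") as fh:
            _emit(fh)
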