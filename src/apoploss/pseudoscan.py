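"""In-frame stop-codon scanning of aligned candidate genes.

Given a candidate amino-acid sequence aligned against intact reference
sequences, insertions are called where the candidate has residues opposite
mostly-gap reference columns. Stops ('*') falling inside the structural
domain are counted and split into inside-insertion vs outside-insertion;
a stop outside insertions that hits the conserved sub-span upgrades the
verdict.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

from .seqio_gc import read_fasta, translate

__all__ = [
    "AlignedCandidate",
    "InsertionSegment",
    "AlignmentIndex",
    "Verdict",
    "PseudogeneReport",
    "index_alignment",
    "find_insertions",
    "scan_stops",
    "scan_alignment_file",
    "report_to_text",
]

GAP_CHARS = frozenset("-.")


class Verdict(str, enum.Enum):
    INTACT = "intact"
    PSEUDOGENE_INSERTION_ONLY = "pseudogene_insertion_only"
    PSEUDOGENE_CONSERVED_DISRUPTED = "pseudogene_conserved_disrupted"
    # stops outside insertions but missing the conserved sub-span; not one of
    # the three canonical patterns but logically reachable
    PSEUDOGENE_OUTSIDE_INSERTIONS = "pseudogene_outside_insertions"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class AlignedCandidate:
    """A candidate coding sequence plus its row in a reference alignment.

    ``domain_span`` and ``conserved_span`` are 1-based inclusive intervals
    in reference coordinates (positions along the ungapped reference
    consensus). ``nt_seq`` (frame +1 by construction) is optional context;
    when given, its translation must equal the ungapped ``aligned_aa``.
    """

    candidate_id: str
    aligned_aa: str
    domain_span: tuple[int, int]
    conserved_span: Optional[tuple[int, int]] = None
    nt_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.domain_span[0] < 1 or self.domain_span[0] > self.domain_span[1]:
            raise ValueError(f"bad domain_span {self.domain_span}")
        if self.conserved_span is not None:
            c0, c1 = self.conserved_span
            if not (self.domain_span[0] <= c0 <= c1 <= self.domain_span[1]):
                raise ValueError("conserved_span must lie within domain_span")
        if self.nt_seq is not None:
            ungapped = "".join(ch for ch in self.aligned_aa if ch not in GAP_CHARS)
            trans = translate(self.nt_seq)
            if trans != ungapped:
                raise ValueError(
                    f"candidate {self.candidate_id!r}: translation of nt_seq does not "
                    "match the ungapped aligned sequence"
                )


@dataclass(frozen=True)
class InsertionSegment:
    """A candidate-specific insertion, in alignment-column and reference coords.

    ``col_start``/``col_end`` are 0-based half-open alignment columns;
    ``ref_anchor`` is the 1-based reference position immediately preceding
    the insertion (0 when it precedes the first reference position).
    """

    col_start: int
    col_end: int
    ref_anchor: int

    @property
    def length(self) -> int:
        return self.col_end - self.col_start


@dataclass
class AlignmentIndex:
    """Per-column bookkeeping for one candidate against its references."""

    n_columns: int
    is_insertion: list[bool]
    ref_pos: list[int]  # 1-based ref position of each reference column; for
    # insertion columns, the position of the preceding reference column
    is_ref_column: list[bool]
    insertions: list[InsertionSegment]


def index_alignment(
    candidate_aligned: str,
    references_aligned: Sequence[str],
    gap_fraction: float = 0.8,
) -> AlignmentIndex:
    """Classify alignment columns and call candidate insertions.

    A column is an insertion column when the candidate holds a residue and
    at least ``gap_fraction`` of the references are gapped there; maximal
    runs of such columns form insertion segments anchored to reference
    coordinates.
    """
    if not references_aligned:
        raise ValueError("at least one reference row is required")
    n = len(candidate_aligned)
    for r in references_aligned:
        if len(r) != n:
            raise ValueError("alignment rows differ in length")

    n_refs = len(references_aligned)
    is_insertion = [False] * n
    is_ref_column = [False] * n
    ref_pos = [0] * n
    pos = 0
    for i in range(n):
        gapped = sum(1 for r in references_aligned if r[i] in GAP_CHARS)
        mostly_gap = gapped / n_refs >= gap_fraction
        if not mostly_gap:
            pos += 1
            is_ref_column[i] = True
        elif candidate_aligned[i] not in GAP_CHARS:
            is_insertion[i] = True
        ref_pos[i] = pos

    insertions: list[InsertionSegment] = []
    i = 0
    while i < n:
        if is_insertion[i]:
            j = i
            while j < n and is_insertion[j]:
                j += 1
            insertions.append(InsertionSegment(i, j, ref_pos[i]))
            i = j
        else:
            i += 1
    return AlignmentIndex(n, is_insertion, ref_pos, is_ref_column, insertions)


def find_insertions(
    candidate_aligned: str,
    references_aligned: Sequence[str],
    gap_fraction: float = 0.8,
) -> list[InsertionSegment]:
    return index_alignment(candidate_aligned, references_aligned, gap_fraction).insertions


@dataclass
class PseudogeneReport:
    candidate_id: str
    n_stops_total: int
    n_stops_in_insertions: int
    n_stops_outside_insertions: int
    n_stops_in_conserved: int
    insertion_segments: list[InsertionSegment]
    verdict: Verdict
    # alignment columns of domain stops, for rendering
    stop_columns: list[int] = field(default_factory=list)


def scan_stops(candidate: AlignedCandidate, index: AlignmentIndex) -> PseudogeneReport:
    """Count in-frame stops within the structural domain and classify them.

    A stop at a reference column with position p is inside the domain iff
    d0 <= p <= d1; a stop inside an insertion anchored after reference
    position a counts iff d0 <= a < d1. Verdict: intact when no domain stop
    exists; conserved-disrupted when any outside-insertion stop falls in the
    conserved span; insertion-only when all domain stops sit in insertions.
    """
    if len(candidate.aligned_aa) != index.n_columns:
        raise ValueError("candidate row length does not match the alignment index")
    d0, d1 = candidate.domain_span
    conserved = candidate.conserved_span
    n_in = n_out = n_cons = 0
    cons_outside = False
    stop_cols: list[int] = []
    for i, ch in enumerate(candidate.aligned_aa):
        if ch != "*":
            continue
        p = index.ref_pos[i]
        if index.is_ref_column[i]:
            in_domain = d0 <= p <= d1
        else:
            # column anchored between ref positions p and p+1 (insertion
            # columns stay anchored even if the insertion mask is edited)
            in_domain = d0 <= p < d1
        if not in_domain:
            continue
        stop_cols.append(i)
        if index.is_insertion[i]:
            n_in += 1
        else:
            n_out += 1
            if conserved is not None and conserved[0] <= p <= conserved[1]:
                n_cons += 1
                cons_outside = True
    total = n_in + n_out
    if total == 0:
        verdict = Verdict.INTACT
    elif cons_outside:
        verdict = Verdict.PSEUDOGENE_CONSERVED_DISRUPTED
    elif n_out == 0:
        verdict = Verdict.PSEUDOGENE_INSERTION_ONLY
    else:
        verdict = Verdict.PSEUDOGENE_OUTSIDE_INSERTIONS
    return PseudogeneReport(
        candidate_id=candidate.candidate_id,
        n_stops_total=total,
        n_stops_in_insertions=n_in,
        n_stops_outside_insertions=n_out,
        n_stops_in_conserved=n_cons,
        insertion_segments=list(index.insertions),
        verdict=verdict,
        stop_columns=stop_cols,
    )


def scan_alignment_file(
    path: Union[str, Path],
    candidate_id: str,
    domain_span: tuple[int, int],
    conserved_span: Optional[tuple[int, int]] = None,
    gap_fraction: float = 0.8,
) -> PseudogeneReport:
    """Run the scan on an aligned FASTA (candidate + >= 1 reference rows)."""
    records = read_fasta(path)
    rows = {r.id: r.seq for r in records}
    if candidate_id not in rows:
        raise ValueError(f"candidate {candidate_id!r} not found in alignment {path}")
    refs = [seq for rid, seq in rows.items() if rid != candidate_id]
    if not refs:
        raise ValueError(f"alignment {path} has no reference rows besides the candidate")
    cand_row = rows[candidate_id]
    index = index_alignment(cand_row, refs, gap_fraction)
    candidate = AlignedCandidate(candidate_id, cand_row, domain_span, conserved_span)
    return scan_stops(candidate, index)


def report_to_text(report: PseudogeneReport) -> str:
    lines = [
        f"candidate: {report.candidate_id}",
        f"verdict: {report.verdict.value}",
        f"stops in domain: {report.n_stops_total} "
        f"(in insertions: {report.n_stops_in_insertions}, "
        f"outside: {report.n_stops_outside_insertions}, "
        f"in conserved region: {report.n_stops_in_conserved})",
    ]
    for seg in report.insertion_segments:
        n_here = sum(1 for c in report.stop_columns if seg.col_start <= c < seg.col_end)
        lines.append(
            f"insertion after ref position {seg.ref_anchor}: {seg.length} columns, "
            f"{n_here} stop(s)"
        )
    return "\n".join(lines)


def report_to_tsv(reports: Sequence[PseudogeneReport], dest: Union[str, Path, TextIO]) -> None:
    def _emit(fh: TextIO) -> None:
        fh.write(
            "candidate_id\tn_stops_total\tn_stops_in_insertions\t"
            "n_stops_outside_insertions\tn_stops_in_conserved\tn_insertions\tverdict\n"
        )
        for r in reports:
            fh.write(
                f"{r.candidate_id}\t{r.n_stops_total}\t{r.n_stops_in_insertions}\t"
                f"{r.n_stops_outside_insertions}\t{r.n_stops_in_conserved}\t"
                f"{len(r.insertion_segments)}\t{r.verdict.value}\n"
            )

    if hasattr(dest, "write"):
        _emit(dest)  # type: ignore[arg-type]
    else:
        with open(dest, "w") as fh:
            _emit(fh)
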