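"""Sequence I/O, GC content and six-frame ORF extraction.

Contigs are plain nucleotide records over {A,C,G,T,N} (ambiguity codes other
than N are tolerated and treated like N). ORFs are maximal stop-free
translated segments in any of the six reading frames, reported when they pass
a minimum amino-acid length (default 70 aa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

__all__ = [
    "Contig",
    "Orf",
    "OrfParams",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "gc_content",
    "reverse_complement",
    "translate",
    "extract_orfs",
    "orfs_to_fasta",
    "orfs_to_tsv",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# Standard genetic code. Stops are '*'; any codon containing a non-ACGT
# character translates to 'X' and never terminates an ORF.
_CODONS = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODONS[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

STOP_CODONS = frozenset(c for c, a in _CODONS.items() if a == "*")


class FastaParseError(ValueError):
    """Raised on malformed FASTA input; message carries the line number."""


@dataclass
class Contig:
    """A nucleotide sequence record.

    ``gc`` is the GC fraction over unambiguous bases, or ``None`` when the
    sequence has no A/C/G/T at all (GC-dependent code must route such
    contigs down the ambiguous path).
    """

    id: str
    seq: str
    truth_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) == 0:
            raise ValueError(f"contig {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> Optional[float]:
        return gc_content(self.seq)


@dataclass(frozen=True)
class Orf:
    """A translated open reading frame.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    strand of the contig regardless of frame sign; for negative frames the
    segment must be reverse-complemented before translation.
    """

    contig_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    start: int
    end: int
    aa_seq: str

    @property
    def aa_len(self) -> int:
        return len(self.aa_seq)


@dataclass(frozen=True)
class OrfParams:
    min_len_aa: int = 70
    require_start_codon: bool = False
    genetic_code: str = "standard"

    def __post_init__(self) -> None:
        if self.min_len_aa < 1:
            raise ValueError("min_len_aa must be >= 1")
        if self.genetic_code != "standard":
            raise ValueError("only the standard genetic code is supported")


def read_fasta(path: Union[str, Path]) -> list[Contig]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    The header token before the first whitespace becomes the contig id.
    Duplicate ids, empty records and text before the first '>' are errors.
    """
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    cur_id: Optional[str] = None
    cur_chunks: list[str] = []
    cur_line = 0

    def _flush() -> None:
        nonlocal cur_id, cur_chunks
        if cur_id is None:
            return
        seq = "".join(cur_chunks)
        if not seq:
            raise FastaParseError(
                f"{path}: record {cur_id!r} starting at line {cur_line} has an empty sequence"
            )
        contigs.append(Contig(id=cur_id, seq=seq))
        cur_id, cur_chunks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                token = line[1:].split()
                if not token:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                cur_id = token[0]
                cur_line = lineno
                if cur_id in seen:
                    raise FastaParseError(
                        f"{path}: duplicate sequence id {cur_id!r} at line {lineno}"
                    )
                seen.add(cur_id)
            else:
                if cur_id is None:
                    raise FastaParseError(
                        f"{path}: sequence data before first '>' at line {lineno}"
                    )
                cur_chunks.append(line)
    _flush()
    return contigs


def write_fasta(
    records: Iterable[tuple[str, str]], dest: Union[str, Path, TextIO], width: int = 60
) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""

    def _emit(fh: TextIO) -> None:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")

    if hasattr(dest, "write"):
        _emit(dest)  # type: ignore[arg-type]
    else:
        with open(dest, "w") as fh:
            _emit(fh)


def gc_content(seq_or_contig: Union[str, Contig]) -> Optional[float]:
    """GC fraction over unambiguous bases; None when there are none.

    N and other ambiguity codes are excluded from both numerator and
    denominator, so the result is invariant under reverse complement.
    """
    seq = seq_or_contig.seq if isinstance(seq_or_contig, Contig) else seq_or_contig.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return None
    return gc / (gc + at)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate frame +1 of ``nt``; trailing partial codon is dropped."""
    nt = nt.upper()
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        aa.append(_CODONS.get(nt[i : i + 3], "X"))
    return "".join(aa)


def extract_orfs(contig: Contig, params: OrfParams = OrfParams()) -> list[Orf]:
    """Extract stop-to-stop ORFs from all six reading frames.

    Segments truncated by the contig edge (no bounding stop codon) are
    reported when they meet the length floor. With ``require_start_codon``
    a segment is trimmed to its first internal methionine before the length
    check. Output is sorted by (contig_id, start, frame).
    """
    seq = contig.seq
    n = len(seq)
    out: list[Orf] = []
    for strand in (1, -1):
        strand_seq = seq if strand == 1 else reverse_complement(seq)
        for off in range(3):
            aa = translate(strand_seq[off:])
            i, m = 0, len(aa)
            while i < m:
                if aa[i] == "*":
                    i += 1
                    continue
                j = i
                while j < m and aa[j] != "*":
                    j += 1
                seg_start = i
                if params.require_start_codon:
                    k = aa.find("M", seg_start, j)
                    if k == -1:
                        i = j + 1
                        continue
                    seg_start = k
                aa_seq = aa[seg_start:j]
                if len(aa_seq) >= params.min_len_aa:
                    a = off + 3 * seg_start
                    b = off + 3 * j
                    start, end = (a, b) if strand == 1 else (n - b, n - a)
                    out.append(
                        Orf(
                            contig_id=contig.id,
                            frame=strand * (off + 1),
                            start=start,
                            end=end,
                            aa_seq=aa_seq,
                        )
                    )
                i = j + 1
    out.sort(key=lambda o: (o.contig_id, o.start, o.frame))
    return out


def orfs_to_fasta(orfs: Sequence[Orf], dest: Union[str, Path, TextIO]) -> None:
    """Write ORF amino-acid sequences with ``contigID|frame|start-end`` headers."""
    write_fasta(
        ((f"{o.contig_id}|{o.frame:+d}|{o.start}-{o.end}", o.aa_seq) for o in orfs), dest
    )


def orfs_to_tsv(orfs: Sequence[Orf], dest: Union[str, Path, TextIO]) -> None:
    def _emit(fh: TextIO) -> None:
        fh.write("contig_id\tframe\tstart\tend\taa_len\n")
        for o in orfs:
            fh.write(f"{o.contig_id}\t{o.frame:+d}\t{o.start}\t{o.end}\t{o.aa_len}\n")

    if hasattr(dest, "write"):
        _emit(dest)  # type: ignore[arg-type]
    else:
        with open(dest, "w") as fh:
            _emit(fh)
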