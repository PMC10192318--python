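"""Synthetic fixtures with known ground truth.

Generates (a) two-population contig mixtures with a low-GC target mode and
a high-GC contaminant mode, (b) paired 12-column best-hit tables whose
e-value/bit-score separation between the two databases is a tunable knob,
and (c) aligned pseudogene fixtures with planted insertions and stop
codons. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .hits import HitRecord, write_hit_table
from .pseudoscan import (
    AlignedCandidate,
    PseudogeneReport,
    Verdict,
    index_alignment,
    scan_stops,
)
from .seqio_gc import Contig, write_fasta

__all__ = [
    "SimParams",
    "simulate_assembly",
    "simulate_hits",
    "PseudoFixtureParams",
    "PseudoFixture",
    "simulate_pseudogene_fixture",
    "write_assembly",
    "write_manifest",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    seed: int
    n_target: int = 1000
    n_contam: int = 1000
    gc_target_mean: float = 0.28
    gc_target_sd: float = 0.03
    gc_contam_mean: float = 0.55
    gc_contam_sd: float = 0.04
    length_median: float = 1000.0
    length_sigma: float = 0.5
    min_length: int = 300
    # hit model: own-db best-hit strength s ~ U(*strength_range*) in
    # -log10(e-value); other db weaker by sep_evalue fold (with a small
    # exponent jitter) and sep_bitscore-fold lower bit score
    strength_range: tuple[float, float] = (40.0, 150.0)
    sep_evalue: float = 1e4
    sep_bitscore: float = 2.0
    evalue_jitter_log10: float = 0.25
    bitscore_jitter: float = 0.1
    p_no_hit: float = 0.0

    def __post_init__(self) -> None:
        if self.n_target < 0 or self.n_contam < 0:
            raise ValueError("population sizes must be non-negative")
        if not 0 <= self.p_no_hit <= 1:
            raise ValueError("p_no_hit must be in [0, 1]")
        for sd in (self.gc_target_sd, self.gc_contam_sd):
            if sd <= 0:
                raise ValueError("GC standard deviations must be positive")
        if self.sep_evalue < 1 or self.sep_bitscore < 1:
            raise ValueError("separation knobs must be >= 1")


def _realize_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """Sequence with composition matching ``gc`` exactly (to rounding)."""
    n_gc = int(round(gc * length))
    strong = rng.choice(["G", "C"], size=n_gc)
    weak = rng.choice(["A", "T"], size=length - n_gc)
    seq = np.concatenate([strong, weak])
    rng.shuffle(seq)
    return "".join(seq)


def simulate_assembly(params: SimParams) -> list[Contig]:
    """Mixed assembly with truth labels 'target' / 'contaminant'.

    Per-contig GC is drawn from the origin's normal mode (clipped to
    [0.05, 0.95]) and realized by exact-composition sampling, so realized GC
    matches the draw to rounding precision.
    """
    if params.n_target + params.n_contam == 0:
        raise ValueError("n_target + n_contam must be positive")
    rng = np.random.default_rng(params.seed)
    contigs: list[Contig] = []
    specs = [
        ("target", params.n_target, params.gc_target_mean, params.gc_target_sd),
        ("contaminant", params.n_contam, params.gc_contam_mean, params.gc_contam_sd),
    ]
    idx = 0
    for label, n, mean, sd in specs:
        for _ in range(n):
            idx += 1
            gc = float(np.clip(rng.normal(mean, sd), 0.05, 0.95))
            length = max(
                params.min_length,
                int(round(rng.lognormal(np.log(params.length_median), params.length_sigma))),
            )
            contigs.append(
                Contig(
                    id=f"contig_{idx:06d}",
                    seq=_realize_sequence(rng, length, gc),
                    truth_label=label,
                )
            )
    return contigs


def simulate_hits(
    contigs: Sequence[Contig], params: SimParams
) -> tuple[list[HitRecord], list[HitRecord]]:
    """Best-hit rows against the target and contaminant databases.

    Each hit-bearing contig gets one row per database; its own-origin
    database dominates: e-value smaller by ~``sep_evalue`` fold and bit
    score larger by ~``sep_bitscore`` fold. ``sep_evalue == sep_bitscore ==
    1`` gives no signal (identical pairs up to jitter).
    """
    rng = np.random.default_rng(params.seed + 1)
    target_rows: list[HitRecord] = []
    contam_rows: list[HitRecord] = []
    for c in contigs:
        if c.truth_label not in ("target", "contaminant"):
            raise ValueError(f"contig {c.id} lacks a truth label")
        if rng.random() < params.p_no_hit:
            continue
        s = rng.uniform(*params.strength_range)  # own-db -log10(e-value)
        jitter = rng.uniform(-params.evalue_jitter_log10, params.evalue_jitter_log10)
        s_other = s - np.log10(params.sep_evalue) + jitter
        bit_own = 2.0 * s
        bit_other = (bit_own / params.sep_bitscore) * (
            1.0 + rng.uniform(-params.bitscore_jitter, params.bitscore_jitter)
        )
        aln_len = max(50, c.length // 3)

        def _row(subject: str, strength: float, bits: float) -> HitRecord:
            e_val = float(10.0 ** (-max(strength, 0.0))) if strength > 0 else 1.0
            ident = float(np.round(rng.uniform(70.0, 99.5), 2))
            return HitRecord(
                query_id=c.id,
                subject_id=subject,
                pct_identity=ident,
                aln_len=aln_len,
                mismatches=int(aln_len * (1 - ident / 100)),
                gap_opens=0,
                q_start=1,
                q_end=aln_len,
                s_start=1,
                s_end=aln_len,
                e_value=e_val,
                bit_score=float(np.round(bits, 1)),
            )

        if c.truth_label == "target":
            target_rows.append(_row(f"tdb|{c.id}", s, bit_own))
            contam_rows.append(_row(f"cdb|{c.id}", s_other, bit_other))
        else:
            contam_rows.append(_row(f"cdb|{c.id}", s, bit_own))
            target_rows.append(_row(f"tdb|{c.id}", s_other, bit_other))
    return target_rows, contam_rows


# ---------------------------------------------------------------------------
# pseudogene fixture

# one unambiguous codon per amino acid (no stops)
_AA_TO_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_AA_ALPHABET = "".join(sorted(_AA_TO_CODON))


@dataclass(frozen=True)
class PseudoFixtureParams:
    seed: int
    ref_len: int = 130
    n_refs: int = 4
    domain_span: tuple[int, int] = (11, 120)
    conserved_span: Optional[tuple[int, int]] = (41, 109)  # 69-aa conserved core
    # insertions: (ref_anchor, length_aa, n_stops_inside)
    insertions: tuple[tuple[int, int, int], ...] = ()
    # stops planted outside insertions, at 1-based reference positions
    stops_at_ref_positions: tuple[int, ...] = ()


@dataclass
class PseudoFixture:
    records: list[tuple[str, str]]  # aligned FASTA rows (candidate first)
    candidate_id: str
    candidate_nt: str
    domain_span: tuple[int, int]
    conserved_span: Optional[tuple[int, int]]
    truth: PseudogeneReport


def simulate_pseudogene_fixture(params: PseudoFixtureParams) -> PseudoFixture:
    """Reference set + candidate with planted insertions and stop codons.

    The candidate equals the reference protein except for the planted
    edits, so the truth report is known by construction (and re-derived
    through the scanner on the constructed alignment for consistency).
    """
    rng = np.random.default_rng(params.seed)
    ref_aa = "".join(rng.choice(list(_AA_ALPHABET), size=params.ref_len))

    # candidate amino acids in reference coordinates, then planted edits
    cand_cols: list[str] = list(ref_aa)
    stops_outside = set(params.stops_at_ref_positions)
    for p in stops_outside:
        if not 1 <= p <= params.ref_len:
            raise ValueError(f"stop position {p} outside reference length")
        cand_cols[p - 1] = "*"

    # build aligned rows: walk reference positions, splicing insertions after
    # their anchors (anchors must be distinct and ordered for clarity)
    ins_by_anchor = {}
    for anchor, length, n_stops in params.insertions:
        if not 0 <= anchor <= params.ref_len:
            raise ValueError(f"insertion anchor {anchor} outside reference")
        if n_stops > length:
            raise ValueError("more stops than insertion columns")
        if anchor in ins_by_anchor:
            raise ValueError("duplicate insertion anchor")
        ins_by_anchor[anchor] = (length, n_stops)

    cand_row: list[str] = []
    ref_row: list[str] = []
    def _emit_insertion(anchor: int) -> None:
        length, n_stops = ins_by_anchor[anchor]
        aa = list(rng.choice(list(_AA_ALPHABET), size=length))
        stop_cols = rng.choice(length, size=n_stops, replace=False)
        for ci in stop_cols:
            aa[ci] = "*"
        cand_row.extend(aa)
        ref_row.extend("-" * length)

    if 0 in ins_by_anchor:
        _emit_insertion(0)
    for p in range(1, params.ref_len + 1):
        cand_row.append(cand_cols[p - 1])
        ref_row.append(ref_aa[p - 1])
        if p in ins_by_anchor:
            _emit_insertion(p)

    cand_aligned = "".join(cand_row)
    ref_aligned = "".join(ref_row)
    cand_nt = "".join(
        "TAA" if ch == "*" else _AA_TO_CODON[ch]
        for ch in cand_aligned
        if ch != "-"
    )

    records = [("candidate", cand_aligned)]
    for i in range(params.n_refs):
        records.append((f"ref_{i+1}", ref_aligned))

    candidate = AlignedCandidate(
        "candidate",
        cand_aligned,
        params.domain_span,
        params.conserved_span,
        nt_seq=cand_nt,
    )
    index = index_alignment(cand_aligned, [r for _, r in records[1:]])
    truth = scan_stops(candidate, index)
    return PseudoFixture(
        records=records,
        candidate_id="candidate",
        candidate_nt=cand_nt,
        domain_span=params.domain_span,
        conserved_span=params.conserved_span,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# file emission

def write_assembly(
    contigs: Sequence[Contig], fasta_path: Union[str, Path], truth_path: Union[str, Path]
) -> None:
    write_fasta(((c.id, c.seq) for c in contigs), fasta_path)
    with open(truth_path, "w") as fh:
        fh.write("contig_id\ttruth_label\tlength\tgc\n")
        for c in contigs:
            gc = c.gc
            fh.write(
                f"{c.id}\t{c.truth_label}\t{c.length}\t"
                f"{'' if gc is None else f'{gc:.4f}'}\n"
            )


def write_manifest(
    out_dir: Union[str, Path], seed: int, paths: dict[str, Union[str, Path]],
    extra: Optional[dict] = None,
) -> Path:
    """Record the seed, output paths and their checksums."""
    out_dir = Path(out_dir)
    manifest = {"seed": seed, "files": {}, **(extra or {})}
    for name, p in sorted(paths.items()):
        p = Path(p)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        manifest["files"][name] = {"path": str(p), "sha256": digest}
    dest = out_dir / "manifest.json"
    with open(dest, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return dest
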