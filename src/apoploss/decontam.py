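"""Assembly decontamination.

Two procedures:

1. Host-genome exclusion: a contig whose best hit against the host genome
   shows > 85% identity AND e-value < 1e-75 (both strict) is excluded.

2. Three-way classification of contigs from dual-database best hits: a
   contig is assigned to the target clade when its best target-database hit
   has an e-value at least 100-fold smaller AND a bit score at least
   1.5-fold larger than the best contaminant-database hit (mirrored for the
   contamination call; both comparisons inclusive), otherwise it is
   "not clear" and resolved by a GC-content cutoff (low GC -> target).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.stats import gaussian_kde

from .hits import BestHitPair, HitRecord, best_hits, pair_best_hits
from .seqio_gc import Contig, write_fasta

__all__ = [
    "Label",
    "HostFilterParams",
    "ClassifierParams",
    "ClassLabel",
    "GcPartitionParams",
    "GcCutoffEstimate",
    "UnimodalGcError",
    "PRESET_GC_CUTOFFS",
    "host_filter",
    "classify_contig",
    "gc_partition",
    "estimate_gc_cutoff",
    "run_decontam_pipeline",
    "DecontamResult",
]


class Label(str, enum.Enum):
    TARGET = "target"
    CONTAMINATION = "contamination"
    NOT_CLEAR = "not_clear"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# GC cutoffs used for the three published transcriptome filterings, as
# fractions: Buddenbrockia plumatellae; Tetracapsuloides bryosalmonae from
# fish kidney; T. bryosalmonae from the bryozoan host.
PRESET_GC_CUTOFFS = {
    "b_plumatellae": 0.3903,
    "t_bryosalmonae_fish": 0.4080,
    "t_bryosalmonae_bryozoan": 0.3692,
}


@dataclass(frozen=True)
class HostFilterParams:
    identity_threshold: float = 85.0  # strictly-greater comparison
    evalue_threshold: float = 1e-75  # strictly-less comparison

    def __post_init__(self) -> None:
        if not 0 <= self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in [0, 100]")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")


@dataclass(frozen=True)
class ClassifierParams:
    evalue_fold: float = 100.0
    bitscore_fold: float = 1.5
    evalue_floor: float = 1e-180  # substitutes exact-zero e-values in ratios
    no_hit_label: Label = Label.NOT_CLEAR

    def __post_init__(self) -> None:
        if self.evalue_fold <= 1:
            raise ValueError("evalue_fold must be > 1")
        if self.bitscore_fold <= 1:
            raise ValueError("bitscore_fold must be > 1")
        if self.evalue_floor <= 0:
            raise ValueError("evalue_floor must be positive")


@dataclass(frozen=True)
class ClassLabel:
    value: Label
    rule: str
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GcPartitionParams:
    cutoff: Union[float, str] = "auto"  # fraction in (0,1) or "auto"
    # contigs with undefined GC (no unambiguous bases) default to
    # contamination with a warning; configurable
    undefined_gc_label: Label = Label.CONTAMINATION

    def __post_init__(self) -> None:
        if self.cutoff != "auto" and not 0 < float(self.cutoff) < 1:
            raise ValueError("cutoff must be a fraction in (0, 1) or 'auto'")


class UnimodalGcError(ValueError):
    """No valley found between two GC modes; an explicit cutoff is required."""


@dataclass(frozen=True)
class GcCutoffEstimate:
    cutoff: float
    method: str
    peak_low: float
    peak_high: float


def host_filter(
    contig_id: str,
    best_hit: Optional[HitRecord],
    params: HostFilterParams = HostFilterParams(),
) -> str:
    """Decide keep/exclude for one contig from its best host-genome hit.

    Excludes iff a hit exists with pct_identity strictly above the identity
    threshold and e-value strictly below the e-value threshold.
    """
    if (
        best_hit is not None
        and best_hit.pct_identity > params.identity_threshold
        and best_hit.e_value < params.evalue_threshold
    ):
        return "exclude"
    return "keep"


def classify_contig(
    pair: BestHitPair, params: ClassifierParams = ClassifierParams()
) -> ClassLabel:
    """Three-way label from best hits against the two databases.

    Fold comparisons are inclusive ("at least"); a hit in exactly one
    database decides toward that database; no hits at all yields
    ``params.no_hit_label``.
    """
    t, c = pair.best_target, pair.best_contam
    ev = {
        "target_hit": t.subject_id if t else None,
        "contam_hit": c.subject_id if c else None,
    }
    if t is None and c is None:
        return ClassLabel(params.no_hit_label, "no_hits", ev)
    if c is None:
        return ClassLabel(Label.TARGET, "single_db_target", ev)
    if t is None:
        return ClassLabel(Label.CONTAMINATION, "single_db_contam", ev)
    et = max(t.e_value, params.evalue_floor)
    ec = max(c.e_value, params.evalue_floor)
    ev.update(e_target=et, e_contam=ec, bits_target=t.bit_score, bits_contam=c.bit_score)
    if et <= ec / params.evalue_fold and t.bit_score >= params.bitscore_fold * c.bit_score:
        return ClassLabel(Label.TARGET, "fold_rule", ev)
    if ec <= et / params.evalue_fold and c.bit_score >= params.bitscore_fold * t.bit_score:
        return ClassLabel(Label.CONTAMINATION, "fold_rule", ev)
    return ClassLabel(Label.NOT_CLEAR, "ambiguous", ev)


def gc_partition(
    contigs: Sequence[Contig],
    params: GcPartitionParams,
    warnings: Optional[list[str]] = None,
) -> dict[str, ClassLabel]:
    """Resolve "not clear" contigs by GC content: gc <= cutoff -> target.

    The low side is inclusive. With ``cutoff="auto"`` the boundary is
    estimated from the contigs' own GC values (requires >= 20 defined
    values).
    """
    if params.cutoff == "auto":
        values = [c.gc for c in contigs if c.gc is not None]
        if len(values) < 20:
            raise ValueError(
                f"auto GC cutoff needs >= 20 contigs with defined GC, got {len(values)}; "
                "pass an explicit cutoff"
            )
        cutoff = estimate_gc_cutoff(values).cutoff
    else:
        cutoff = float(params.cutoff)

    out: dict[str, ClassLabel] = {}
    for c in contigs:
        gc = c.gc
        if gc is None:
            if warnings is not None:
                warnings.append(f"contig {c.id}: undefined GC, defaulting to "
                                f"{params.undefined_gc_label.value}")
            out[c.id] = ClassLabel(
                params.undefined_gc_label, "gc_undefined", {"cutoff": cutoff}
            )
        elif gc <= cutoff:
            out[c.id] = ClassLabel(Label.TARGET, "gc_rescue", {"gc": gc, "cutoff": cutoff})
        else:
            out[c.id] = ClassLabel(
                Label.CONTAMINATION, "gc_rescue", {"gc": gc, "cutoff": cutoff}
            )
    return out


def estimate_gc_cutoff(
    gc_values: Iterable[float],
    *,
    grid_step: float = 0.001,
    valley_low: float = 0.15,
    valley_high: float = 0.70,
) -> GcCutoffEstimate:
    """Estimate the boundary between a low-GC and a high-GC contig mode.

    A Gaussian kernel density is evaluated on a fixed grid; the cutoff is
    the density minimum between the two tallest modes. Deterministic (no
    randomness is involved). Raises :class:`UnimodalGcError` when no valley
    exists between ``valley_low`` and ``valley_high``.
    """
    vals = np.asarray(sorted(gc_values), dtype=float)
    if vals.size < 20:
        raise ValueError(f"need >= 20 GC values, got {vals.size}")
    if np.ptp(vals) == 0:
        raise UnimodalGcError("all GC values identical; supply an explicit cutoff")

    kde = gaussian_kde(vals)
    grid = np.arange(0.0, 1.0 + grid_step, grid_step)
    dens = kde(grid)

    # interior local maxima (plateau-tolerant on the right)
    peak_idx = [
        i
        for i in range(1, len(grid) - 1)
        if dens[i] > dens[i - 1] and dens[i] >= dens[i + 1]
    ]
    # ignore negligible bumps
    peak_idx = [i for i in peak_idx if dens[i] >= 0.05 * dens.max()]
    if len(peak_idx) < 2:
        raise UnimodalGcError(
            "GC distribution appears unimodal; supply an explicit cutoff"
        )
    top_two = sorted(sorted(peak_idx, key=lambda i: dens[i], reverse=True)[:2])
    lo_i, hi_i = top_two
    between = slice(lo_i, hi_i + 1)
    valley_i = lo_i + int(np.argmin(dens[between]))
    cutoff = float(grid[valley_i])
    if not (valley_low < cutoff < valley_high):
        raise UnimodalGcError(
            f"density valley at {cutoff:.3f} outside ({valley_low}, {valley_high}); "
            "supply an explicit cutoff"
        )
    return GcCutoffEstimate(
        cutoff=cutoff,
        method="kde_valley",
        peak_low=float(grid[lo_i]),
        peak_high=float(grid[hi_i]),
    )


@dataclass
class DecontamResult:
    rows: list[dict]  # per-contig: contig_id, length, gc, label, rule, evidence
    counts: dict[str, int]  # final label -> n (plus 'not_clear_resolved')
    warnings: list[str]
    gc_cutoff: Optional[float]
    kept: list[Contig]  # target-labelled contigs


def run_decontam_pipeline(
    contigs: Sequence[Contig],
    target_records: Iterable[HitRecord],
    contam_records: Iterable[HitRecord],
    *,
    host_records: Optional[Iterable[HitRecord]] = None,
    host_params: HostFilterParams = HostFilterParams(),
    classifier_params: ClassifierParams = ClassifierParams(),
    gc_params: GcPartitionParams = GcPartitionParams(cutoff="auto"),
    out_dir: Optional[Union[str, Path]] = None,
) -> DecontamResult:
    """End-to-end decontamination of one assembly.

    Optional host-genome exclusion first, then dual-database classification,
    then GC resolution of the "not clear" group. Per-contig decisions and
    label counts are returned and (optionally) written as a filtered FASTA
    plus TSV reports. Label counts always sum to the input contig count.
    """
    if not contigs:
        raise ValueError("assembly contains no contigs")
    warnings: list[str] = []
    ids = [c.id for c in contigs]
    id_set = set(ids)
    by_id = {c.id: c for c in contigs}

    target_records = list(target_records)
    contam_records = list(contam_records)
    stray = sorted(
        {r.query_id for r in target_records} | {r.query_id for r in contam_records}
    - id_set)
    for q in stray:
        warnings.append(f"hit-table query {q!r} not found in assembly")

    labels: dict[str, ClassLabel] = {}

    remaining = list(contigs)
    if host_records is not None:
        best_host = best_hits(host_records, ids)
        kept_after_host = []
        for c in remaining:
            if host_filter(c.id, best_host[c.id], host_params) == "exclude":
                hit = best_host[c.id]
                labels[c.id] = ClassLabel(
                    Label.CONTAMINATION,
                    "host_excluded",
                    {"subject": hit.subject_id, "pct_identity": hit.pct_identity,
                     "e_value": hit.e_value},
                )
            else:
                kept_after_host.append(c)
        remaining = kept_after_host

    pairs = pair_best_hits(target_records, contam_records, [c.id for c in remaining])
    not_clear: list[Contig] = []
    for c, pair in zip(remaining, pairs):
        lab = classify_contig(pair, classifier_params)
        labels[c.id] = lab
        if lab.value is Label.NOT_CLEAR:
            not_clear.append(c)

    gc_cutoff: Optional[float] = None
    if not_clear:
        if gc_params.cutoff == "auto":
            vals = [c.gc for c in not_clear if c.gc is not None]
            if len(vals) >= 20:
                try:
                    gc_cutoff = estimate_gc_cutoff(vals).cutoff
                except UnimodalGcError as exc:
                    raise UnimodalGcError(
                        f"auto GC cutoff failed for the not_clear group: {exc}"
                    ) from exc
            else:
                raise ValueError(
                    "auto GC cutoff needs >= 20 not_clear contigs with defined GC; "
                    "pass an explicit cutoff"
                )
            resolved = gc_partition(
                not_clear, GcPartitionParams(gc_cutoff, gc_params.undefined_gc_label),
                warnings,
            )
        else:
            gc_cutoff = float(gc_params.cutoff)
            resolved = gc_partition(not_clear, gc_params, warnings)
        labels.update(resolved)

    counts = {"target": 0, "contamination": 0, "host_excluded": 0,
              "not_clear_resolved": len(not_clear)}
    rows = []
    kept: list[Contig] = []
    for cid in ids:
        lab = labels[cid]
        if lab.rule == "host_excluded":
            counts["host_excluded"] += 1
        else:
            counts[lab.value.value] += 1
        c = by_id[cid]
        gc = c.gc
        rows.append(
            {
                "contig_id": cid,
                "length": c.length,
                "gc": "" if gc is None else f"{gc:.4f}",
                "label": "host_excluded" if lab.rule == "host_excluded" else lab.value.value,
                "rule": lab.rule,
                "evidence": ";".join(f"{k}={v}" for k, v in sorted(lab.evidence.items())),
            }
        )
        if lab.value is Label.TARGET and lab.rule != "host_excluded":
            kept.append(c)

    result = DecontamResult(rows, counts, warnings, gc_cutoff, kept)
    if out_dir is not None:
        _write_outputs(result, host_params, classifier_params, gc_params, Path(out_dir))
    return result


def _write_outputs(
    result: DecontamResult,
    host_params: HostFilterParams,
    classifier_params: ClassifierParams,
    gc_params: GcPartitionParams,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(((c.id, c.seq) for c in result.kept), out_dir / "target_contigs.fasta")
    header = [
        "# decontamination report",
        f"# identity_threshold={host_params.identity_threshold}",
        f"# evalue_threshold={host_params.evalue_threshold}",
        f"# evalue_fold={classifier_params.evalue_fold}",
        f"# bitscore_fold={classifier_params.bitscore_fold}",
        f"# evalue_floor={classifier_params.evalue_floor}",
        f"# gc_cutoff={'auto' if gc_params.cutoff == 'auto' else gc_params.cutoff}"
        + (f" (resolved={result.gc_cutoff})" if result.gc_cutoff is not None else ""),
    ]
    cols = ["contig_id", "length", "gc", "label", "rule", "evidence"]
    with open(out_dir / "classification_report.tsv", "w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write("\t".join(cols) + "\n")
        for row in result.rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    with open(out_dir / "gc_length_by_label.tsv", "w") as fh:
        fh.write("contig_id\tgc\tlength\tlabel\n")
        for row in result.rows:
            fh.write(f"{row['contig_id']}\t{row['gc']}\t{row['length']}\t{row['label']}\n")
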