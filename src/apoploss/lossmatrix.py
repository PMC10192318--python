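"""Taxon x actor-category presence/absence matrix and loss-gradient summary.

The catalogue records named protein homologs per taxon group and actor
category (caspases, multidomain Bcl-2, BH3-only, death receptor, adaptor
protein, IAP, APAF-1, p53, cytochrome C, calpain). The boolean reduction
marks a cell present when at least one intact entry exists; pseudogene
entries are tracked in a side channel (optionally countable as present).
The loss gradient reports per-taxon retention counts along an ordered taxon
list and whether they are non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .hits import DomainHit

__all__ = [
    "CATEGORIES",
    "STATUSES",
    "CatalogueEntry",
    "ActorCatalogue",
    "PresenceMatrix",
    "GradientReport",
    "CategoryRule",
    "catalogue_from_table",
    "load_reference_catalogue",
    "load_default_category_rules",
    "catalogue_from_domains",
    "build_matrix",
    "loss_gradient",
    "render_circles",
]

CATEGORIES = (
    "caspase",
    "bcl2_multidomain",
    "bh3_only",
    "death_receptor",
    "adaptor_protein",
    "iap",
    "apaf1",
    "p53",
    "cytochrome_c",
    "calpain",
)
STATUSES = ("intact", "pseudogene", "absent_marker")

# Ordered parasitism gradient used for the reference catalogue
GRADIENT_ORDER = ("Hydra", "Polypodium", "Malacosporea", "Myxosporea")


@dataclass(frozen=True)
class CatalogueEntry:
    taxon: str
    category: str
    protein_id: str
    status: str = "intact"
    species: Optional[str] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; allowed: {', '.join(CATEGORIES)}"
            )
        if self.status not in STATUSES:
            raise ValueError(
                f"unknown status {self.status!r}; allowed: {', '.join(STATUSES)}"
            )


@dataclass
class ActorCatalogue:
    entries: list[CatalogueEntry]
    taxon_order: list[str]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for e in self.entries:
            key = (e.taxon, e.category, e.protein_id)
            if key in seen:
                raise ValueError(f"duplicate catalogue entry {key}")
            seen.add(key)
        order = set(self.taxon_order)
        for e in self.entries:
            if e.taxon not in order:
                raise ValueError(f"taxon {e.taxon!r} missing from taxon_order")

    @property
    def taxa(self) -> list[str]:
        return list(self.taxon_order)

    def count(
        self,
        taxon: Optional[str] = None,
        category: Optional[str] = None,
        species: Optional[str] = None,
        flag: Optional[str] = None,
        statuses: Iterable[str] = ("intact",),
    ) -> int:
        """Count entries matching the given filters (intact only by default)."""
        statuses = set(statuses)
        n = 0
        for e in self.entries:
            if taxon is not None and e.taxon != taxon:
                continue
            if category is not None and e.category != category:
                continue
            if species is not None and e.species != species:
                continue
            if flag is not None and flag not in e.flags:
                continue
            if e.status not in statuses:
                continue
            n += 1
        return n

    def to_tsv(self, dest: Union[str, Path]) -> None:
        with open(dest, "w") as fh:
            fh.write("taxon\tspecies\tcategory\tprotein_id\tstatus\tflags\n")
            for e in self.entries:
                fh.write(
                    f"{e.taxon}\t{e.species or ''}\t{e.category}\t{e.protein_id}\t"
                    f"{e.status}\t{','.join(e.flags)}\n"
                )


def catalogue_from_table(
    source: Union[str, Path, Iterable[Sequence[str]]],
    taxon_order: Optional[Sequence[str]] = None,
) -> ActorCatalogue:
    """Build a catalogue from a TSV file or row iterable.

    Rows carry (taxon, category, protein_id, status) in 4-column form, or
    (taxon, species, category, protein_id, status[, flags]) in 5/6-column
    form. A header row naming 'taxon' first is skipped; '#' lines are
    comments. When ``taxon_order`` is omitted it defaults to first
    appearance order.
    """
    if isinstance(source, (str, Path)):
        rows: list[list[str]] = []
        with open(source) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                rows.append(line.split("\t"))
    else:
        rows = [list(r) for r in source]

    entries: list[CatalogueEntry] = []
    order: list[str] = []
    for row in rows:
        if row and row[0] == "taxon":  # header
            continue
        if len(row) == 4:
            taxon, category, protein_id, status = row
            species, flags = None, ()
        elif len(row) in (5, 6):
            taxon, species, category, protein_id, status = row[:5]
            species = species or None
            flags = tuple(f for f in (row[5].split(",") if len(row) == 6 else []) if f)
        else:
            raise ValueError(f"catalogue row must have 4-6 columns, got {len(row)}: {row}")
        entries.append(
            CatalogueEntry(taxon, category, protein_id, status, species, tuple(flags))
        )
        if taxon not in order:
            order.append(taxon)
    return ActorCatalogue(entries, list(taxon_order) if taxon_order else order)


def load_reference_catalogue() -> ActorCatalogue:
    """The packaged curated catalogue (six taxon groups, ten categories)."""
    with resources.as_file(
        resources.files("apoploss.data") / "table1_catalogue.tsv"
    ) as p:
        return catalogue_from_table(p)


@dataclass(frozen=True)
class CategoryRule:
    category: str
    required: frozenset[str]
    flags: Mapping[str, frozenset[str]]


def load_default_category_rules() -> dict[str, CategoryRule]:
    with resources.as_file(resources.files("apoploss.data") / "category_rules.yaml") as p:
        raw = yaml.safe_load(p.read_text())
    rules = {}
    for cat, spec in raw.items():
        rules[cat] = CategoryRule(
            category=cat,
            required=frozenset(spec["required"]),
            flags={k: frozenset(v) for k, v in (spec.get("flags") or {}).items()},
        )
    return rules


def catalogue_from_domains(
    domain_hits_by_taxon: Mapping[str, Iterable[DomainHit]],
    category_map: Optional[Mapping[str, CategoryRule]] = None,
    evalue_max: float = 1e-5,
    taxon_order: Optional[Sequence[str]] = None,
) -> ActorCatalogue:
    """Assign proteins to actor categories from their domain complements.

    A protein joins a category iff every domain in the category's required
    set appears among its hits with e-value <= ``evalue_max`` (matching on
    domain name or accession). Flag domain sets annotate entries, e.g.
    CARD-bearing initiator caspases or "classical" calpains with both
    peptidase domains plus an EF-hand.
    """
    if category_map is None:
        category_map = load_default_category_rules()
    if not category_map:
        raise ValueError("category_map must not be empty")

    entries: list[CatalogueEntry] = []
    order: list[str] = []
    for taxon, hits in domain_hits_by_taxon.items():
        if taxon not in order:
            order.append(taxon)
        by_protein: dict[str, set[str]] = {}
        for h in hits:
            if h.e_value <= evalue_max:
                by_protein.setdefault(h.protein_id, set()).update(
                    {h.domain_name, h.domain_acc}
                )
        for protein_id in sorted(by_protein):
            domains = by_protein[protein_id]
            for cat in sorted(category_map):
                rule = category_map[cat]
                if rule.required and rule.required <= domains:
                    flags = tuple(
                        sorted(f for f, req in rule.flags.items() if req <= domains)
                    )
                    entries.append(
                        CatalogueEntry(taxon, rule.category, protein_id, "intact",
                                       None, flags)
                    )
    return ActorCatalogue(entries, list(taxon_order) if taxon_order else order)


@dataclass
class PresenceMatrix:
    taxa: list[str]
    categories: list[str]
    cells: pd.DataFrame  # bool, taxa x categories
    counts: pd.DataFrame  # int, intact entries
    pseudo_counts: pd.DataFrame  # int, pseudogene entries (side channel)
    retention: pd.Series  # per-taxon count of present categories

    def to_tsv(self, dest_prefix: Union[str, Path]) -> None:
        prefix = Path(dest_prefix)
        self.cells.astype(int).to_csv(f"{prefix}.presence.tsv", sep="\t")
        self.counts.to_csv(f"{prefix}.counts.tsv", sep="\t")


def build_matrix(
    catalogue: ActorCatalogue,
    taxa: Optional[Sequence[str]] = None,
    categories: Sequence[str] = CATEGORIES,
    count_pseudogenes: bool = False,
) -> PresenceMatrix:
    """Boolean presence matrix with per-cell intact counts and retention.

    A cell is present when it holds >= 1 intact entry (pseudogenes count
    only with ``count_pseudogenes=True``; absent markers never count).
    ``taxa`` subsets/orders the rows; default is the catalogue's own order.
    """
    if not catalogue.entries:
        raise ValueError("catalogue is empty")
    taxa = list(taxa) if taxa is not None else catalogue.taxa
    categories = list(categories)
    counts = pd.DataFrame(0, index=taxa, columns=categories, dtype=int)
    pseudo = pd.DataFrame(0, index=taxa, columns=categories, dtype=int)
    for e in catalogue.entries:
        if e.taxon not in counts.index or e.category not in counts.columns:
            continue
        if e.status == "intact":
            counts.loc[e.taxon, e.category] += 1
        elif e.status == "pseudogene":
            pseudo.loc[e.taxon, e.category] += 1
    present_counts = counts + pseudo if count_pseudogenes else counts
    cells = present_counts >= 1
    retention = cells.sum(axis=1)
    return PresenceMatrix(taxa, categories, cells, counts, pseudo, retention)


@dataclass
class GradientReport:
    taxa: list[str]
    retention: list[int]
    non_increasing: bool
    # categories newly lost at each step of the gradient (relative to the
    # previous taxon), aligned with taxa[1:]
    losses_per_step: list[list[str]]

    def to_tsv(self, dest: Union[str, Path]) -> None:
        with open(dest, "w") as fh:
            fh.write("taxon\tretention\tnewly_lost\n")
            for i, (t, r) in enumerate(zip(self.taxa, self.retention)):
                lost = "" if i == 0 else ",".join(self.losses_per_step[i - 1])
                fh.write(f"{t}\t{r}\t{lost}\n")


def loss_gradient(matrix: PresenceMatrix) -> GradientReport:
    """Retention counts along the matrix's taxon order plus a monotone verdict."""
    retention = [int(matrix.retention[t]) for t in matrix.taxa]
    non_increasing = all(a >= b for a, b in zip(retention, retention[1:]))
    losses: list[list[str]] = []
    for prev, cur in zip(matrix.taxa, matrix.taxa[1:]):
        lost = [
            c
            for c in matrix.categories
            if bool(matrix.cells.loc[prev, c]) and not bool(matrix.cells.loc[cur, c])
        ]
        losses.append(lost)
    return GradientReport(list(matrix.taxa), retention, non_increasing, losses)


def render_circles(matrix: PresenceMatrix) -> str:
    """Plain-text rendering: filled circles for present cells, empty otherwise."""
    width = max(len(t) for t in matrix.taxa)
    lines = [" " * width + "  " + " ".join(c[:4].ljust(4) for c in matrix.categories)]
    for t in matrix.taxa:
        row = " ".join(
            ("●".ljust(4) if bool(matrix.cells.loc[t, c]) else "○".ljust(4))
            for c in matrix.categories
        )
        lines.append(t.ljust(width) + "  " + row)
    return "\n".join(lines)
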