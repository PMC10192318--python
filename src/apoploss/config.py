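"""Declarative run configuration: validation with aggregated errors."""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .decontam import ClassifierParams, GcPartitionParams, HostFilterParams
from .seqio_gc import OrfParams

__all__ = ["RunConfig", "ConfigError", "validate_config"]


class ConfigError(ValueError):
    """Aggregated configuration problems, one per line."""


_SCHEMA: dict[str, dict[str, type | tuple[type, ...]]] = {
    "inputs": {
        "assembly": str,
        "target_hits": str,
        "contam_hits": str,
        "host_hits": str,
        "catalogue": str,
        "alignment": str,
    },
    "host_filter": {"identity": (int, float), "evalue": (int, float)},
    "classifier": {
        "evalue_fold": (int, float),
        "bitscore_fold": (int, float),
        "evalue_floor": (int, float),
    },
    "gc": {"cutoff": (int, float, str)},
    "orfs": {"min_len_aa": int, "require_start_codon": bool},
    "matrix": {"count_pseudogenes": bool, "taxon_order": list},
    "pseudoscan": {
        "candidate_id": str,
        "domain_span": list,
        "conserved_span": list,
        "gap_fraction": (int, float),
    },
    "output": {"dir": str},
    "run": {"seed": int},
}

_REQUIRED = {
    "inputs": ["assembly", "target_hits", "contam_hits"],
    "output": ["dir"],
}

_PATH_KEYS = {"assembly", "target_hits", "contam_hits", "host_hits", "catalogue",
              "alignment"}


@dataclass
class RunConfig:
    assembly: Path
    target_hits: Path
    contam_hits: Path
    out_dir: Path
    host_hits: Optional[Path] = None
    catalogue: Optional[Path] = None
    alignment: Optional[Path] = None
    host_params: HostFilterParams = field(default_factory=HostFilterParams)
    classifier_params: ClassifierParams = field(default_factory=ClassifierParams)
    gc_params: GcPartitionParams = field(default_factory=GcPartitionParams)
    orf_params: OrfParams = field(default_factory=OrfParams)
    count_pseudogenes: bool = False
    taxon_order: Optional[list[str]] = None
    pseudoscan_candidate: Optional[str] = None
    pseudoscan_domain_span: Optional[tuple[int, int]] = None
    pseudoscan_conserved_span: Optional[tuple[int, int]] = None
    pseudoscan_gap_fraction: float = 0.8
    seed: int = 0


def _suggest(key: str, candidates: list[str]) -> str:
    close = difflib.get_close_matches(key, candidates, n=1)
    return f" (did you mean {close[0]!r}?)" if close else ""


def validate_config(path: Union[str, Path]) -> RunConfig:
    """Parse and validate a YAML run config; all problems reported at once."""
    path = Path(path)
    errors: list[str] = []
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not parseable as YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")

    for section, content in raw.items():
        if section not in _SCHEMA:
            errors.append(f"unknown section {section!r}{_suggest(section, list(_SCHEMA))}")
            continue
        if content is None:
            continue
        if not isinstance(content, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key, value in content.items():
            if key not in _SCHEMA[section]:
                errors.append(
                    f"unknown key {section}.{key}"
                    f"{_suggest(key, list(_SCHEMA[section]))}"
                )
                continue
            expected = _SCHEMA[section][key]
            if not isinstance(value, expected):
                errors.append(
                    f"{section}.{key}: expected {expected}, got {type(value).__name__}"
                )

    def get(section: str, key: str, default: Any = None) -> Any:
        return (raw.get(section) or {}).get(key, default)

    for section, keys in _REQUIRED.items():
        for key in keys:
            if get(section, key) is None:
                errors.append(f"missing required key {section}.{key}")

    for key in _PATH_KEYS:
        value = get("inputs", key)
        if isinstance(value, str) and not Path(value).exists():
            errors.append(f"inputs.{key}: path does not exist: {value}")

    if errors:
        raise ConfigError(
            f"{path}: {len(errors)} configuration problem(s):\n  "
            + "\n  ".join(errors)
        )

    def span(key: str) -> Optional[tuple[int, int]]:
        v = get("pseudoscan", key)
        if v is None:
            return None
        return (int(v[0]), int(v[1]))

    gc_cutoff = get("gc", "cutoff", "auto")
    return RunConfig(
        assembly=Path(get("inputs", "assembly")),
        target_hits=Path(get("inputs", "target_hits")),
        contam_hits=Path(get("inputs", "contam_hits")),
        out_dir=Path(get("output", "dir")),
        host_hits=Path(get("inputs", "host_hits")) if get("inputs", "host_hits") else None,
        catalogue=Path(get("inputs", "catalogue")) if get("inputs", "catalogue") else None,
        alignment=Path(get("inputs", "alignment")) if get("inputs", "alignment") else None,
        host_params=HostFilterParams(
            identity_threshold=float(get("host_filter", "identity", 85.0)),
            evalue_threshold=float(get("host_filter", "evalue", 1e-75)),
        ),
        classifier_params=ClassifierParams(
            evalue_fold=float(get("classifier", "evalue_fold", 100.0)),
            bitscore_fold=float(get("classifier", "bitscore_fold", 1.5)),
            evalue_floor=float(get("classifier", "evalue_floor", 1e-180)),
        ),
        gc_params=GcPartitionParams(
            cutoff=gc_cutoff if gc_cutoff == "auto" else float(gc_cutoff)
        ),
        orf_params=OrfParams(
            min_len_aa=int(get("orfs", "min_len_aa", 70)),
            require_start_codon=bool(get("orfs", "require_start_codon", False)),
        ),
        count_pseudogenes=bool(get("matrix", "count_pseudogenes", False)),
        taxon_order=get("matrix", "taxon_order"),
        pseudoscan_candidate=get("pseudoscan", "candidate_id"),
        pseudoscan_domain_span=span("domain_span"),
        pseudoscan_conserved_span=span("conserved_span"),
        pseudoscan_gap_fraction=float(get("pseudoscan", "gap_fraction", 0.8)),
        seed=int(get("run", "seed", 0)),
    )
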