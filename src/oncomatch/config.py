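"""Run configuration: thresholds, filter selection, tier map.

Configuration is a flat ``key = value`` text file (``#`` comments allowed).
Recognised keys::

    copy_deletion_threshold       = -2
    copy_amplification_threshold  = 2
    expression_z_low              = -2
    expression_z_high             = 2
    expression_percentile_low     = 2.5
    expression_percentile_high    = 97.5
    synonymous_classes            = silent,synonymous
    filters                      = AMP_Tier_I,Diagnosis_Match
    tier_one.<source>            = comma,separated,levels

Unset keys keep their defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Tuple, Union

from .errors import ConfigurationError
from .matching import ALL_FILTERS, DEFAULT_TIER_I_MAP
from .variants import DEFAULT_SYNONYMOUS_CLASSES


@dataclass(frozen=True)
class Config:
    copy_deletion_threshold: float = -2.0
    copy_amplification_threshold: float = 2.0
    expression_z_low: float = -2.0
    expression_z_high: float = 2.0
    expression_percentile_low: float = 2.5
    expression_percentile_high: float = 97.5
    synonymous_classes: FrozenSet[str] = DEFAULT_SYNONYMOUS_CLASSES
    filters: Tuple[str, ...] = ()
    tier_one_map: Dict[str, FrozenSet[str]] = field(
        default_factory=lambda: dict(DEFAULT_TIER_I_MAP)
    )


_FLOAT_KEYS = {
    "copy_deletion_threshold",
    "copy_amplification_threshold",
    "expression_z_low",
    "expression_z_high",
    "expression_percentile_low",
    "expression_percentile_high",
}


def load_config(path: Union[str, Path]) -> Config:
    config = Config()
    tier_map = dict(config.tier_one_map)
    updates: dict = {}
    for number, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"config line {number}: expected key = value")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in _FLOAT_KEYS:
            try:
                updates[key] = float(value)
            except ValueError:
                raise ConfigurationError(
                    f"config line {number}: {key} must be numeric"
                ) from None
        elif key == "synonymous_classes":
            updates["synonymous_classes"] = frozenset(
                item.strip().lower() for item in value.split(",") if item.strip()
            )
        elif key == "filters":
            names = tuple(item.strip() for item in value.split(",") if item.strip())
            for name in names:
                if name not in ALL_FILTERS:
                    raise ConfigurationError(
                        f"config line {number}: unknown filter {name!r}"
                    )
            updates["filters"] = names
        elif key.startswith("tier_one."):
            source = key[len("tier_one."):].strip().lower()
            tier_map[source] = frozenset(
                item.strip().lower() for item in value.split(",") if item.strip()
            )
        else:
            raise ConfigurationError(f"config line {number}: unknown key {key!r}")
    updates["tier_one_map"] = tier_map
    return replace(config, **updates)
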