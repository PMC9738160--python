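"""Run configuration: YAML-backed, strictly validated settings for the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Tuple, Union

import yaml

from .fragments import FORCE_LADDER_PN, PACKAGED_FRAGMENTS, FragmentSpec
from .simulate import BdParams

__all__ = ["RunConfig", "load_config"]

_FRAGMENT_KEYS = {"name", "n_residues", "l_max", "rise_per_residue", "sequence"}
_BD_KEYS = {"n_steps", "save_stride", "timestep", "friction", "bond_stiffness", "seed"}


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for a simulate/analyze/fit run."""

    fragments: Tuple[FragmentSpec, ...]
    temperature: float = 298.0
    link_length: float = 8.1
    force_ladder: Tuple[float, ...] = FORCE_LADDER_PN
    zero_force_replicates: int = 3
    bd: BdParams = field(default_factory=BdParams)
    seed: int = 0
    output_dir: Path = Path("elastochain_out")

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.link_length <= 0:
            raise ValueError("link_length must be positive")
        if self.zero_force_replicates < 1:
            raise ValueError("zero_force_replicates must be >= 1")
        if not self.fragments:
            raise ValueError("at least one fragment is required")


def _parse_fragment(entry: Union[str, dict]) -> FragmentSpec:
    if isinstance(entry, str):
        try:
            return PACKAGED_FRAGMENTS[entry]
        except KeyError:
            raise ValueError(
                f"unknown packaged fragment {entry!r}; available: "
                f"{sorted(PACKAGED_FRAGMENTS)}"
            ) from None
    unknown = set(entry) - _FRAGMENT_KEYS
    if unknown:
        raise ValueError(f"unknown fragment keys {sorted(unknown)}; allowed: {sorted(_FRAGMENT_KEYS)}")
    return FragmentSpec(**entry)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration.

    Top-level keys: ``fragments`` (list of packaged names or mappings),
    ``temperature``, ``link_length``, ``force_ladder``,
    ``zero_force_replicates``, ``bd`` (mapping), ``seed``, ``output_dir``.
    Unknown keys anywhere are rejected.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    allowed = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}; allowed: {sorted(allowed)}")
    kwargs: dict = {}
    if "fragments" in raw:
        kwargs["fragments"] = tuple(_parse_fragment(e) for e in raw["fragments"])
    else:
        kwargs["fragments"] = tuple(PACKAGED_FRAGMENTS.values())
    if "bd" in raw:
        bd_raw = raw["bd"] or {}
        unknown_bd = set(bd_raw) - _BD_KEYS
        if unknown_bd:
            raise ValueError(f"{path}: unknown bd keys {sorted(unknown_bd)}; allowed: {sorted(_BD_KEYS)}")
        kwargs["bd"] = BdParams(**bd_raw)
    for key in ("temperature", "link_length", "zero_force_replicates", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "force_ladder" in raw:
        kwargs["force_ladder"] = tuple(float(f) for f in raw["force_ladder"])
    if "output_dir" in raw:
        kwargs["output_dir"] = Path(raw["output_dir"])
    return RunConfig(**kwargs)
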