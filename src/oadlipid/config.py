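"""Tool configuration: tolerances, thresholds and enumeration constraints.

Defaults follow the operating point of the annotation workflow: 15 ppm
fragment mass accuracy, a minimum diagnostic-ion intensity of 0.01 % of the
base peak (0.005 % for the sphingoid Δ4 bond), and data integration windows
of 0.01 Da / 0.15 min between the CID-level table and the OAD spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class MatchingConfig:
    tol_ppm: float = 15.0
    #: minimum diagnostic-ion intensity, as a fraction of the base peak
    min_rel_intensity: float = 0.0001  # 0.01 %
    min_rel_intensity_delta4: float = 0.00005  # 0.005 %
    tie_epsilon: float = 1e-6
    #: require the diagnostic pair for every double bond (relaxation knob)
    require_pair_all_bonds: bool = True


@dataclass(frozen=True)
class EnumerationConfig:
    min_pos: int = 3  # lowest allowed n-position
    max_offset: int = 2  # highest position is n-(C - max_offset)
    min_gap: int = 2  # no conjugated double bonds


@dataclass(frozen=True)
class JoinConfig:
    mz_tol_da: float = 0.01
    rt_tol_min: float = 0.15


@dataclass(frozen=True)
class Config:
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    enumeration: EnumerationConfig = field(default_factory=EnumerationConfig)
    join: JoinConfig = field(default_factory=JoinConfig)
    #: demote "PC P-" annotations to "PC O-" on output (confidence policy)
    demote_plasmalogen_pc: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "Config":
        cfg = cls()
        if "matching" in raw:
            cfg = replace(cfg, matching=replace(cfg.matching, **raw["matching"]))
        if "enumeration" in raw:
            cfg = replace(
                cfg, enumeration=replace(cfg.enumeration, **raw["enumeration"])
            )
        if "join" in raw:
            cfg = replace(cfg, join=replace(cfg.join, **raw["join"]))
        if "demote_plasmalogen_pc" in raw:
            cfg = replace(cfg, demote_plasmalogen_pc=bool(raw["demote_plasmalogen_pc"]))
        return cfg
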