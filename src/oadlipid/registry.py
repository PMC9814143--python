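"""Subclass registry: data-driven vocabulary of lipid subclasses.

Each subclass carries its expected chain count, backbone formula, default
chain linkages and head-group product ions. The registry is loaded from a
packaged YAML file so new subclasses can be added without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .chem import ElementalFormula

VALID_LINKAGES = frozenset(
    {"ester", "ether", "vinyl_ether", "amide", "amide_hydroxy", "sphingoid"}
)


@dataclass(frozen=True)
class HeadIon:
    """A subclass-specific product ion: either a charged fragment formula or a
    neutral loss subtracted from the precursor."""

    kind: str  # "fragment" | "neutral_loss"
    formula: ElementalFormula
    rel_intensity: float
    label: str


@dataclass(frozen=True)
class SubclassInfo:
    name: str
    n_chains: int
    backbone: ElementalFormula
    linkages: tuple[str, ...]
    default_adduct: str
    head_ions: tuple[HeadIon, ...]


class SubclassRegistry:
    """Lookup of :class:`SubclassInfo` by subclass key, with aliases."""

    def __init__(self, subclasses: dict[str, SubclassInfo], aliases: dict[str, str]):
        self._subclasses = subclasses
        self._aliases = aliases

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SubclassRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def default(cls) -> "SubclassRegistry":
        ref = resources.files("oadlipid.data").joinpath("subclasses.yaml")
        raw = yaml.safe_load(ref.read_text())
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "SubclassRegistry":
        subclasses = {}
        for name, entry in raw["subclasses"].items():
            linkages = tuple(entry["linkages"])
            bad = set(linkages) - VALID_LINKAGES
            if bad:
                raise ValueError(f"subclass {name}: unknown linkages {sorted(bad)}")
            if len(linkages) != int(entry["chains"]):
                raise ValueError(f"subclass {name}: linkage count != chain count")
            head_ions = tuple(
                HeadIon(
                    kind=h["kind"],
                    formula=ElementalFormula.parse(h["formula"]),
                    rel_intensity=float(h["rel_intensity"]),
                    label=h["label"],
                )
                for h in entry.get("head_ions", [])
            )
            subclasses[name] = SubclassInfo(
                name=name,
                n_chains=int(entry["chains"]),
                backbone=ElementalFormula.parse(entry.get("backbone") or ""),
                linkages=linkages,
                default_adduct=entry["default_adduct"],
                head_ions=head_ions,
            )
        return cls(subclasses, dict(raw.get("aliases", {})))

    def resolve(self, name: str) -> str:
        return self._aliases.get(name, name)

    def __contains__(self, name: str) -> bool:
        return self.resolve(name) in self._subclasses

    def get(self, name: str) -> SubclassInfo:
        key = self.resolve(name)
        if key not in self._subclasses:
            raise KeyError(
                f"unknown lipid subclass {name!r}; known: {sorted(self._subclasses)}"
            )
        return self._subclasses[key]

    def names(self) -> list[str]:
        return sorted(self._subclasses)


_DEFAULT: SubclassRegistry | None = None


def default_registry() -> SubclassRegistry:
    """The packaged registry, loaded once per process."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = SubclassRegistry.default()
    return _DEFAULT
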