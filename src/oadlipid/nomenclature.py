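"""Shorthand lipid name parsing and serialization.

Names follow LIPID MAPS-style shorthand as emitted by untargeted lipidomics
software, e.g. ``PC 18:1_22:6``, ``PE P-18:0/18:1(n-9)`` or
``SM 18:1(Δ4);O2/18:1(n-9)``. Double-bond positions are accepted in both the
n-description (methyl-end counting, ``n-9``) and the Δ-description
(carboxyl-end counting, ``Δ9`` or CID-style ``9Z``); internally every position
is stored as an n-position (Δ = carbons − n). On output, acyl chains use the
n-description and sphingoid bases the Δ-description.

``_`` between chains means the sn-assignment is unknown; ``/`` means it is
known. An ``&`` inside a position list (``38:5(n-3&6)``) denotes an ambiguous
annotation whose lowest double-bond position could not be resolved between the
listed alternatives.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .chem import ElementalFormula, adduct_mz, monoisotopic_mass
from .registry import SubclassRegistry, default_registry

_LINKAGE_PREFIX = {"O": "ether", "P": "vinyl_ether", "N": "amide"}
_PREFIX_FOR_LINKAGE = {"ether": "O-", "vinyl_ether": "P-"}

_CHAIN_RE = re.compile(r"^(?:(?P<link>[OPN])-)?(?P<c>\d+):(?P<d>\d+)(?P<rest>.*)$")


class LipidNameError(ValueError):
    """Raised when a lipid name cannot be parsed."""


@dataclass(frozen=True)
class AcylChain:
    """One chain (acyl, alkyl, alkenyl or sphingoid base) of a lipid.

    ``positions`` are n-positions (methyl-end counting), ascending; empty means
    unresolved. ``first_alternatives`` carries the ``&`` ambiguity notation:
    the alternatives for the lowest position when a unique assignment could
    not be made (positions is then empty). ``geometry`` optionally tags each
    position with E/Z.
    """

    carbons: int
    double_bonds: int
    hydroxyls: int = 0
    linkage: str = "ester"
    positions: tuple[int, ...] = ()
    geometry: tuple[str, ...] = ()
    first_alternatives: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise LipidNameError(f"chain needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0 or self.hydroxyls < 0:
            raise LipidNameError("negative double bond or hydroxyl count")
        if self.positions:
            validate_positions(self.carbons, self.double_bonds, self.positions)
        if self.geometry and len(self.geometry) != len(self.positions):
            raise LipidNameError("geometry tags must align with positions")

    @property
    def resolved(self) -> bool:
        return self.double_bonds == 0 or len(self.positions) == self.double_bonds

    def with_positions(self, positions: tuple[int, ...]) -> "AcylChain":
        return replace(self, positions=tuple(positions), geometry=(),
                       first_alternatives=())


def validate_positions(
    carbons: int, double_bonds: int, positions: tuple[int, ...], min_pos: int = 3,
    max_offset: int = 2, min_gap: int = 2,
) -> None:
    """Check the structural constraints on an n-position assignment."""
    if len(positions) != double_bonds:
        raise LipidNameError(
            f"{len(positions)} positions given for {double_bonds} double bonds"
        )
    prev = None
    for p in positions:
        if p < min_pos or p > carbons - max_offset:
            raise LipidNameError(
                f"position n-{p} outside [n-{min_pos}, n-{carbons - max_offset}] "
                f"for a C{carbons} chain"
            )
        if prev is not None and p - prev < min_gap:
            raise LipidNameError(
                f"positions must be ascending with gap >= {min_gap}: "
                f"{positions}"
            )
        prev = p


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid with subclass, chains and adduct."""

    subclass: str
    chains: tuple[AcylChain, ...]
    chain_order_known: bool = False
    adduct: str | None = None

    @property
    def resolved(self) -> bool:
        return all(ch.resolved for ch in self.chains)

    @property
    def n_unsaturated_chains(self) -> int:
        return sum(1 for ch in self.chains if ch.double_bonds > 0)

    def with_chain(self, index: int, chain: AcylChain) -> "LipidSpecies":
        chains = list(self.chains)
        chains[index] = chain
        return replace(self, chains=tuple(chains))


def n_to_delta(carbons: int, n_pos: int) -> int:
    """Convert an n-position to a Δ-position (Δ = carbons − n)."""
    if not 1 <= n_pos < carbons:
        raise ValueError(f"n-position {n_pos} out of range for C{carbons}")
    return carbons - n_pos


def delta_to_n(carbons: int, delta_pos: int) -> int:
    """Convert a Δ-position to an n-position (inverse of :func:`n_to_delta`)."""
    if not 1 <= delta_pos < carbons:
        raise ValueError(f"Δ-position {delta_pos} out of range for C{carbons}")
    return carbons - delta_pos


def _split_chains(text: str) -> tuple[list[str], bool]:
    """Split on top-level ``/`` or ``_``; returns tokens and order-known flag."""
    tokens, depth, start = [], 0, 0
    seps = set()
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch in "/_" and depth == 0:
            tokens.append(text[start:i])
            seps.add(ch)
            start = i + 1
    tokens.append(text[start:])
    order_known = "_" not in seps
    return [t.strip() for t in tokens if t.strip()], order_known


def _parse_position_block(block: str, carbons: int) -> tuple[
    tuple[int, ...], tuple[str, ...], tuple[int, ...]
]:
    """Parse the inside of a position parenthesis.

    Returns (n-positions ascending, geometry tags, first_alternatives).
    Accepted styles: ``n-9``, ``n-3,6,9``, ``n-3&6``, ``Δ4,8``, ``d4``,
    ``9Z,12Z`` (Δ-counting with stereo tags).
    """
    block = block.replace(" ", "")
    if block.startswith("n-"):
        mode, body = "n", block[2:]
    elif block.startswith("Δ") or block.startswith("d"):
        mode, body = "delta", block[1:]
    elif block and (block[0].isdigit()):
        mode, body = "delta", block
    else:
        raise LipidNameError(f"cannot parse position block {block!r}")

    items = body.split(",")
    if "&" in body:
        if len(items) != 1:
            raise LipidNameError(
                f"'&' ambiguity must be the only position item: {block!r}"
            )
        alts = []
        for part in items[0].split("&"):
            if not part.isdigit():
                raise LipidNameError(f"bad ambiguous position {items[0]!r}")
            v = int(part)
            alts.append(v if mode == "n" else delta_to_n(carbons, v))
        return (), (), tuple(sorted(alts))

    positions, geometry = [], []
    for item in items:
        m = re.match(r"^[Δd]?(\d+)([EZ]?)$", item)
        if not m:
            raise LipidNameError(f"bad position item {item!r} in {block!r}")
        v = int(m.group(1))
        positions.append(v if mode == "n" else delta_to_n(carbons, v))
        geometry.append(m.group(2))
    order = sorted(range(len(positions)), key=lambda i: positions[i])
    positions = tuple(positions[i] for i in order)
    geometry = tuple(geometry[i] for i in order)
    if not any(geometry):
        geometry = ()
    return positions, geometry, ()


def parse_chain(token: str, linkage: str | None = None) -> AcylChain:
    """Parse one chain token, e.g. ``P-18:0``, ``18:1(n-9)``, ``18:1(Δ4);O2``."""
    m = _CHAIN_RE.match(token.strip())
    if not m:
        raise LipidNameError(f"malformed chain token {token!r}")
    carbons, dbs = int(m.group("c")), int(m.group("d"))
    if m.group("link"):
        linkage = _LINKAGE_PREFIX[m.group("link")]
    elif linkage is None:
        linkage = "ester"
    rest = m.group("rest")
    hydroxyls = 0
    positions: tuple[int, ...] = ()
    geometry: tuple[str, ...] = ()
    alts: tuple[int, ...] = ()
    offset = m.end("d")
    while rest:
        if rest.startswith("("):
            depth, j = 0, 0
            for j, ch in enumerate(rest):
                depth += ch == "("
                depth -= ch == ")"
                if depth == 0:
                    break
            if depth != 0:
                raise LipidNameError(f"unbalanced parenthesis in {token!r}")
            positions, geometry, alts = _parse_position_block(rest[1:j], carbons)
            rest = rest[j + 1:]
        elif rest.startswith(";O"):
            m2 = re.match(r"^;O(\d*)", rest)
            hydroxyls = int(m2.group(1)) if m2.group(1) else 1
            rest = rest[m2.end():]
        else:
            raise LipidNameError(
                f"cannot parse chain token {token!r} near offset {offset}"
            )
    if positions and len(positions) != dbs:
        raise LipidNameError(
            f"{token!r}: {len(positions)} positions for {dbs} double bonds"
        )
    return AcylChain(
        carbons=carbons, double_bonds=dbs, hydroxyls=hydroxyls, linkage=linkage,
        positions=positions, geometry=geometry, first_alternatives=alts,
    )


def parse_lipid_name(
    text: str, registry: SubclassRegistry | None = None, adduct: str | None = None,
) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`."""
    registry = registry or default_registry()
    text = text.strip()
    if not text:
        raise LipidNameError("empty lipid name")

    if text.startswith("PE-N(FA"):
        depth, j = 0, 0
        for j, ch in enumerate(text):
            depth += ch == "("
            depth -= ch == ")"
            if depth == 0 and ch == ")":
                break
        inner = text[len("PE-N(FA"): j].strip()
        amide = parse_chain(inner, linkage="amide")
        subclass = "PE-N(FA)"
        chain_text = text[j + 1:].strip()
        tokens, order_known = _split_chains(chain_text)
        info = registry.get(subclass)
        if len(tokens) != info.n_chains - 1:
            raise LipidNameError(
                f"{subclass} expects {info.n_chains - 1} glycerol chains, "
                f"got {len(tokens)} in {text!r}"
            )
        chains = [amide] + [
            parse_chain(tok, linkage=info.linkages[i + 1])
            for i, tok in enumerate(tokens)
        ]
        return LipidSpecies(
            subclass=subclass, chains=tuple(chains), chain_order_known=order_known,
            adduct=adduct or info.default_adduct,
        )

    head, _, chain_text = text.partition(" ")
    if head not in registry:
        raise LipidNameError(f"unknown subclass token {head!r} in {text!r}")
    subclass = registry.resolve(head)
    info = registry.get(subclass)
    tokens, order_known = _split_chains(chain_text)
    if len(tokens) != info.n_chains:
        raise LipidNameError(
            f"{subclass} expects {info.n_chains} chains, got {len(tokens)} "
            f"in {text!r}"
        )
    chains = tuple(
        parse_chain(tok, linkage=info.linkages[i]) for i, tok in enumerate(tokens)
    )
    return LipidSpecies(
        subclass=subclass, chains=chains, chain_order_known=order_known,
        adduct=adduct or info.default_adduct,
    )


def _format_positions(chain: AcylChain) -> str:
    if chain.first_alternatives:
        if chain.linkage == "sphingoid":
            alts = sorted(n_to_delta(chain.carbons, p)
                          for p in chain.first_alternatives)
            return "(Δ" + "&".join(str(a) for a in alts) + ")"
        return "(n-" + "&".join(str(a) for a in chain.first_alternatives) + ")"
    if not chain.positions:
        return ""
    geometry = chain.geometry or ("",) * len(chain.positions)
    if chain.linkage == "sphingoid":
        pairs = sorted(
            (n_to_delta(chain.carbons, p), g)
            for p, g in zip(chain.positions, geometry)
        )
        return "(Δ" + ",".join(f"{d}{g}" for d, g in pairs) + ")"
    return "(n-" + ",".join(
        f"{p}{g}" for p, g in zip(chain.positions, geometry)
    ) + ")"


def serialize_chain(chain: AcylChain) -> str:
    prefix = _PREFIX_FOR_LINKAGE.get(chain.linkage, "")
    core = f"{prefix}{chain.carbons}:{chain.double_bonds}"
    core += _format_positions(chain)
    if chain.hydroxyls:
        core += ";O" if chain.hydroxyls == 1 else f";O{chain.hydroxyls}"
    return core


def serialize_lipid_name(species: LipidSpecies) -> str:
    """Serialize a species back to shorthand text (inverse of parsing)."""
    sep = "/" if species.chain_order_known else "_"
    if species.subclass == "PE-N(FA)":
        amide, rest = species.chains[0], species.chains[1:]
        return (
            f"PE-N(FA {serialize_chain(amide)}) "
            + sep.join(serialize_chain(ch) for ch in rest)
        )
    return f"{species.subclass} " + sep.join(
        serialize_chain(ch) for ch in species.chains
    )


def strip_positions(species: LipidSpecies) -> LipidSpecies:
    """Drop all double-bond position annotations (molecular species level)."""
    chains = tuple(
        replace(ch, positions=(), geometry=(), first_alternatives=())
        for ch in species.chains
    )
    return replace(species, chains=chains)


def canonical_name(species: LipidSpecies) -> str:
    """Serialization with a deterministic chain order for comparisons.

    When the sn-assignment is unknown (``_``), chains that are interchangeable
    are sorted by (linkage, carbons, double bonds, hydroxyls, positions) so
    that two equivalent annotations compare string-equal.
    """
    if species.chain_order_known:
        return serialize_lipid_name(species)
    chains = tuple(sorted(
        species.chains,
        key=lambda ch: (ch.linkage, ch.carbons, ch.double_bonds, ch.hydroxyls,
                        ch.positions, ch.first_alternatives),
    ))
    return serialize_lipid_name(replace(species, chains=chains))


# ---------------------------------------------------------------------------
# formula assembly

def _chain_contribution(chain: AcylChain) -> dict[str, int]:
    c, d, h = chain.carbons, chain.double_bonds, chain.hydroxyls
    if chain.linkage in ("ester", "amide"):
        return {"C": c, "H": 2 * c - 2 * d - 2, "O": 1 + h}
    if chain.linkage == "amide_hydroxy":  # omega-esterified hydroxy amide chain
        return {"C": c, "H": 2 * c - 2 * d - 2, "O": 2 + h}
    if chain.linkage == "ether":
        return {"C": c, "H": 2 * c - 2 * d, "O": h}
    if chain.linkage == "vinyl_ether":  # P-18:0 carries an implicit Δ1' C=C
        return {"C": c, "H": 2 * c - 2 * d - 2, "O": h}
    if chain.linkage == "sphingoid":
        return {"C": c, "H": 2 * c + 3 - 2 * d, "N": 1, "O": h}
    raise LipidNameError(f"unknown linkage {chain.linkage!r}")


def species_formula(
    species: LipidSpecies, registry: SubclassRegistry | None = None
) -> ElementalFormula:
    """Neutral elemental formula of the intact lipid."""
    registry = registry or default_registry()
    info = registry.get(species.subclass)
    if len(species.chains) != info.n_chains:
        raise LipidNameError(
            f"{species.subclass} expects {info.n_chains} chains, "
            f"got {len(species.chains)}"
        )
    counts = dict(info.backbone.counts)
    for chain in species.chains:
        for sym, n in _chain_contribution(chain).items():
            counts[sym] = counts.get(sym, 0) + n
    return ElementalFormula(counts, 0)


def precursor_mz(
    species: LipidSpecies, registry: SubclassRegistry | None = None
) -> float:
    """Theoretical precursor m/z of the species under its adduct."""
    registry = registry or default_registry()
    adduct = species.adduct or registry.get(species.subclass).default_adduct
    return adduct_mz(monoisotopic_mass(species_formula(species, registry)), adduct)
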