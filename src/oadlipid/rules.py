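"""In-silico OAD-MS/MS spectrum generation (algorithm step 2).

Oxygen attachment dissociation attaches O/OH radicals to a C=C bond and
cleaves a nearby C–C bond, producing fragment ions whose neutral losses pin
the double-bond position. For a double bond at n-x, cleavage occurs at one of
three bonds: n-(x−1)_n-x (``bond_site`` −1), n-x_n-(x+1) (0, the C=C itself)
or n-(x+1)_n-(x+2) (+1). The lost fragment spans the methyl terminus through
the cleaved bond; its composition is C_k H_(2k+1−2u+δH), where k is the
carbon count of the lost side and u the number of double bonds it fully
contains. When the attached oxygen stays on the charged fragment
(``oxygen_delta`` = 1), the net neutral loss is lighter by one O.

The two diagnostic "fragment pair" ions per double bond are the O-retaining
bond −1 cleavage (for 18:1(n-9): NL C8H17−O = 97.1381 Da) and the
hydrocarbon-radical bond +1 cleavage (NL C10H19 = 139.1487 Da). Dedicated
low-abundance analogs cover the sphingoid Δ4 bond, and configured
vinyl-ether rows cover the implicit Δ1' bond of plasmalogens.

Rule rows are packaged data (``data/oad_rules.tsv``); relative intensities
are heuristic defaults on a base-peak = 1 scale.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .chem import (
    ELEMENT_MASSES,
    ElementalFormula,
    FormulaDelta,
    monoisotopic_mass,
)
from .nomenclature import AcylChain, LipidSpecies, precursor_mz, serialize_lipid_name
from .registry import SubclassRegistry, default_registry

_WATER_MASS = 2 * ELEMENT_MASSES["H"] + ELEMENT_MASSES["O"]

#: m/z window inside which colliding theoretical peaks are merged (max kept)
MERGE_TOL_DA = 1e-4


class RuleError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentRule:
    """One OAD ion type relative to a double bond at n-x."""

    rule_id: str
    bond_site: int  # -1, 0, +1 (see module docstring)
    hydrogen_delta: int
    oxygen_delta: int  # 1 if the attached oxygen is retained on the ion
    water_loss: bool
    rel_intensity: float
    diagnostic: bool
    applicability: str  # "acyl" | "sphingoid_delta4" | "vinyl_ether"

    def __post_init__(self) -> None:
        if self.bond_site not in (-1, 0, 1):
            raise RuleError(f"{self.rule_id}: bond_site must be -1/0/+1")
        if self.oxygen_delta not in (0, 1):
            raise RuleError(f"{self.rule_id}: oxygen_delta must be 0 or 1")
        if not 0 < self.rel_intensity <= 1:
            raise RuleError(f"{self.rule_id}: rel_intensity must be in (0, 1]")


@dataclass(frozen=True)
class TheoreticalPeak:
    mz: float
    rel_intensity: float
    annotation: str  # "OAD03@chain0:n-9", "head:phosphocholine", "precursor"


@dataclass(frozen=True)
class TheoreticalSpectrum:
    species_name: str
    precursor_mz: float
    adduct: str
    peaks: tuple[TheoreticalPeak, ...]  # sorted by m/z

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    def peak_for(self, annotation: str) -> TheoreticalPeak:
        for p in self.peaks:
            if annotation in p.annotation:
                return p
        raise KeyError(f"no peak annotated {annotation!r}")


def load_rules(path: str | Path | None = None) -> tuple[FragmentRule, ...]:
    """Load the fragment-rule table (packaged default or a user file)."""
    if path is None:
        ref = resources.files("oadlipid.data").joinpath("oad_rules.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    rules = []
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        rules.append(FragmentRule(
            rule_id=row["rule_id"],
            bond_site=int(row["bond_site"]),
            hydrogen_delta=int(row["hydrogen_delta"]),
            oxygen_delta=int(row["oxygen_delta"]),
            water_loss=bool(int(row["water_loss"])),
            rel_intensity=float(row["rel_intensity"]),
            diagnostic=bool(int(row["diagnostic"])),
            applicability=row["applicability"],
        ))
    _check_diagnostic_pairs(rules)
    return tuple(rules)


def _check_diagnostic_pairs(rules: list[FragmentRule]) -> None:
    by_class: dict[str, int] = {}
    for r in rules:
        if r.diagnostic:
            by_class[r.applicability] = by_class.get(r.applicability, 0) + 1
    for cls, n in by_class.items():
        if n != 2:
            raise RuleError(
                f"applicability class {cls!r} must have exactly 2 diagnostic "
                f"rules (the fragment pair), found {n}"
            )


_DEFAULT_RULES: tuple[FragmentRule, ...] | None = None


def default_rules() -> tuple[FragmentRule, ...]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def bond_context(chain: AcylChain, n_pos: int) -> str:
    """Rule applicability class governing the double bond at ``n_pos``.

    The sphingoid Δ4 bond (n = C − 4) fragments anomalously (neighbouring
    hydroxyls) and uses its own low-abundance subset; sphingoid bonds at
    Δ >= 8 behave like ordinary acyl-chain bonds.
    """
    if chain.linkage == "sphingoid" and n_pos == chain.carbons - 4:
        return "sphingoid_delta4"
    return "acyl"


def rules_for_context(
    context: str, rules: tuple[FragmentRule, ...] | None = None
) -> tuple[FragmentRule, ...]:
    """Subset of the rule table applicable in a bonding context."""
    rules = rules or default_rules()
    if context not in {"acyl", "sphingoid_delta4", "vinyl_ether"}:
        raise RuleError(f"unknown rule context {context!r}")
    return tuple(r for r in rules if r.applicability == context)


def special_case_rules(
    context: str, rules: tuple[FragmentRule, ...] | None = None
) -> tuple[FragmentRule, ...]:
    """Rule subset for a special context (sphingoid Δ4 / Δ>=8 / vinyl ether).

    Δ4 returns the dedicated low-abundance subset; ``sphingoid_delta_ge8``
    maps to the standard acyl rules; ``vinyl_ether`` returns the configured
    ether-bond entries.
    """
    mapping = {
        "sphingoid_delta4": "sphingoid_delta4",
        "sphingoid_delta_ge8": "acyl",
        "vinyl_ether": "vinyl_ether",
    }
    if context not in mapping:
        raise RuleError(f"unknown special context {context!r}")
    return rules_for_context(mapping[context], rules)


def fragment_neutral_loss(
    chain: AcylChain, db_index: int, rule: FragmentRule,
    n_pos: int | None = None,
) -> tuple[FormulaDelta, float]:
    """Neutral-loss composition and mass for one rule at one double bond.

    ``db_index`` selects the double bond from the chain's assigned positions
    (ascending); alternatively an explicit ``n_pos`` can be supplied (used
    for the implicit Δ1' bond of vinyl ethers, which is not part of the
    counted double bonds).
    """
    if n_pos is None:
        if db_index >= len(chain.positions):
            raise RuleError(
                f"chain has {len(chain.positions)} assigned positions; "
                f"double bond index {db_index} unavailable"
            )
        n_pos = chain.positions[db_index]
        if rule.applicability != bond_context(chain, n_pos):
            raise RuleError(
                f"rule {rule.rule_id} ({rule.applicability}) not applicable to "
                f"the n-{n_pos} bond of this {chain.linkage} chain"
            )
    x = n_pos
    k = x + rule.bond_site  # carbons lost from the methyl end
    if k < 1 or k >= chain.carbons:
        raise RuleError(
            f"cleavage site {rule.bond_site:+d} at n-{x} leaves no valid bond "
            f"on a C{chain.carbons} chain"
        )
    # double bonds fully contained in the lost fragment (carbons p, p+1 <= k)
    u = sum(1 for p in chain.positions if p + 1 <= k)
    if rule.applicability == "vinyl_ether" and x + 1 <= k:
        u += 1  # the implicit Δ1' bond itself
    hydrogens = 2 * k + 1 - 2 * u + rule.hydrogen_delta
    if hydrogens < 0:
        raise RuleError(f"rule {rule.rule_id} at n-{x}: negative hydrogen count")
    counts: dict[str, int] = {"C": k, "H": hydrogens}
    delta = FormulaDelta(counts)
    mass = delta.mass() - rule.oxygen_delta * ELEMENT_MASSES["O"]
    if rule.water_loss:
        mass += _WATER_MASS
        counts = dict(counts)
        counts["H"] = counts.get("H", 0) + 2
        counts["O"] = counts.get("O", 0) + 1
        delta = FormulaDelta(counts)
    if rule.oxygen_delta:
        counts = dict(delta.counts)
        counts["O"] = counts.get("O", 0) - 1
        delta = FormulaDelta(counts)
    return delta, mass


def diagnostic_pair(
    chain: AcylChain, db_index: int, rules: tuple[FragmentRule, ...] | None = None
) -> tuple[tuple[FragmentRule, float], ...]:
    """The two essential pair rules and their NL masses for one double bond."""
    context = bond_context(chain, chain.positions[db_index])
    pair = [r for r in rules_for_context(context, rules) if r.diagnostic]
    return tuple((r, fragment_neutral_loss(chain, db_index, r)[1]) for r in pair)


def generate_reference_spectrum(
    species: LipidSpecies,
    rules: tuple[FragmentRule, ...] | None = None,
    registry: SubclassRegistry | None = None,
    allow_partial: bool = False,
) -> TheoreticalSpectrum:
    """Reference OAD spectrum of a species with assigned C=C positions.

    Peaks: per (chain, double bond, applicable rule) fragment ions, implicit
    vinyl-ether Δ1' ions, subclass head-group ions from the registry, and the
    precursor ion. Colliding peaks merge keeping the maximum intensity. With
    ``allow_partial`` chains lacking positions contribute no C=C peaks
    (used while candidates are evaluated chain by chain); otherwise
    unresolved chains are an error.
    """
    registry = registry or default_registry()
    rules = rules or default_rules()
    if not allow_partial and not species.resolved:
        raise RuleError(
            f"unresolved chain positions in {serialize_lipid_name(species)}"
        )
    prec_mz = precursor_mz(species, registry)
    adduct = species.adduct or registry.get(species.subclass).default_adduct

    raw: list[TheoreticalPeak] = [
        TheoreticalPeak(prec_mz, 1.0, "precursor")
    ]
    for ion in registry.get(species.subclass).head_ions:
        if ion.kind == "fragment":
            mz = monoisotopic_mass(ion.formula)
        else:
            mz = prec_mz - monoisotopic_mass(ion.formula)
        raw.append(TheoreticalPeak(mz, ion.rel_intensity, f"head:{ion.label}"))

    for ci, chain in enumerate(species.chains):
        if chain.double_bonds and not chain.resolved:
            continue  # allow_partial path
        for di, n_pos in enumerate(chain.positions):
            context = bond_context(chain, n_pos)
            for rule in rules_for_context(context, rules):
                _, nl = fragment_neutral_loss(chain, di, rule)
                mz = prec_mz - nl
                if mz <= 0:
                    continue
                raw.append(TheoreticalPeak(
                    mz, rule.rel_intensity, f"{rule.rule_id}@chain{ci}:n-{n_pos}"
                ))
        if chain.linkage == "vinyl_ether":
            # implicit Δ1' bond at n-(C-1)
            for rule in rules_for_context("vinyl_ether", rules):
                _, nl = fragment_neutral_loss(
                    chain, 0, rule, n_pos=chain.carbons - 1
                )
                raw.append(TheoreticalPeak(
                    prec_mz - nl, rule.rel_intensity,
                    f"{rule.rule_id}@chain{ci}:vinyl-ether"
                ))

    merged = _merge_peaks(raw)
    return TheoreticalSpectrum(
        species_name=serialize_lipid_name(species),
        precursor_mz=prec_mz,
        adduct=adduct,
        peaks=tuple(merged),
    )


def _merge_peaks(peaks: list[TheoreticalPeak]) -> list[TheoreticalPeak]:
    """Merge peaks within MERGE_TOL_DA keeping the maximum intensity."""
    out: list[TheoreticalPeak] = []
    for p in sorted(peaks, key=lambda q: (q.mz, -q.rel_intensity, q.annotation)):
        if out and p.mz - out[-1].mz <= MERGE_TOL_DA:
            prev = out[-1]
            if p.rel_intensity > prev.rel_intensity:
                out[-1] = TheoreticalPeak(
                    prev.mz, p.rel_intensity, prev.annotation + "|" + p.annotation
                )
            else:
                out[-1] = TheoreticalPeak(
                    prev.mz, prev.rel_intensity, prev.annotation + "|" + p.annotation
                )
        else:
            out.append(p)
    return out


def export_msp(spectra: list[TheoreticalSpectrum], path: str | Path) -> None:
    """Dump reference spectra as MSP-style text for inspection."""
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write(f"NAME: {sp.species_name}\n")
            fh.write(f"PRECURSORMZ: {sp.precursor_mz:.4f}\n")
            fh.write(f"PRECURSORTYPE: {sp.adduct}\n")
            fh.write(f"Num Peaks: {len(sp.peaks)}\n")
            for p in sp.peaks:
                fh.write(f"{p.mz:.4f}\t{p.rel_intensity:.4f}\t\"{p.annotation}\"\n")
            fh.write("\n")
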