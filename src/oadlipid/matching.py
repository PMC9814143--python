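"""Peak matching, diagnostic-pair verification and candidate ranking
(algorithm steps 3–4).

A structural candidate survives only if, for every double bond, BOTH
essential pair ions are present within the ppm tolerance and above the
minimum relative-intensity threshold (0.01 % of the base peak by default;
0.005 % for the sphingoid Δ4 bond). Survivors are ranked by the reverse
dot product of square-root-transformed intensities, summed over reference
peaks only; the top candidate becomes the annotation, score ties within an
epsilon are reported as ambiguous with the ``&`` notation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import Config, MatchingConfig
from .enumeration import chain_evaluation_order, enumerate_positions
from .nomenclature import (
    AcylChain,
    LipidSpecies,
    canonical_name,
    serialize_lipid_name,
)
from .registry import SubclassRegistry, default_registry
from .rules import (
    FragmentRule,
    TheoreticalSpectrum,
    bond_context,
    default_rules,
    diagnostic_pair,
    generate_reference_spectrum,
)


@dataclass(frozen=True)
class MeasuredSpectrum:
    """An observed centroided MS/MS spectrum."""

    precursor_mz: float
    retention_time: float | None
    mz: np.ndarray
    intensity: np.ndarray
    spectrum_id: str = ""
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity must have the same length")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])
        if len(inten) and inten.max() <= 0:
            raise ValueError("base peak intensity must be > 0")

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self.intensity) else 0.0

    def __len__(self) -> int:
        return len(self.mz)


def match_peaks(
    measured: MeasuredSpectrum,
    reference: TheoreticalSpectrum,
    tol_ppm: float,
) -> list[tuple[int, int | None, float | None]]:
    """Match each reference peak to its nearest measured peak within ppm.

    Returns ``(reference_index, measured_index or None, ppm error or None)``
    for every reference peak, unmatched ones included.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    out: list[tuple[int, int | None, float | None]] = []
    mzs = measured.mz
    for ri, peak in enumerate(reference.peaks):
        idx = _nearest_within(mzs, peak.mz, tol_ppm)
        if idx is None:
            out.append((ri, None, None))
        else:
            ppm = (mzs[idx] - peak.mz) / peak.mz * 1e6
            out.append((ri, idx, float(ppm)))
    return out


def _nearest_within(mzs: np.ndarray, target: float, tol_ppm: float) -> int | None:
    if len(mzs) == 0:
        return None
    tol = target * tol_ppm * 1e-6
    i = int(np.searchsorted(mzs, target))
    best, best_err = None, tol
    for j in (i - 1, i):
        if 0 <= j < len(mzs):
            err = abs(float(mzs[j]) - target)
            if err <= best_err:
                best, best_err = j, err
    return best


@dataclass(frozen=True)
class PairVerification:
    """Diagnostic-pair verdicts for every double bond of a candidate."""

    per_bond: tuple[bool, ...]
    evidence: tuple[str, ...]  # "chain0 n-9 OAD03 mz=... (+0.4 ppm)" for hits

    @property
    def passed(self) -> bool:
        return all(self.per_bond)


def verify_essential_pair(
    measured: MeasuredSpectrum,
    species: LipidSpecies,
    rules: tuple[FragmentRule, ...] | None = None,
    config: MatchingConfig | None = None,
    registry: SubclassRegistry | None = None,
    chain_indices: list[int] | None = None,
) -> PairVerification:
    """Check both essential pair ions for each double bond of the species.

    Only chains with assigned positions are checked (optionally restricted to
    ``chain_indices``); each pair ion must match within ``tol_ppm`` and reach
    the context-dependent minimum relative intensity.
    """
    cfg = config or MatchingConfig()
    rules = rules or default_rules()
    registry = registry or default_registry()
    from .nomenclature import precursor_mz as _precursor_mz

    prec = _precursor_mz(species, registry)
    base = measured.base_peak_intensity
    verdicts: list[bool] = []
    evidence: list[str] = []
    for ci, chain in enumerate(species.chains):
        if chain_indices is not None and ci not in chain_indices:
            continue
        if not chain.positions:
            continue
        for di, n_pos in enumerate(chain.positions):
            context = bond_context(chain, n_pos)
            threshold = (
                cfg.min_rel_intensity_delta4
                if context == "sphingoid_delta4"
                else cfg.min_rel_intensity
            )
            bond_ok = True
            for rule, nl in diagnostic_pair(chain, di, rules):
                mz = prec - nl
                idx = _nearest_within(measured.mz, mz, cfg.tol_ppm)
                ok = (
                    idx is not None
                    and base > 0
                    and measured.intensity[idx] / base >= threshold
                )
                if ok:
                    ppm = (measured.mz[idx] - mz) / mz * 1e6
                    evidence.append(
                        f"chain{ci} n-{n_pos} {rule.rule_id} "
                        f"mz={measured.mz[idx]:.4f} ({ppm:+.1f} ppm)"
                    )
                bond_ok = bond_ok and ok
            verdicts.append(bond_ok)
    return PairVerification(tuple(verdicts), tuple(evidence))


def reverse_dot_product(
    measured: MeasuredSpectrum,
    reference: TheoreticalSpectrum,
    tol_ppm: float,
) -> float:
    """Spectral similarity over reference peaks with sqrt-transformed
    intensities; unmatched reference peaks contribute zero measured weight."""
    if not reference.peaks:
        raise ValueError("reference spectrum is empty")
    w_ref = np.sqrt([p.rel_intensity for p in reference.peaks])
    w_meas = np.zeros_like(w_ref)
    for ri, mi, _ in match_peaks(measured, reference, tol_ppm):
        if mi is not None:
            w_meas[ri] = np.sqrt(measured.intensity[mi])
    denom = float(np.sum(w_meas**2)) * float(np.sum(w_ref**2))
    if denom == 0:
        return 0.0
    num = float(np.sum(w_meas * w_ref))
    return num * num / denom


@dataclass(frozen=True)
class CandidateAssignment:
    """A fully scored candidate: species with positions, verdicts and score."""

    species: LipidSpecies
    diagnostics_passed: bool
    score: float | None  # present only if all diagnostics passed
    matched_reference_peaks: int = 0
    rank: int | None = None


@dataclass(frozen=True)
class AnnotationOutcome:
    """Result of annotating one spectrum against one molecular species."""

    status: str  # resolved | ambiguous | chain-unresolved | unresolved
    species: LipidSpecies | None
    score: float | None
    survivors: tuple[CandidateAssignment, ...]
    tied_names: tuple[str, ...] = ()
    ambiguous_label: str | None = None
    evidence: tuple[str, ...] = ()
    n_candidates: int = 0

    @property
    def resolved_name(self) -> str | None:
        if self.species is None:
            return None
        return serialize_lipid_name(self.species)


def rank_candidates(
    measured: MeasuredSpectrum,
    candidates: list[LipidSpecies],
    rules: tuple[FragmentRule, ...] | None = None,
    config: MatchingConfig | None = None,
    registry: SubclassRegistry | None = None,
    verify_chain_indices: list[int] | None = None,
) -> list[CandidateAssignment]:
    """Verify and score a list of position-assigned candidates.

    Survivors are sorted by score descending, then by the number of matched
    reference peaks (more corroborating ions first), then by position tuples
    lexicographically — a fully deterministic order.
    """
    cfg = config or MatchingConfig()
    rules = rules or default_rules()
    registry = registry or default_registry()
    scored: list[CandidateAssignment] = []
    # candidates with identical reference spectra are indistinguishable in
    # principle; score each distinct spectrum once so such groups tie exactly
    seen: dict[tuple, tuple[float, int]] = {}
    for cand in candidates:
        ver = verify_essential_pair(
            measured, cand, rules, cfg, registry, chain_indices=verify_chain_indices
        )
        if cfg.require_pair_all_bonds and not ver.passed:
            scored.append(CandidateAssignment(cand, False, None))
            continue
        ref = generate_reference_spectrum(
            cand, rules, registry, allow_partial=True
        )
        fingerprint = tuple(
            (round(p.mz, 4), round(p.rel_intensity, 6)) for p in ref.peaks
        )
        if fingerprint in seen:
            score, n_matched = seen[fingerprint]
        else:
            matches = match_peaks(measured, ref, cfg.tol_ppm)
            n_matched = sum(1 for _, mi, _ in matches if mi is not None)
            score = reverse_dot_product(measured, ref, cfg.tol_ppm)
            seen[fingerprint] = (score, n_matched)
        scored.append(CandidateAssignment(cand, True, score, n_matched))
    survivors = [c for c in scored if c.diagnostics_passed]
    eps = max(cfg.tie_epsilon, 1e-12)
    survivors.sort(
        key=lambda c: (
            # quantize so float noise below the tie epsilon cannot reorder
            -round(c.score / eps),
            -c.matched_reference_peaks,
            tuple(ch.positions for ch in c.species.chains),
        )
    )
    return [replace(c, rank=i + 1) for i, c in enumerate(survivors)]


def _ambiguous_first_positions(
    tied: list[LipidSpecies], chain_index: int
) -> tuple[int, ...]:
    firsts = sorted({
        sp.chains[chain_index].positions[0]
        for sp in tied
        if sp.chains[chain_index].positions
    })
    return tuple(firsts)


#: cap on the number of surviving candidates reported per record
MAX_TIED_EXPANSION = 100


def _swap_degenerate(species: LipidSpecies) -> bool:
    """True when equal-DBE chains carry different assignments that cannot be
    attributed chain-specifically (e.g. 16:1(n-7)_18:1(n-9) vs swapped)."""
    if species.chain_order_known:
        return False
    seen: dict[int, list[AcylChain]] = {}
    for ch in species.chains:
        if ch.double_bonds > 0:
            seen.setdefault(ch.double_bonds, []).append(ch)
    for chains in seen.values():
        if len(chains) >= 2:
            keys = {(c.carbons, c.positions) for c in chains}
            if len(keys) > 1:
                return True
    return False


#: cap on the number of jointly scored multi-chain combinations
MAX_JOINT_CANDIDATES = 2000


def _surviving_tuples(
    species: LipidSpecies,
    chain_index: int,
    measured: MeasuredSpectrum,
    rules: tuple[FragmentRule, ...],
    cfg: Config,
    registry: SubclassRegistry,
) -> tuple[int, list[tuple[int, ...]]]:
    """Position tuples of one chain passing the essential-pair check.

    The pair neutral losses depend only on the chain's own assignment, so
    verification prunes each chain independently before joint scoring.
    Returns (number enumerated, surviving tuples).
    """
    chain = species.chains[chain_index]
    tuples = enumerate_positions(chain.carbons, chain.double_bonds, cfg.enumeration)
    survivors = []
    for t in tuples:
        cand = species.with_chain(chain_index, chain.with_positions(t))
        ver = verify_essential_pair(
            measured, cand, rules, cfg.matching, registry,
            chain_indices=[chain_index],
        )
        if ver.passed or not cfg.matching.require_pair_all_bonds:
            survivors.append(t)
    return len(tuples), survivors


def _prune_by_partial_score(
    species: LipidSpecies,
    chain_index: int,
    tuples: list[tuple[int, ...]],
    keep: int,
    measured: MeasuredSpectrum,
    rules: tuple[FragmentRule, ...],
    cfg: Config,
    registry: SubclassRegistry,
) -> list[tuple[int, ...]]:
    chain = species.chains[chain_index]
    candidates = [species.with_chain(chain_index, chain.with_positions(t))
                  for t in tuples]
    ranked = rank_candidates(measured, candidates, rules, cfg.matching,
                             registry, verify_chain_indices=[chain_index])
    return [c.species.chains[chain_index].positions for c in ranked[:keep]]


def annotate_species(
    species: LipidSpecies,
    measured: MeasuredSpectrum,
    rules: tuple[FragmentRule, ...] | None = None,
    config: Config | None = None,
    registry: SubclassRegistry | None = None,
) -> AnnotationOutcome:
    """Assign C=C positions to a molecular-species-level annotation.

    Chains are processed in descending double-bond-count order. Each chain's
    candidate tuples are first pruned by the essential-pair requirement
    (chain-local, so chains prune independently); the surviving combinations
    are then scored jointly against full reference spectra, because peaks
    from different chains merge in the spectrum and only a complete
    assignment predicts the merged pattern. Score ties within the epsilon
    are reported as ambiguous.
    """
    cfg = config or Config()
    rules = rules or default_rules()
    registry = registry or default_registry()

    total_candidates = 0
    unresolved_indices = []
    per_chain: list[tuple[int, list[tuple[int, ...]]]] = []
    for ci in chain_evaluation_order(species):
        chain = species.chains[ci]
        if chain.double_bonds == 0 or chain.resolved:
            continue
        unresolved_indices.append(ci)
        n_enum, survivors = _surviving_tuples(
            species, ci, measured, rules, cfg, registry
        )
        total_candidates += n_enum
        if not survivors:
            return AnnotationOutcome(
                status="unresolved", species=None, score=None, survivors=(),
                n_candidates=total_candidates,
            )
        per_chain.append((ci, survivors))

    # keep the joint candidate set tractable: shrink the largest list by
    # partial-reference score until the product fits the cap
    def _product(lists: list[tuple[int, list]]) -> int:
        n = 1
        for _, lst in lists:
            n *= len(lst)
        return n

    while _product(per_chain) > MAX_JOINT_CANDIDATES:
        ci, largest = max(per_chain, key=lambda item: len(item[1]))
        keep = max(1, len(largest) // 2)
        pruned = _prune_by_partial_score(
            species, ci, largest, keep, measured, rules, cfg, registry
        )
        per_chain = [
            (cj, pruned if cj == ci else lst) for cj, lst in per_chain
        ]

    combos: list[LipidSpecies] = [species]
    for ci, tuples in per_chain:
        combos = [
            sp.with_chain(ci, sp.chains[ci].with_positions(t))
            for sp in combos for t in tuples
        ]

    ranked = rank_candidates(measured, combos, rules, cfg.matching, registry)
    if not ranked:
        return AnnotationOutcome(
            status="unresolved", species=None, score=None, survivors=(),
            n_candidates=total_candidates,
        )
    best = ranked[0]
    ties = [
        c for c in ranked
        if abs(c.score - best.score) <= cfg.matching.tie_epsilon
        and c.matched_reference_peaks == best.matched_reference_peaks
    ]
    current = best.species

    ambiguous = len(ties) > 1
    ambiguous_label = None
    if ambiguous:
        for ci in unresolved_indices:
            firsts = _ambiguous_first_positions([c.species for c in ties], ci)
            if len(firsts) > 1:
                ch = current.chains[ci]
                ambiguous_label = (
                    f"{ch.carbons}:{ch.double_bonds}"
                    f"(n-" + "&".join(str(p) for p in firsts) + ")"
                )
                break
    tied_names = sorted({canonical_name(c.species) for c in ties}) \
        if ambiguous else []

    verification = verify_essential_pair(
        measured, current, rules, cfg.matching, registry
    )
    score = best.score

    survivors = tuple(
        replace(c, rank=i + 1) for i, c in enumerate(ranked[:MAX_TIED_EXPANSION])
    )
    if ambiguous:
        status = "ambiguous"
    elif _swap_degenerate(current):
        status = "chain-unresolved"
    else:
        status = "resolved"
    return AnnotationOutcome(
        status=status,
        species=current,
        score=score,
        survivors=survivors,
        tied_names=tuple(tied_names),
        ambiguous_label=ambiguous_label,
        evidence=verification.evidence,
        n_candidates=total_candidates,
    )
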