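"""Combinatorial enumeration of C=C position candidates (algorithm step 1).

Positions are n-positions (methyl-end counting). Under the default
constraints — lowest position n-3, highest n-(C−2), adjacent double bonds
separated by at least two (no conjugation) — an 18:1 chain has 14 candidates
(n-3 … n-16) and a 22:6 chain has C(13, 6) = 1716, from (3,5,7,9,11,13) to
(10,12,14,16,18,20). The count is binomial(C − 3 − d, d) in general.
"""

from __future__ import annotations

from .config import EnumerationConfig
from .nomenclature import LipidSpecies


def enumerate_positions(
    carbons: int,
    double_bonds: int,
    config: EnumerationConfig | None = None,
) -> list[tuple[int, ...]]:
    """All valid n-position tuples for a chain, in lexicographic order.

    A saturated chain yields one empty tuple (its unique, vacuous
    assignment); a chain too short for its double-bond count yields none.
    """
    cfg = config or EnumerationConfig()
    if double_bonds == 0:
        return [()]
    lo, hi, gap = cfg.min_pos, carbons - cfg.max_offset, cfg.min_gap

    out: list[tuple[int, ...]] = []

    def extend(prefix: tuple[int, ...], start: int, remaining: int) -> None:
        if remaining == 0:
            out.append(prefix)
            return
        # leave room for the remaining-1 positions after this one
        last_ok = hi - gap * (remaining - 1)
        for p in range(start, last_ok + 1):
            extend(prefix + (p,), p + gap, remaining - 1)

    extend((), lo, double_bonds)
    return out


def chain_evaluation_order(species: LipidSpecies) -> list[int]:
    """Chain indices in evaluation order: highest double-bond count first.

    Ties break toward the longer chain, then input order — all deterministic.
    """
    return sorted(
        range(len(species.chains)),
        key=lambda i: (
            -species.chains[i].double_bonds,
            -species.chains[i].carbons,
            i,
        ),
    )
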