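"""Simplified nearest-neighbour energetics for hairpin scoring.

Watson-Crick stack free energies follow the standard RNA nearest-neighbour
parameter set (37 degC, kcal/mol), converted to kJ/mol on output. The loop
penalty is linear in loop size. This is a deliberately reduced model meant
for ranking candidate hairpins within one genome: absolute values are not
comparable with full secondary-structure predictors, which add terminal
mismatches, special loop tables and multibranch terms.
"""

from __future__ import annotations

KCAL_TO_KJ = 4.184

# rows/cols: 5' pair then 3' pair, pairs written top-strand-base +
# bottom-strand-base (RNA alphabet; DNA input is mapped T->U upstream)
_WC_STACK_KCAL: dict[tuple[str, str], float] = {
    ("AU", "AU"): -0.93, ("AU", "CG"): -2.24, ("AU", "GC"): -2.08, ("AU", "UA"): -1.10,
    ("CG", "AU"): -2.11, ("CG", "CG"): -3.26, ("CG", "GC"): -2.36, ("CG", "UA"): -2.08,
    ("GC", "AU"): -2.35, ("GC", "CG"): -3.42, ("GC", "GC"): -3.26, ("GC", "UA"): -2.24,
    ("UA", "AU"): -1.33, ("UA", "CG"): -2.35, ("UA", "GC"): -2.11, ("UA", "UA"): -0.93,
}

_GU_STACK_KCAL = -1.0  # flat value for any stack involving a wobble pair

# hairpin loop initiation: value at loop length 4 plus a linear size term
_LOOP_BASE_KCAL = 5.6
_LOOP_SLOPE_KCAL = 0.3

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def is_pair(x: str, y: str, wobble: bool = False) -> bool:
    if (x, y) in _WC:
        return True
    return wobble and (x, y) in _WOBBLE


def stack_energy_kcal(pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
    """Free energy of stacking pair2 on pair1 (5'->3' on the top strand)."""
    key = (pair1[0] + pair1[1], pair2[0] + pair2[1])
    if key in _WC_STACK_KCAL:
        return _WC_STACK_KCAL[key]
    return _GU_STACK_KCAL  # at least one wobble pair


def hairpin_energy_kj(pairs: list[tuple[str, str]], loop_length: int) -> float:
    """Total dG (kJ/mol) of a hairpin: sum of stem stacks + loop penalty.

    `pairs` are listed outermost-first along the top (5') arm.
    """
    if loop_length < 3:
        raise ValueError("hairpin loops shorter than 3 nt are sterically forbidden")
    stacks = sum(
        stack_energy_kcal(pairs[i], pairs[i + 1]) for i in range(len(pairs) - 1)
    )
    loop = _LOOP_BASE_KCAL + _LOOP_SLOPE_KCAL * (loop_length - 4)
    return (stacks + loop) * KCAL_TO_KJ
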