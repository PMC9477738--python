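"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths (no regex, no
scipy.hypergeom) so they can serve as ground truth.
"""

from itertools import combinations

IUPAC_SETS = {
    "A": set("A"),
    "C": set("C"),
    "G": set("G"),
    "T": set("T"),
    "R": set("AG"),
    "Y": set("CT"),
    "S": set("CG"),
    "W": set("AT"),
    "K": set("GT"),
    "M": set("AC"),
    "B": set("CGT"),
    "D": set("AGT"),
    "H": set("ACT"),
    "V": set("ACG"),
    "N": set("ACGT"),
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_hits(seq: str, consensus: str) -> list[tuple[int, str]]:
    """All (offset, strand) matches by direct window comparison on both
    strands; palindromic consensi reported once, on the forward strand.
    Minus-strand offsets are forward-strand starts."""
    m = len(consensus)
    rc_cons = "".join(
        {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}[c]
        for c in reversed(consensus)
    )
    palindromic = consensus == rc_cons
    hits = []
    for off in range(len(seq) - m + 1):
        window = seq[off : off + m]
        if all(ch in IUPAC_SETS[c] for ch, c in zip(window, consensus)):
            hits.append((off, "+"))
        if not palindromic:
            rc_window = "".join(_COMP.get(ch, "N") for ch in reversed(window))
            if all(ch in IUPAC_SETS[c] for ch, c in zip(rc_window, consensus)):
                hits.append((off, "-"))
    return sorted(hits)


def hypergeom_upper_tail_by_enumeration(n_universe: int, n_a: int, n_b: int, k: int) -> float:
    """P(|A ∩ B| >= k) by enumerating every possible draw A of size n_a."""
    universe = range(n_universe)
    b_set = set(range(n_b))  # symmetry: which elements are 'successes'
    total = 0
    ge = 0
    for draw in combinations(universe, n_a):
        total += 1
        if len(b_set.intersection(draw)) >= k:
            ge += 1
    return ge / total if total else 1.0
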