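"""Lox cargo insert design and RNA structural-flexibility scoring.

Cargo inserts are cloned into the intron's domain-IV MluI site, so an
insert travels as part of the intron RNA.  Symmetric lox sites fold into
tight hairpins that can disrupt intron folding; adding the sequence GAGAG
at both ends of the insert restores unpaired, flexible regions at the base
of the stem, which splits inserts into a flexible (wild-type-efficiency)
and an inflexible (impaired) class.  Structures are predicted by
base-pair maximization (Nussinov-style dynamic programming, Watson-Crick
plus GU, minimum hairpin loop of 3); a hook accepts externally computed
dot-bracket structures for users who prefer a thermodynamic folder.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lox import LoxSite

__all__ = [
    "CargoInsert",
    "FoldResult",
    "design_insert",
    "fold",
    "fold_from_dotbracket",
    "flexibility_score",
    "catalog_inserts",
    "MLU_I",
    "PME_I",
    "GAGAG",
]

MLU_I = "ACGCGT"
PME_I = "GTTTAAAC"
GAGAG = "GAGAG"
_PME_LINKER = "CTAG"  # short linker joining double-site payloads

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3


@dataclass(frozen=True)
class CargoInsert:
    name: str
    sequence: str  # DNA, including MluI cloning context
    lox_payload: tuple[LoxSite, ...]
    flanked_with_gagag: bool

    @property
    def core(self) -> str:
        """Insert without the MluI cloning context."""
        return self.sequence[len(MLU_I) : -len(MLU_I)]


@dataclass(frozen=True)
class FoldResult:
    sequence: str  # RNA
    pairs: tuple[int, ...]  # pairs[i] = partner index, or -1 if unpaired

    def __post_init__(self):
        for i, j in enumerate(self.pairs):
            if j >= 0 and (self.pairs[j] != i or abs(i - j) <= MIN_LOOP):
                raise ValueError("pairing map must be an involution with min loop 3")

    @property
    def n_pairs(self) -> int:
        return sum(1 for j in self.pairs if j >= 0) // 2

    @property
    def unpaired_fraction(self) -> float:
        n = len(self.pairs)
        return sum(1 for j in self.pairs if j < 0) / n if n else 0.0

    def unpaired_in_terminal(self, window: int = 5) -> tuple[int, int]:
        """Unpaired counts in the first and last ``window`` positions (the
        base of any stem the insert forms)."""
        head = sum(1 for j in self.pairs[:window] if j < 0)
        tail = sum(1 for j in self.pairs[-window:] if j < 0)
        return head, tail

    @property
    def longest_unpaired_run(self) -> int:
        best = run = 0
        for j in self.pairs:
            run = run + 1 if j < 0 else 0
            best = max(best, run)
        return best

    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.pairs):
            out.append("." if j < 0 else ("(" if i < j else ")"))
        return "".join(out)


def design_insert(
    lox_list: list[LoxSite] | tuple[LoxSite, ...],
    flexible: bool,
    name: str | None = None,
) -> CargoInsert:
    """Build a domain-IV cargo insert carrying one or two lox sites.

    Single-site inserts are the lox site in its cloning context; double-site
    inserts join the two sites with a PmeI site and a short linker.  When
    ``flexible``, GAGAG is appended at both ends of the insert (inside the
    MluI context) to keep the ends of the folded structure unpaired.
    """
    lox_list = tuple(lox_list)
    if len(lox_list) == 0:
        raise ValueError("cargo insert needs at least one lox site")
    if len(lox_list) > 2:
        raise ValueError("at most two lox sites per insert are supported")
    payload = lox_list[0].sequence()
    if len(lox_list) == 2:
        payload += PME_I + _PME_LINKER + lox_list[1].sequence()
    core = (GAGAG + payload + GAGAG) if flexible else payload
    if name is None:
        tags = "+".join(s.name or s.linker_class for s in lox_list)
        name = f"insert[{tags}]{'+GAGAG' if flexible else ''}"
    return CargoInsert(
        name=name,
        sequence=MLU_I + core + MLU_I,
        lox_payload=lox_list,
        flanked_with_gagag=flexible,
    )


def catalog_inserts() -> dict[str, CargoInsert]:
    """The shipped insert catalogue (single sites, wild type, and the
    double-mutant pairs used for cassette exchange, each with and without
    flexibility flanks)."""
    from .lox import LoxCatalog, Orientation

    cat = LoxCatalog.default()
    fwd = Orientation.FORWARD

    def site(n):
        return cat[n].oriented(fwd)

    return {
        "1L66": design_insert([site("lox66")], flexible=False, name="1L66"),
        "1L71": design_insert([site("lox71")], flexible=False, name="1L71"),
        "1WL1": design_insert([site("loxP")], flexible=False, name="1WL1"),
        "1WL2": design_insert([site("loxP")], flexible=True, name="1WL2"),
        "2ML1": design_insert(
            [site("lox511/71"), site("loxFAS/66")], flexible=False, name="2ML1"
        ),
        "2ML4": design_insert(
            [site("lox511/71"), site("loxFAS/66")], flexible=True, name="2ML4"
        ),
        "2ML5": design_insert(
            [site("lox71"), site("loxm2/66")], flexible=True, name="2ML5"
        ),
    }


# ---------------------------------------------------------------------------
# Base-pair maximization folding
# ---------------------------------------------------------------------------


def _to_rna(seq: str) -> str:
    rna = seq.upper().replace("T", "U")
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return rna


def fold(rna: str) -> FoldResult:
    """Maximum base-pairing secondary structure (no pseudoknots).

    Dynamic programming over Watson-Crick + GU pairs with a minimum hairpin
    loop of {MIN_LOOP} nt.  Tie-breaking is deterministic: the traceback
    prefers pairing the interval end with the smallest eligible 5' index,
    so identical inputs always give identical structures.  DNA input is
    transcribed (T -> U).
    """
    rna = _to_rna(rna)
    n = len(rna)
    if n < 10:
        raise ValueError("fold needs at least 10 nt")
    dp = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - MIN_LOOP):
                if (rna[k], rna[j]) in _PAIRS:
                    left = dp[i][k - 1] if k > i else 0
                    cand = left + 1 + dp[k + 1][j - 1]
                    if cand > best:
                        best = cand
            dp[i][j] = best
    pairs = [-1] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        target = dp[i][j]
        chosen = None
        if target != dp[i][j - 1]:  # j must pair; take the smallest 5' partner
            for k in range(i, j - MIN_LOOP):
                if (rna[k], rna[j]) in _PAIRS:
                    left = dp[i][k - 1] if k > i else 0
                    if left + 1 + dp[k + 1][j - 1] == target:
                        chosen = k
                        break
        if chosen is None:
            stack.append((i, j - 1))
        else:
            pairs[chosen], pairs[j] = j, chosen
            if chosen > i:
                stack.append((i, chosen - 1))
            stack.append((chosen + 1, j - 1))
    return FoldResult(sequence=rna, pairs=tuple(pairs))


fold.__doc__ = fold.__doc__.format(MIN_LOOP=MIN_LOOP)


def fold_from_dotbracket(rna: str, structure: str) -> FoldResult:
    """Wrap an externally computed dot-bracket structure (e.g. from a
    thermodynamic folder) in a :class:`FoldResult` for scoring."""
    rna = _to_rna(rna)
    if len(structure) != len(rna):
        raise ValueError("structure/sequence length mismatch")
    pairs = [-1] * len(rna)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif c != ".":
            raise ValueError(f"bad dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return FoldResult(sequence=rna, pairs=tuple(pairs))


def flexibility_score(
    insert: CargoInsert,
    terminal_window: int = 5,
    min_terminal_unpaired: int = 2,
    structure: FoldResult | None = None,
) -> tuple[float, str]:
    """Score an insert's predicted structural flexibility.

    The score is the insert's unpaired fraction plus the unpaired count in
    the ``terminal_window`` positions at each end (normalized), emphasizing
    slack at the base of the stem.  Classification is two-class: flexible
    iff the two terminal windows together hold at least
    ``2 * min_terminal_unpaired`` unpaired bases.  The sum is used rather
    than a per-end cutoff because co-optimal maximum-pairing structures can
    shuffle slack between the two ends; the threshold is configurable and
    the underlying distinction is qualitative.
    """
    fr = structure or fold(insert.core)
    head, tail = fr.unpaired_in_terminal(terminal_window)
    score = fr.unpaired_fraction + (head + tail) / (2 * terminal_window)
    label = "flexible" if head + tail >= 2 * min_terminal_unpaired else "inflexible"
    return score, label
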