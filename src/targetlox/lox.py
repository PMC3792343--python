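"""Lox-site algebra: parsing, compatibility, and Cre recombination products.

A lox site is a 34-nt Cre recombination target: two 13-nt inverted-repeat
arms flanking an asymmetric 8-nt linker.  The linker sets both the
orientation of the site and its recombination specificity (sites recombine
only with linker-compatible partners).  Arm mutations (as in lox66/lox71)
lower Cre affinity; recombining a left-arm mutant with a right-arm mutant
leaves one double-mutant site (lox72-type) that Cre no longer recognizes,
which is what makes such reactions unidirectional.

All algebra here operates on the decomposed representation
(left arm, linker, right arm, arm states, orientation); nucleotide strings
only matter at the parsing/rendering boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

__all__ = [
    "ArmState",
    "Orientation",
    "LoxSite",
    "LoxCatalog",
    "LoxError",
    "LoxLengthError",
    "UnknownLoxError",
    "RecombinationError",
    "parse_lox",
    "linker_compatible",
    "is_active",
    "recombine",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ARM_LEN = 13
LINKER_LEN = 8
SITE_LEN = 2 * ARM_LEN + LINKER_LEN


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ArmState(str, enum.Enum):
    WILD_TYPE = "wild_type"
    MUTANT = "mutant"


class Orientation(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"

    def flipped(self) -> "Orientation":
        return Orientation.REVERSE if self is Orientation.FORWARD else Orientation.FORWARD


class LoxError(ValueError):
    """Base class for lox parsing/recombination errors."""


class LoxLengthError(LoxError):
    """Input sequence is not exactly 34 nt."""


class UnknownLoxError(LoxError):
    """Linker does not match any catalogue linker class (or is ambiguous)."""


class RecombinationError(LoxError):
    """The requested pair of sites cannot recombine."""


@dataclass(frozen=True)
class LoxSite:
    """Decomposed lox site.

    ``left_arm``/``linker``/``right_arm`` are given on the site's own strand
    (the strand on which the linker reads in its canonical class
    orientation).  ``orientation`` records how that strand maps onto the
    hosting molecule's reference strand; it is metadata, so the arm-exchange
    rule of :func:`recombine` never has to reason about strands.
    """

    left_arm: str
    linker: str
    right_arm: str
    left_arm_state: ArmState = ArmState.WILD_TYPE
    right_arm_state: ArmState = ArmState.WILD_TYPE
    linker_class: str = "P"
    orientation: Orientation = Orientation.FORWARD
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.left_arm) != ARM_LEN or len(self.right_arm) != ARM_LEN:
            raise LoxLengthError(
                f"lox arms must be {ARM_LEN} nt, got "
                f"{len(self.left_arm)}/{len(self.right_arm)}"
            )
        if len(self.linker) != LINKER_LEN:
            raise LoxLengthError(f"lox linker must be {LINKER_LEN} nt, got {len(self.linker)}")
        if self.linker == revcomp(self.linker):
            raise LoxError(
                f"linker {self.linker!r} is palindromic; orientation would be undefined"
            )

    # -- derived properties -------------------------------------------------

    @property
    def is_active(self) -> bool:
        """False iff both arms are mutant (lox72-type; invisible to Cre)."""
        return not (
            self.left_arm_state is ArmState.MUTANT
            and self.right_arm_state is ArmState.MUTANT
        )

    @property
    def is_wild_type_arms(self) -> bool:
        return (
            self.left_arm_state is ArmState.WILD_TYPE
            and self.right_arm_state is ArmState.WILD_TYPE
        )

    def site_strand_sequence(self) -> str:
        """34-mer on the site's own strand (linker in canonical orientation)."""
        return self.left_arm + self.linker + self.right_arm

    def sequence(self) -> str:
        """34-mer on the hosting molecule's reference strand."""
        s = self.site_strand_sequence()
        return s if self.orientation is Orientation.FORWARD else revcomp(s)

    def flipped(self) -> "LoxSite":
        """Same site seen from the other strand of the molecule."""
        return replace(self, orientation=self.orientation.flipped())

    def oriented(self, orientation: Orientation) -> "LoxSite":
        return replace(self, orientation=orientation)


class LoxCatalog:
    """Named collection of reference lox sites.

    The default catalogue covers the wild-type site, the arm mutants
    (lox66/lox71/lox72), the orthogonal-linker variants (lox511, loxFAS,
    loxm2, lox2272, loxN), and the combined arm/linker mutants used for
    cassette exchange (e.g. lox511/71, loxFAS/66, loxm2/71, loxm2/66).
    """

    def __init__(self, sites: dict[str, LoxSite]):
        if not sites:
            raise ValueError("empty lox catalogue")
        self._sites = dict(sites)
        self._validate()

    def _validate(self) -> None:
        wild = [s for s in self._sites.values() if s.is_wild_type_arms]
        if not wild:
            raise ValueError("catalogue needs at least one site with wild-type arms")
        for name, s in self._sites.items():
            if s.is_wild_type_arms and s.left_arm != revcomp(s.right_arm):
                raise ValueError(
                    f"{name}: wild-type arms must be reverse complements of each other"
                )
            if name.endswith("/66") and s.right_arm_state is not ArmState.MUTANT:
                raise ValueError(f"{name}: '/66' names must carry a mutant right arm")
            if name.endswith("/71") and s.left_arm_state is not ArmState.MUTANT:
                raise ValueError(f"{name}: '/71' names must carry a mutant left arm")
        # Linkers must identify a unique class on a unique strand.
        seen: dict[str, str] = {}
        for s in self._sites.values():
            for k, cls in ((s.linker, s.linker_class), (revcomp(s.linker), s.linker_class + "(rc)")):
                if k in seen and not seen[k].startswith(cls.split("(")[0]):
                    raise ValueError(f"linker {k} maps to two classes; parsing would be ambiguous")
                seen.setdefault(k, cls)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LoxCatalog":
        sites: dict[str, LoxSite] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().strip().split("\t")
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                row = dict(zip(header, line.strip().split("\t")))
                sites[row["name"]] = LoxSite(
                    left_arm=row["left_arm"],
                    linker=row["linker"],
                    right_arm=row["right_arm"],
                    left_arm_state=ArmState(row["left_arm_state"]),
                    right_arm_state=ArmState(row["right_arm_state"]),
                    linker_class=row["linker_class"],
                    name=row["name"],
                )
        return cls(sites)

    _default: "LoxCatalog | None" = None

    @classmethod
    def default(cls) -> "LoxCatalog":
        if cls._default is None:
            with resources.as_file(
                resources.files("targetlox.data").joinpath("lox_catalog.tsv")
            ) as p:
                cls._default = cls.from_tsv(p)
        return cls._default

    # -- access -------------------------------------------------------------

    def __getitem__(self, name: str) -> LoxSite:
        try:
            return self._sites[name]
        except KeyError:
            raise UnknownLoxError(f"no catalogue site named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._sites

    def __iter__(self):
        return iter(self._sites)

    def names(self) -> list[str]:
        return list(self._sites)

    def linker_classes(self) -> dict[str, str]:
        """Map linker class label -> canonical linker sequence."""
        return {s.linker_class: s.linker for s in self._sites.values()}

    def arm_states(self, left_arm: str, right_arm: str) -> tuple[ArmState, ArmState]:
        """Classify arms by comparison with catalogue wild-type arms."""
        wt = next(s for s in self._sites.values() if s.is_wild_type_arms)
        left = ArmState.WILD_TYPE if left_arm == wt.left_arm else ArmState.MUTANT
        right = ArmState.WILD_TYPE if right_arm == wt.right_arm else ArmState.MUTANT
        return left, right

    def name_of(self, site: LoxSite) -> str | None:
        """Catalogue name matching a site's decomposition, if any."""
        for name, ref in self._sites.items():
            if (
                ref.left_arm == site.left_arm
                and ref.linker == site.linker
                and ref.right_arm == site.right_arm
            ):
                return name
        return None


def parse_lox(sequence: str, catalog: LoxCatalog | None = None) -> LoxSite:
    """Decompose a 34-nt sequence into a :class:`LoxSite`.

    Orientation is inferred from which strand carries a known linker; arm
    states are classified by comparison with the catalogue arm sequences.

    Raises :class:`LoxLengthError` for wrong-length input and
    :class:`UnknownLoxError` when the linker matches no catalogue class (or,
    pathologically, more than one).
    """
    catalog = catalog or LoxCatalog.default()
    sequence = sequence.upper()
    if len(sequence) != SITE_LEN:
        raise LoxLengthError(f"lox sites are {SITE_LEN} nt; got {len(sequence)} nt")
    linker = sequence[ARM_LEN : ARM_LEN + LINKER_LEN]
    classes = catalog.linker_classes()
    fwd = [c for c, k in classes.items() if k == linker]
    rev = [c for c, k in classes.items() if k == revcomp(linker)]
    if len(fwd) + len(rev) > 1:
        raise UnknownLoxError(f"linker {linker!r} matches more than one catalogue class")
    if fwd:
        cls, orientation, strand_seq = fwd[0], Orientation.FORWARD, sequence
    elif rev:
        cls, orientation, strand_seq = rev[0], Orientation.REVERSE, revcomp(sequence)
    else:
        raise UnknownLoxError(f"linker {linker!r} matches no catalogue linker class")
    left, right = strand_seq[:ARM_LEN], strand_seq[ARM_LEN + LINKER_LEN :]
    lstate, rstate = catalog.arm_states(left, right)
    site = LoxSite(
        left_arm=left,
        linker=strand_seq[ARM_LEN : ARM_LEN + LINKER_LEN],
        right_arm=right,
        left_arm_state=lstate,
        right_arm_state=rstate,
        linker_class=cls,
        orientation=orientation,
    )
    return replace(site, name=catalog.name_of(site))


CompatibilityMatrix = dict[frozenset[str], bool]


def linker_compatible(
    a: LoxSite, b: LoxSite, matrix: CompatibilityMatrix | None = None
) -> bool:
    """True iff the two sites' linker classes may recombine.

    Defaults to exact class identity (distinct linker classes are mutually
    incompatible); a user matrix keyed by frozen class pairs overrides.
    """
    if matrix is not None:
        key = frozenset((a.linker_class, b.linker_class))
        if key in matrix:
            return matrix[key]
    return a.linker_class == b.linker_class


def is_active(site: LoxSite) -> bool:
    """Whether Cre still recognizes the site (false for double-arm mutants)."""
    return site.is_active


def recombine(
    a: LoxSite, b: LoxSite, matrix: CompatibilityMatrix | None = None
) -> tuple[LoxSite, LoxSite]:
    """Products of Cre-mediated recombination between two sites.

    With both inputs normalized to their own linker strand, the crossover
    exchanges arms across the linker::

        product1 = a.left_arm + linker + b.right_arm
        product2 = b.left_arm + linker + a.right_arm

    Arm-mutation states travel with their arms, so the arm multiset and the
    linker multiset are conserved.  Raises :class:`RecombinationError` when
    the linkers are incompatible or either participant is inactive.
    """
    if not linker_compatible(a, b, matrix):
        raise RecombinationError(
            f"incompatible linkers: {a.linker_class!r} vs {b.linker_class!r}"
        )
    if not a.is_active or not b.is_active:
        raise RecombinationError("inactive (double-arm-mutant) sites cannot recombine")
    p1 = LoxSite(
        left_arm=a.left_arm,
        linker=a.linker,
        right_arm=b.right_arm,
        left_arm_state=a.left_arm_state,
        right_arm_state=b.right_arm_state,
        linker_class=a.linker_class,
        orientation=a.orientation,
    )
    p2 = LoxSite(
        left_arm=b.left_arm,
        linker=b.linker,
        right_arm=a.right_arm,
        left_arm_state=b.left_arm_state,
        right_arm_state=a.right_arm_state,
        linker_class=b.linker_class,
        orientation=b.orientation,
    )
    return p1, p2
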