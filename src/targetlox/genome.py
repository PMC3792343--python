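"""Annotated DNA molecules (chromosomes, plasmids, excised circles).

Coordinates are 0-based half-open on the reference strand throughout; the
gene-relative 1-based positions used in intron names are converted at the
naming layer only.  Circular molecules are stored as a linearized string
with an implicit junction between the last and first base; operations that
care (feature extraction, PCR, canonical hashing) handle the wrap
explicitly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .lox import LoxSite, Orientation, parse_lox, revcomp

__all__ = [
    "FeatureKind",
    "Feature",
    "IntronFragment",
    "Scaffold",
    "IntronDesign",
    "Molecule",
    "Part",
    "GenomeError",
    "insert_intron",
    "locate_lox",
    "default_scaffold",
    "molecule_rc",
    "part_of",
    "rc_part",
    "lox_part",
    "assemble",
    "least_rotation",
    "canonical_sequence",
    "read_molecules",
    "write_fasta",
    "write_genbank",
]


class GenomeError(ValueError):
    """Coordinate/feature bookkeeping error on a molecule."""


class FeatureKind(str, enum.Enum):
    GENE = "gene"
    INTRON = "intron"
    LOX = "lox"
    PRIMER_SITE = "primer_site"
    SCAR = "scar"


@dataclass(frozen=True)
class IntronFragment:
    """Payload of an intron feature: which slice of which scaffold is present.

    ``scaffold_start``/``scaffold_end`` are coordinates in the scaffold's own
    frame, so homology between intron copies survives any amount of genomic
    cutting and flipping.
    """

    scaffold_id: str
    scaffold_start: int
    scaffold_end: int

    @property
    def length(self) -> int:
        return self.scaffold_end - self.scaffold_start

    def overlap(self, other: "IntronFragment") -> int:
        if self.scaffold_id != other.scaffold_id:
            return 0
        return max(
            0,
            min(self.scaffold_end, other.scaffold_end)
            - max(self.scaffold_start, other.scaffold_start),
        )


@dataclass(frozen=True)
class Feature:
    kind: FeatureKind
    start: int
    end: int
    strand: str = "+"  # '+' or '-'
    label: str = ""
    payload: object = None  # LoxSite for lox, IntronFragment for intron

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise GenomeError(f"empty/inverted feature interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise GenomeError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Feature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class Scaffold:
    """Intron scaffold: the ~1 kb intron body with a single cargo cloning
    position (the MluI-equivalent site of domain IV, where the intron-encoded
    protein ORF sits in the wild type)."""

    id: str
    sequence: str
    cargo_site: int  # offset of the cloning position within the scaffold

    def __post_init__(self) -> None:
        if not 0 < self.cargo_site < len(self.sequence):
            raise GenomeError("cargo site must be interior to the scaffold")

    @property
    def length(self) -> int:
        return len(self.sequence)


#: Intron scaffold types with little mutual sequence homology.
INTRON_TYPES = ("Ll.LtrB", "EcI5")

_SCAFFOLD_SEEDS = {"Ll.LtrB": 71366, "EcI5": 22721}
_scaffold_cache: dict[tuple[str, int], Scaffold] = {}


def default_scaffold(intron_type: str, length: int = 1000) -> Scaffold:
    """Deterministic synthetic scaffold for an intron type.

    Synthetic stand-ins (~1 kb, matching the observation that an intron
    insertion enlarges a verification amplicon by about 1 kb); the cargo
    cloning site sits at the midpoint.  Real scaffolds can be supplied by
    constructing :class:`Scaffold` from a GenBank record instead.
    """
    if intron_type not in _SCAFFOLD_SEEDS:
        raise GenomeError(f"unknown intron type {intron_type!r}; expected one of {INTRON_TYPES}")
    key = (intron_type, length)
    if key not in _scaffold_cache:
        rng = np.random.default_rng(_SCAFFOLD_SEEDS[intron_type])
        seq = "".join(rng.choice(list("ACGT"), size=length))
        _scaffold_cache[key] = Scaffold(id=intron_type, sequence=seq, cargo_site=length // 2)
    return _scaffold_cache[key]


@dataclass(frozen=True)
class IntronDesign:
    """A retargeted intron carrying lox cargo at its domain-IV cloning site."""

    intron_type: str
    target_gene: str
    target_position: int  # 1-based position within the gene (naming convention)
    target_strand: str  # 's' (sense) or 'a' (antisense)
    cargo: tuple[LoxSite, ...] = ()
    scaffold: Scaffold | None = None

    def __post_init__(self) -> None:
        if self.target_strand not in ("s", "a"):
            raise GenomeError(f"target strand must be 's' or 'a', got {self.target_strand!r}")
        if self.intron_type not in INTRON_TYPES:
            raise GenomeError(f"unknown intron type {self.intron_type!r}")

    def resolved_scaffold(self) -> Scaffold:
        return self.scaffold or default_scaffold(self.intron_type)

    @property
    def name(self) -> str:
        from .retarget import format_intron_name

        return format_intron_name(
            self.intron_type, self.target_gene, self.target_position, self.target_strand
        )

    def insert_sequence(self) -> str:
        """Scaffold with cargo spliced at the cloning site, intron-forward."""
        sc = self.resolved_scaffold()
        cargo_seq = "".join(s.sequence() for s in self.cargo)
        return sc.sequence[: sc.cargo_site] + cargo_seq + sc.sequence[sc.cargo_site :]


@dataclass
class Molecule:
    """Circular or linear annotated DNA sequence."""

    id: str
    sequence: str
    topology: str = "circular"  # 'circular' | 'linear'
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise GenomeError(f"bad topology {self.topology!r}")
        self.sequence = self.sequence.upper()
        for f in self.features:
            if f.end > len(self.sequence) and self.topology == "linear":
                raise GenomeError(f"feature {f.label!r} exceeds linear molecule bounds")
        self.features.sort(key=lambda f: (f.start, f.end, f.kind.value, f.label))

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def feature_seq(self, f: Feature) -> str:
        """Reference-strand sequence under a feature (wrap-aware)."""
        if f.end <= self.length:
            return self.sequence[f.start : f.end]
        if not self.is_circular:
            raise GenomeError("feature wraps on a linear molecule")
        return self.sequence[f.start :] + self.sequence[: f.end - self.length]

    def features_of(self, kind: FeatureKind) -> list[Feature]:
        return [f for f in self.features if f.kind is kind]

    def rotated(self, offset: int) -> "Molecule":
        """Rotate a circular molecule so old position ``offset`` becomes 0."""
        if not self.is_circular:
            raise GenomeError("cannot rotate a linear molecule")
        L = self.length
        offset %= L
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            s = (f.start - offset) % L
            feats.append(replace(f, start=s, end=s + f.length))
        return Molecule(self.id, seq, "circular", feats)

    def canonical_key(self) -> tuple[str, str]:
        return (self.topology, canonical_sequence(self.sequence, self.is_circular))


def least_rotation(s: str) -> int:
    """Index of the lexicographically least rotation (Booth's algorithm)."""
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_sequence(seq: str, circular: bool) -> str:
    """Strand- and rotation-independent canonical form of a molecule's
    sequence (a circle read from any point on either strand is the same
    physical molecule)."""
    rc = revcomp(seq)
    if not circular:
        return min(seq, rc)
    i = least_rotation(seq)
    j = least_rotation(rc)
    return min(seq[i:] + seq[:i], rc[j:] + rc[:j])


def molecule_rc(mol: Molecule) -> Molecule:
    """The same molecule viewed from the other strand."""
    L = mol.length
    feats = []
    for f in mol.features:
        payload = f.payload
        if isinstance(payload, LoxSite):
            payload = payload.flipped()
        feats.append(
            Feature(
                kind=f.kind,
                start=L - f.end,
                end=L - f.start,
                strand="-" if f.strand == "+" else "+",
                label=f.label,
                payload=payload,
            )
        )
    return Molecule(mol.id, revcomp(mol.sequence), mol.topology, feats)


# ---------------------------------------------------------------------------
# Part-based assembly: the engine under every sequence surgery.
# ---------------------------------------------------------------------------


@dataclass
class Part:
    """A sequence fragment plus part-local features, ready for assembly."""

    seq: str
    features: list[Feature] = field(default_factory=list)


def part_of(mol: Molecule, start: int, end: int) -> Part:
    """Extract ``[start, end)`` of a molecule as a part.

    ``end`` may exceed the molecule length on circular molecules (wrap).
    Features are clipped to the window; a clipped intron feature keeps track
    of which scaffold slice survives, a clipped lox feature is destroyed
    (a partial site is not a site), other kinds are truncated.
    """
    L = mol.length
    if start < 0 or end < start or (end > L and not mol.is_circular):
        raise GenomeError(f"bad extraction window [{start},{end}) on length {L}")
    if end - start > L:
        raise GenomeError("extraction window longer than the molecule")
    seq = (
        mol.sequence[start:end]
        if end <= L
        else mol.sequence[start:] + mol.sequence[: end - L]
    )
    feats: list[Feature] = []
    copies = (0, L) if mol.is_circular else (0,)
    for f in mol.features:
        for off in copies:
            fs, fe = f.start + off, f.end + off
            s, e = max(fs, start), min(fe, end)
            if e <= s:
                continue
            clipped_left, clipped_right = s - fs, fe - e
            if (clipped_left or clipped_right) and f.kind is FeatureKind.LOX:
                continue
            payload = f.payload
            if isinstance(payload, IntronFragment) and (clipped_left or clipped_right):
                if f.strand == "+":
                    payload = IntronFragment(
                        payload.scaffold_id,
                        payload.scaffold_start + clipped_left,
                        payload.scaffold_end - clipped_right,
                    )
                else:
                    payload = IntronFragment(
                        payload.scaffold_id,
                        payload.scaffold_start + clipped_right,
                        payload.scaffold_end - clipped_left,
                    )
            feats.append(
                Feature(
                    kind=f.kind,
                    start=s - start,
                    end=e - start,
                    strand=f.strand,
                    label=f.label,
                    payload=payload,
                )
            )
    return Part(seq=seq, features=feats)


def rc_part(part: Part) -> Part:
    L = len(part.seq)
    feats = []
    for f in part.features:
        payload = f.payload
        if isinstance(payload, LoxSite):
            payload = payload.flipped()
        feats.append(
            Feature(
                kind=f.kind,
                start=L - f.end,
                end=L - f.start,
                strand="-" if f.strand == "+" else "+",
                label=f.label,
                payload=payload,
            )
        )
    return Part(seq=revcomp(part.seq), features=feats)


def lox_part(site: LoxSite, label: str = "lox") -> Part:
    name = site.name or label
    return Part(
        seq=site.sequence(),
        features=[
            Feature(
                kind=FeatureKind.LOX,
                start=0,
                end=len(site.sequence()),
                strand="+" if site.orientation is Orientation.FORWARD else "-",
                label=name,
                payload=site,
            )
        ],
    )


def assemble(mol_id: str, parts: list[Part], topology: str) -> Molecule:
    seq_chunks: list[str] = []
    feats: list[Feature] = []
    offset = 0
    for p in parts:
        seq_chunks.append(p.seq)
        feats.extend(f.shifted(offset) for f in p.features)
        offset += len(p.seq)
    return Molecule(mol_id, "".join(seq_chunks), topology, feats)


# ---------------------------------------------------------------------------
# Intron insertion
# ---------------------------------------------------------------------------


def insert_intron(mol: Molecule, site_coordinate: int, design: IntronDesign) -> Molecule:
    """Splice an intron (scaffold + lox cargo) into a molecule.

    The insert goes between the bases at ``site_coordinate - 1`` and
    ``site_coordinate`` (the junction between the -1 and +1 positions of the
    target site).  An antisense design inserts the reverse complement, and
    every cargo lox feature is registered with its orientation composed from
    cargo orientation and insertion strand.  Downstream features shift by the
    insert length.
    """
    if not 0 <= site_coordinate <= mol.length:
        raise GenomeError(
            f"insertion coordinate {site_coordinate} outside molecule of length {mol.length}"
        )
    for f in mol.features_of(FeatureKind.INTRON):
        if f.start < site_coordinate < f.end:
            raise GenomeError(
                f"insertion at {site_coordinate} conflicts with existing intron {f.label!r}"
            )

    sc = design.resolved_scaffold()
    antisense = design.target_strand == "a"
    strand = "-" if antisense else "+"

    # Build the insert as a part in intron-forward frame, then flip if needed.
    parts: list[Part] = []
    parts.append(
        Part(
            seq=sc.sequence[: sc.cargo_site],
            features=[
                Feature(
                    kind=FeatureKind.INTRON,
                    start=0,
                    end=sc.cargo_site,
                    strand="+",
                    label=f"{design.name}:5p",
                    payload=IntronFragment(sc.id, 0, sc.cargo_site),
                )
            ],
        )
    )
    for i, cargo_site in enumerate(design.cargo):
        parts.append(lox_part(cargo_site, label=f"lox{i}"))
    parts.append(
        Part(
            seq=sc.sequence[sc.cargo_site :],
            features=[
                Feature(
                    kind=FeatureKind.INTRON,
                    start=0,
                    end=sc.length - sc.cargo_site,
                    strand="+",
                    label=f"{design.name}:3p",
                    payload=IntronFragment(sc.id, sc.cargo_site, sc.length),
                )
            ],
        )
    )
    insert = assemble("_insert", parts, "linear")
    insert_part = Part(seq=insert.sequence, features=list(insert.features))
    if antisense:
        insert_part = rc_part(insert_part)
    ilen = len(insert_part.seq)

    feats: list[Feature] = []
    for f in mol.features:
        if f.end <= site_coordinate:
            feats.append(f)
        elif f.start >= site_coordinate:
            feats.append(f.shifted(ilen))
        else:
            # Feature spanning the insertion point: keep (stretched) for genes,
            # since the gene is interrupted but its exons remain.
            feats.append(replace(f, end=f.end + ilen))
    feats.extend(f.shifted(site_coordinate) for f in insert_part.features)
    seq = mol.sequence[:site_coordinate] + insert_part.seq + mol.sequence[site_coordinate:]
    return Molecule(mol.id, seq, mol.topology, feats)


def locate_lox(mol: Molecule) -> list[tuple[Feature, LoxSite]]:
    """All lox features in coordinate order with resolved genomic orientation.

    Circular molecules yield a deterministic order (lowest coordinate first
    in the stored linearization, which is itself rotation-normalized by the
    callers that care).
    """
    out = []
    for f in mol.features_of(FeatureKind.LOX):
        site = f.payload
        if not isinstance(site, LoxSite):
            site = parse_lox(mol.feature_seq(f))
        out.append((f, site))
    return out


# ---------------------------------------------------------------------------
# IO: FASTA and GenBank via Biopython
# ---------------------------------------------------------------------------

_KIND_TO_GB = {
    FeatureKind.GENE: "gene",
    FeatureKind.INTRON: "mobile_element",
    FeatureKind.LOX: "misc_feature",
    FeatureKind.PRIMER_SITE: "primer_bind",
    FeatureKind.SCAR: "misc_feature",
}


def to_seqrecord(mol: Molecule) -> SeqRecord:
    rec = SeqRecord(Seq(mol.sequence), id=mol.id, name=mol.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = mol.topology
    for f in mol.features:
        quals = {"label": [f.label], "targetlox_kind": [f.kind.value]}
        if isinstance(f.payload, LoxSite):
            quals["lox_class"] = [f.payload.linker_class]
            quals["lox_arms"] = [
                f"{f.payload.left_arm_state.value}/{f.payload.right_arm_state.value}"
            ]
        if isinstance(f.payload, IntronFragment):
            quals["scaffold"] = [
                f"{f.payload.scaffold_id}:{f.payload.scaffold_start}-{f.payload.scaffold_end}"
            ]
        end = min(f.end, mol.length)  # GenBank locations cannot wrap here
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, end, strand=1 if f.strand == "+" else -1),
                type=_KIND_TO_GB[f.kind],
                qualifiers=quals,
            )
        )
    return rec


def from_seqrecord(rec: SeqRecord) -> Molecule:
    topology = rec.annotations.get("topology", "linear")
    feats: list[Feature] = []
    for sf in rec.features:
        kind_label = sf.qualifiers.get("targetlox_kind", [None])[0]
        if kind_label is None:
            kind_label = {"gene": "gene", "mobile_element": "intron", "primer_bind": "primer_site"}.get(
                sf.type, "scar"
            )
        payload = None
        if kind_label == "lox":
            try:
                payload = parse_lox(str(sf.extract(rec.seq)))
            except Exception:
                payload = None
        if kind_label == "intron" and "scaffold" in sf.qualifiers:
            sid, rng = sf.qualifiers["scaffold"][0].rsplit(":", 1)
            a, b = rng.split("-")
            payload = IntronFragment(sid, int(a), int(b))
        feats.append(
            Feature(
                kind=FeatureKind(kind_label),
                start=int(sf.location.start),
                end=int(sf.location.end),
                strand="+" if (sf.location.strand or 1) >= 0 else "-",
                label=sf.qualifiers.get("label", [""])[0],
                payload=payload,
            )
        )
    return Molecule(rec.id, str(rec.seq), topology, feats)


def write_fasta(mols: list[Molecule], path) -> None:
    SeqIO.write([to_seqrecord(m) for m in mols], path, "fasta")


def write_genbank(mols: list[Molecule], path) -> None:
    SeqIO.write([to_seqrecord(m) for m in mols], path, "genbank")


def read_molecules(path, fmt: str | None = None) -> list[Molecule]:
    if fmt is None:
        fmt = "genbank" if str(path).endswith((".gb", ".gbk", ".genbank")) else "fasta"
    return [from_seqrecord(r) for r in SeqIO.parse(path, fmt)]
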