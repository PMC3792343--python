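"""Intron naming grammar, target-site enumeration, retargeting fragments.

A retargetable group II intron recognizes its DNA insertion site mostly by
base pairing between intron RNA elements (EBS2, EBS1, delta) and target
positions around the insertion point (numbered relative to the junction
between the -1 and +1 bases).  Retargeting therefore means rewriting those
intron elements to complement a chosen target window; the published scoring
algorithms for ranking candidate sites are deliberately not re-implemented
here — templates carry hard constraints plus a pluggable scorer hook.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genome import IntronDesign, Scaffold, default_scaffold
from .lox import revcomp

__all__ = [
    "TargetSite",
    "PairingElement",
    "PairingTemplate",
    "RetargetingFragment",
    "NameError_",
    "parse_intron_name",
    "format_intron_name",
    "enumerate_sites",
    "build_fragment",
    "DEFAULT_TEMPLATES",
]


class NameError_(ValueError):
    """Malformed intron name."""


_NAME_RE = re.compile(r"^(?P<type>[A-Za-z0-9]+)\.(?P<gene>[A-Za-z0-9_-]+)\.(?P<pos>\d+)(?P<strand>[sa])(?:\.(?P<cargo>[A-Za-z0-9]+))?$")

# Short type tokens used in names vs full intron type labels.
_TYPE_ALIASES = {"LtrB": "Ll.LtrB", "Ll.LtrB": "Ll.LtrB", "EcI5": "EcI5"}


def parse_intron_name(name: str) -> tuple[str, str, int, str]:
    """Parse ``TYPE.GENE.POSITION{s|a}[.CARGO]`` into its components.

    The position is 1-based within the gene and 's'/'a' gives the targeted
    strand (sense/antisense).  Known type tokens are expanded (LtrB ->
    Ll.LtrB); unknown tokens pass through unchanged so foreign intron types
    can be named.
    """
    m = _NAME_RE.match(name)
    if m is None:
        bad = name.split(".")[0] if "." not in name else name
        raise NameError_(f"intron name {name!r} does not match TYPE.GENE.POSITION{{s|a}}: offending token {bad!r}")
    itype = _TYPE_ALIASES.get(m.group("type"), m.group("type"))
    return itype, m.group("gene"), int(m.group("pos")), m.group("strand")


def format_intron_name(intron_type: str, gene: str, position: int, strand: str) -> str:
    token = {"Ll.LtrB": "LtrB"}.get(intron_type, intron_type)
    return f"{token}.{gene}.{position}{strand}"


# ---------------------------------------------------------------------------
# Target sites and pairing templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetSite:
    gene: str
    position: int  # 1-based position of the -1 base within the gene
    strand: str  # 's' | 'a'
    window: str  # recognition window around the insertion point

    def __post_init__(self):
        if self.strand not in ("s", "a"):
            raise ValueError("strand must be 's' or 'a'")


@dataclass(frozen=True)
class PairingElement:
    """One intron/target pairing element.

    ``target_range`` is (first, last) inclusive in insertion-point-relative
    numbering (… -2, -1, +1, +2 …; there is no 0).  ``required`` optionally
    pins target bases (position -> base) as a hard constraint.
    """

    name: str  # 'EBS2/IBS2' | 'EBS1/IBS1' | 'delta'
    target_range: tuple[int, int]
    required: dict[int, str] = field(default_factory=dict)


@dataclass(frozen=True)
class PairingTemplate:
    intron_type: str
    elements: tuple[PairingElement, ...]
    window_span: tuple[int, int] = (-30, 15)  # relative positions covered
    scorer: object = None  # optional callable(TargetSite) -> float

    def __post_init__(self):
        taken: set[int] = set()
        lo, hi = self.window_span
        for el in self.elements:
            a, b = el.target_range
            rng = set(_rel_positions(a, b))
            if rng & taken:
                raise ValueError(f"element {el.name} overlaps another element's range")
            if not all(lo <= p <= hi and p != 0 for p in rng):
                raise ValueError(f"element {el.name} range outside recognition window")
            taken |= rng

    @property
    def span_length(self) -> int:
        lo, hi = self.window_span
        return hi - lo  # no position 0

    def rel_to_window_index(self, pos: int) -> int:
        lo = self.window_span[0]
        idx = pos - lo
        return idx if pos < 0 else idx - 1


def _rel_positions(a: int, b: int) -> list[int]:
    return [p for p in range(a, b + 1) if p != 0]


#: Default element geometry per intron type (editable configuration; the
#: ranges follow the published design conventions for each intron family).
DEFAULT_TEMPLATES: dict[str, PairingTemplate] = {
    "Ll.LtrB": PairingTemplate(
        "Ll.LtrB",
        (
            PairingElement("EBS2/IBS2", (-12, -8)),
            PairingElement("EBS1/IBS1", (-6, -1)),
            PairingElement("delta", (1, 1)),
        ),
    ),
    "EcI5": PairingTemplate(
        "EcI5",
        (
            PairingElement("EBS2/IBS2", (-11, -7)),
            PairingElement("EBS1/IBS1", (-6, -1)),
            PairingElement("delta", (1, 3)),
        ),
    ),
}

#: Restriction ends used to clone a retargeted fragment back into its vector.
FRAGMENT_ENDS = {"Ll.LtrB": ("HindIII", "BsrGI"), "EcI5": ("AvaII", "XbaI")}


def enumerate_sites(
    gene_sequence: str, template: PairingTemplate, gene: str = "gene"
) -> list[TargetSite]:
    """Every insertion position on both strands whose recognition window
    satisfies the template's hard constraints, in coordinate order.

    A position ``p`` (1-based, sense strand) denotes insertion between bases
    ``p`` and ``p+1``; windows running off either gene end are skipped.  The
    template's optional scorer does not filter — it only annotates ordering
    downstream tools may use.
    """
    gene_sequence = gene_sequence.upper()
    L = len(gene_sequence)
    lo, hi = template.window_span
    span = template.span_length
    if L < span:
        return []
    out: list[TargetSite] = []
    for strand in ("s", "a"):
        seq = gene_sequence if strand == "s" else revcomp(gene_sequence)
        for p in range(-lo, L - hi + 1):  # p = index of the +1 base in seq
            window = seq[p + lo : p] + seq[p : p + hi]
            ok = True
            for el in template.elements:
                for rel, base in el.required.items():
                    if window[template.rel_to_window_index(rel)] != base:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            pos = p if strand == "s" else L - p  # 1-based -1 position on the sense strand
            out.append(TargetSite(gene=gene, position=pos, strand=strand, window=window))
    out.sort(key=lambda t: (t.position, t.strand))
    return out


# ---------------------------------------------------------------------------
# Fragment construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RetargetingFragment:
    intron_type: str
    fragment_sequence: str
    ends: tuple[str, str]  # restriction-site labels
    primers: tuple[tuple[str, str], ...]  # (name, sequence)
    elements: tuple[tuple[str, str], ...]  # (element name, new intron-side sequence)


def _element_sequences(site: TargetSite, template: PairingTemplate) -> list[tuple[str, str]]:
    """Intron-side sequence of each pairing element: the reverse complement
    of the element's slice of the target window."""
    out = []
    for el in template.elements:
        a, b = el.target_range
        idx = [template.rel_to_window_index(p) for p in _rel_positions(a, b)]
        tgt = "".join(site.window[i] for i in idx)
        if any(c not in "ACGT" for c in tgt):
            raise ValueError(f"target window contains ambiguity codes under {el.name}")
        out.append((el.name, revcomp(tgt)))
    return out


def build_fragment(
    site: TargetSite,
    template: PairingTemplate,
    scaffold: Scaffold | None = None,
) -> RetargetingFragment:
    """Retargeting fragment for one site: element sequences rewritten to
    complement the target window, flanked by the type's cloning ends, with
    the primer set for the type's assembly PCR.

    The fragment is modelled as the concatenation of the rewritten pairing
    elements over a scaffold stub; two-PCR fusion geometry (EcI5) and
    four-primer assembly (Ll.LtrB) differ only in the primer set emitted.
    """
    scaffold = scaffold or default_scaffold(template.intron_type)
    elements = _element_sequences(site, template)
    stub = scaffold.sequence[:60]
    frag = stub + "".join(seq for _, seq in elements) + scaffold.sequence[-60:]
    # Primer sequences: element-bearing oligos in assembly orientation.
    ebs2 = dict(elements)["EBS2/IBS2"]
    ebs1 = dict(elements)["EBS1/IBS1"]
    if template.intron_type == "Ll.LtrB":
        primers = (
            ("IBS", site.window[: len(site.window) // 2]),
            ("EBS2", stub[:20] + ebs2),
            ("EBS1d", ebs1 + scaffold.sequence[-20:]),
            ("EBS2AS", revcomp(stub[:20] + ebs2)),
        )
    else:
        primers = (
            ("IBS1/2S", site.window[: len(site.window) // 2]),
            ("EBS2AS", revcomp(stub[:20] + ebs2)),
            ("EBS1S", ebs1 + scaffold.sequence[-20:]),
            ("EBSR", revcomp(scaffold.sequence[-20:])),
        )
    return RetargetingFragment(
        intron_type=template.intron_type,
        fragment_sequence=frag,
        ends=FRAGMENT_ENDS[template.intron_type],
        primers=primers,
        elements=tuple(elements),
    )


def design_for_site(site: TargetSite, intron_type: str, cargo=()) -> IntronDesign:
    """Convenience: an :class:`IntronDesign` targeting an enumerated site."""
    return IntronDesign(
        intron_type=intron_type,
        target_gene=site.gene,
        target_position=site.position,
        target_strand=site.strand,
        cargo=tuple(cargo),
    )
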