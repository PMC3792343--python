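"""Cre-mediated and host homologous-recombination dynamics over molecules.

The simulator enumerates every eligible Cre event over a multi-molecule
state (excision between same-orientation sites, inversion between
opposite-orientation sites, integration between circles), applies it by
exact sequence surgery, and explores the reachable state space
breadth-first.  Host recombination between homologous intron scaffolds is
modelled as a deterministic post-Cre pass: direct repeats collapse,
adjacent inverted repeats are removed down to a short scar, and separated
inverted repeats invert reversibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

from .genome import (
    Feature,
    FeatureKind,
    GenomeError,
    IntronFragment,
    Molecule,
    Part,
    assemble,
    lox_part,
    molecule_rc,
    part_of,
    rc_part,
)
from .lox import (
    ArmState,
    LoxSite,
    Orientation,
    RecombinationError,
    linker_compatible,
    recombine,
    revcomp,
)

__all__ = [
    "SystemState",
    "CreEvent",
    "HostEvent",
    "OutcomeReport",
    "EditPlan",
    "Participant",
    "DeliveryDesign",
    "DesignError",
    "StateSpaceExceeded",
    "cre_step",
    "cre_closure",
    "host_recombination",
    "host_closure",
    "classify_design",
    "validate_plan",
    "apply_plan",
    "find_inverted_scaffold_repeats",
    "describe_scar",
    "base_counts",
]


class DesignError(ValueError):
    """An edit plan violates the operation's lox compatibility pattern."""


class StateSpaceExceeded(RuntimeError):
    """Breadth-first exploration hit the state bound before closure."""


@dataclass(frozen=True)
class SystemState:
    """A set of molecules (chromosome plus any episomes/excised circles)."""

    molecules: tuple[Molecule, ...]

    def key(self) -> tuple:
        return tuple(sorted(m.canonical_key() for m in self.molecules))

    def total_length(self) -> int:
        return sum(m.length for m in self.molecules)


@dataclass(frozen=True)
class CreEvent:
    kind: str  # 'excision' | 'inversion' | 'integration'
    site_a: str
    site_b: str
    forms_inactive: bool  # a double-mutant (lox72-type) product was created

    def __str__(self) -> str:
        lock = " [locks]" if self.forms_inactive else ""
        return f"{self.kind}({self.site_a} x {self.site_b}){lock}"


@dataclass(frozen=True)
class HostEvent:
    kind: str  # 'collapse' | 'ir_removal' | 'inversion'
    repeat_a: str
    repeat_b: str

    def __str__(self) -> str:
        return f"{self.kind}({self.repeat_a} ~ {self.repeat_b})"


# ---------------------------------------------------------------------------
# Genomic-frame site splitting/joining
# ---------------------------------------------------------------------------


def _gsplit(site: LoxSite):
    """Halves of a site on the genomic (reference) strand, states attached."""
    if site.orientation is Orientation.FORWARD:
        return (
            site.left_arm,
            site.linker,
            site.right_arm,
            site.left_arm_state,
            site.right_arm_state,
        )
    return (
        revcomp(site.right_arm),
        revcomp(site.linker),
        revcomp(site.left_arm),
        site.right_arm_state,
        site.left_arm_state,
    )


def _gjoin(l, k, r, ls, rs, linker_class: str, canonical_linker: str) -> LoxSite:
    """Rebuild a site from genomic-strand halves; orientation follows from
    whether the genomic linker reads in the canonical class orientation."""
    if k == canonical_linker:
        return LoxSite(l, k, r, ls, rs, linker_class, Orientation.FORWARD)
    return LoxSite(revcomp(r), revcomp(k), revcomp(l), rs, ls, linker_class, Orientation.REVERSE)


def _is_locked(*sites: LoxSite) -> bool:
    return any(not s.is_active for s in sites)


def _site_label(feat: Feature, site: LoxSite) -> str:
    return site.name or feat.label or site.linker_class


# ---------------------------------------------------------------------------
# Single Cre events
# ---------------------------------------------------------------------------


def _excise(mol: Molecule, fa: Feature, a: LoxSite, fb: Feature, b: LoxSite):
    """Same-orientation intramolecular event: deletion product + excised circle."""
    al, ak, ar, als, ars = _gsplit(a)
    bl, bk, br, bls, brs = _gsplit(b)
    cls, canon = a.linker_class, a.linker
    keep = _gjoin(al, ak, br, als, brs, cls, canon)
    circ = _gjoin(bl, bk, ar, bls, ars, cls, canon)
    if mol.is_circular:
        chrom = assemble(
            mol.id, [lox_part(keep), part_of(mol, fb.end, fa.start + mol.length)], "circular"
        )
    else:
        chrom = assemble(
            mol.id,
            [part_of(mol, 0, fa.start), lox_part(keep), part_of(mol, fb.end, mol.length)],
            "linear",
        )
    circle = assemble(
        f"{mol.id}.circle", [lox_part(circ), part_of(mol, fa.end, fb.start)], "circular"
    )
    if mol.is_circular and circle.length > chrom.length:
        # Both products are circles; call the larger one the chromosome.
        chrom.id, circle.id = circle.id, chrom.id
        chrom, circle = circle, chrom
    return chrom, circle, (keep, circ)


def _invert(mol: Molecule, fa: Feature, a: LoxSite, fb: Feature, b: LoxSite):
    """Opposite-orientation intramolecular event: invert the intervening span."""
    al, ak, ar, als, ars = _gsplit(a)
    bl, bk, br, bls, brs = _gsplit(b)
    cls, canon = a.linker_class, a.linker
    j1 = _gjoin(al, revcomp(bk), revcomp(bl), als, bls, cls, canon)
    j2 = _gjoin(revcomp(ar), revcomp(ak), br, ars, brs, cls, canon)
    middle = rc_part(part_of(mol, fa.end, fb.start))
    if mol.is_circular:
        prod = assemble(
            mol.id,
            [lox_part(j1), middle, lox_part(j2), part_of(mol, fb.end, fa.start + mol.length)],
            "circular",
        )
    else:
        prod = assemble(
            mol.id,
            [
                part_of(mol, 0, fa.start),
                lox_part(j1),
                middle,
                lox_part(j2),
                part_of(mol, fb.end, mol.length),
            ],
            "linear",
        )
    return prod, (j1, j2)


def _forwardized(mol: Molecule, feat: Feature):
    """Return (molecule, lox feature) with the given site forward-oriented,
    flipping the whole molecule if necessary."""
    site = feat.payload
    if site.orientation is Orientation.FORWARD:
        return mol, feat
    flipped = molecule_rc(mol)
    target = (mol.length - feat.end, mol.length - feat.start)
    for f in flipped.features_of(FeatureKind.LOX):
        if (f.start, f.end) == target:
            return flipped, f
    raise GenomeError("lost track of a lox feature while flipping a molecule")


def _integrate(mol_a: Molecule, fa: Feature, mol_b: Molecule, fb: Feature):
    """Intermolecular event between two circles: fusion into one circle."""
    mol_a, fa = _forwardized(mol_a, fa)
    mol_b, fb = _forwardized(mol_b, fb)
    a, b = fa.payload, fb.payload
    al, ak, ar, als, ars = _gsplit(a)
    bl, bk, br, bls, brs = _gsplit(b)
    cls, canon = a.linker_class, a.linker
    j1 = _gjoin(al, ak, br, als, brs, cls, canon)
    j2 = _gjoin(bl, bk, ar, bls, ars, cls, canon)
    fused = assemble(
        mol_a.id,
        [
            lox_part(j1),
            part_of(mol_b, fb.end, fb.start + mol_b.length),
            lox_part(j2),
            part_of(mol_a, fa.end, fa.start + mol_a.length),
        ],
        "circular",
    )
    return fused, (j1, j2)


def _unwrapped(mol: Molecule) -> Molecule:
    """Rotate a circular molecule so no feature spans the linearization
    junction (surgery assumes in-bounds features)."""
    if not mol.is_circular or all(f.end <= mol.length for f in mol.features):
        return mol
    covered = []
    for f in mol.features:
        covered.append((f.start, min(f.end, mol.length)))
        if f.end > mol.length:  # wrapped tail occupies the start
            covered.append((0, f.end - mol.length))
    pos = 0
    for s, e in sorted(covered):
        if s > pos:
            break
        pos = max(pos, e)
    return mol.rotated(pos % mol.length)


def cre_step(state: SystemState) -> list[tuple[CreEvent, SystemState]]:
    """All successor states one Cre event away.

    One successor per unordered pair of active, linker-compatible lox sites:
    intramolecular same-orientation pairs excise (the excised circle is
    retained in the state), opposite-orientation pairs invert, and pairs on
    two different circles fuse (integration).  Returns an empty list when no
    pair is eligible.
    """
    mols = [_unwrapped(m) for m in state.molecules]
    sites: list[tuple[int, Feature, LoxSite]] = []
    for mi, mol in enumerate(mols):
        for f in mol.features_of(FeatureKind.LOX):
            site = f.payload
            if isinstance(site, LoxSite):
                sites.append((mi, f, site))
    out: list[tuple[CreEvent, SystemState]] = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            mi, fa, a = sites[i]
            mj, fb, b = sites[j]
            if not (a.is_active and b.is_active and linker_compatible(a, b)):
                continue
            if mi == mj:
                if fb.start < fa.start:
                    (fa, a), (fb, b) = (fb, b), (fa, a)
                others = [m for k, m in enumerate(mols) if k != mi]
                if a.orientation is b.orientation:
                    chrom, circle, prods = _excise(mols[mi], fa, a, fb, b)
                    ev = CreEvent("excision", _site_label(fa, a), _site_label(fb, b), _is_locked(*prods))
                    out.append((ev, SystemState(tuple(others + [chrom, circle]))))
                else:
                    prod, prods = _invert(mols[mi], fa, a, fb, b)
                    ev = CreEvent("inversion", _site_label(fa, a), _site_label(fb, b), _is_locked(*prods))
                    out.append((ev, SystemState(tuple(others + [prod]))))
            else:
                if not (mols[mi].is_circular and mols[mj].is_circular):
                    continue  # only circle-circle fusions are modelled
                fused, prods = _integrate(mols[mi], fa, mols[mj], fb)
                others = [m for k, m in enumerate(mols) if k not in (mi, mj)]
                ev = CreEvent(
                    "integration", _site_label(fa, a), _site_label(fb, b), _is_locked(*prods)
                )
                out.append((ev, SystemState(tuple(others + [fused]))))
    out.sort(key=lambda es: (str(es[0]), es[1].key()))
    return out


# ---------------------------------------------------------------------------
# Closure over the Cre transition graph
# ---------------------------------------------------------------------------


@dataclass
class OutcomeReport:
    """Qualitative outcome of a design, in the vocabulary of the method's
    characterization panel."""

    terminal_states: list[SystemState]
    inverted_repeat_generated: bool
    cre_independent_recombination: str  # 'no' | 'yes' | 'some'
    reversible: bool
    scar_length: int | None
    scar_contains_lox: bool | None
    n_states: int = 0
    n_events: int = 0

    def to_dict(self) -> dict:
        return {
            "n_terminal_states": len(self.terminal_states),
            "terminal_molecule_counts": [len(s.molecules) for s in self.terminal_states],
            "inverted_repeat_generated": self.inverted_repeat_generated,
            "cre_independent_recombination": self.cre_independent_recombination,
            "reversible": self.reversible,
            "scar_length": self.scar_length,
            "scar_contains_lox": self.scar_contains_lox,
            "n_states": self.n_states,
            "n_events": self.n_events,
        }


def cre_closure(
    state: SystemState, max_states: int = 10_000, drop_circles: bool = False
) -> OutcomeReport:
    """Breadth-first exploration of all Cre-reachable states.

    Terminal outcomes are the terminal strongly connected components of the
    transition graph: a state with no eligible pair is terminal outright,
    while a set of states locked together by reversible flips (reachable
    only after an irreversible lox72-forming step) is reported once, via its
    lexicographically least member.  ``reversible`` is true iff the initial
    configuration is re-enterable (has a predecessor).  ``drop_circles``
    discards excised circles as they appear (models circle loss instead of
    cut-and-paste re-integration).
    """
    initial_key = state.key()
    states: dict[tuple, SystemState] = {initial_key: state}
    graph = nx.DiGraph()
    graph.add_node(initial_key)
    frontier = [initial_key]
    n_events = 0
    while frontier:
        next_frontier = []
        for key in frontier:
            for event, succ in cre_step(states[key]):
                if drop_circles and event.kind == "excision":
                    keep = tuple(m for m in succ.molecules if not m.id.endswith(".circle"))
                    succ = SystemState(keep)
                skey = succ.key()
                n_events += 1
                if skey not in states:
                    states[skey] = succ
                    next_frontier.append(skey)
                    if len(states) > max_states:
                        raise StateSpaceExceeded(
                            f"more than {max_states} states reachable; raise max_states"
                        )
                graph.add_edge(key, skey)
        frontier = next_frontier

    terminal_keys: list[tuple] = []
    for comp in nx.strongly_connected_components(graph):
        if any(succ not in comp for node in comp for succ in graph.successors(node)):
            continue
        terminal_keys.append(min(comp))
    terminal_keys.sort()
    terminal = [states[k] for k in terminal_keys]

    reversible = graph.in_degree(initial_key) > 0
    ir = any(
        find_inverted_scaffold_repeats(m) for s in terminal for m in s.molecules
    )
    scar_len, scar_lox = (None, None)
    if terminal:
        scar_len, scar_lox = describe_scar(terminal[0])
    return OutcomeReport(
        terminal_states=terminal,
        inverted_repeat_generated=ir,
        cre_independent_recombination="no",
        reversible=reversible,
        scar_length=scar_len,
        scar_contains_lox=scar_lox,
        n_states=len(states),
        n_events=n_events,
    )


# ---------------------------------------------------------------------------
# Host homologous recombination between intron scaffolds
# ---------------------------------------------------------------------------


def _aligned_crossover(f1: Feature, p1: IntronFragment, f2: Feature, p2: IntronFragment):
    """Genomic coordinates in both repeats that map to one shared scaffold
    coordinate (the crossover alignment point)."""
    lo = max(p1.scaffold_start, p2.scaffold_start)
    hi = min(p1.scaffold_end, p2.scaffold_end)
    t = (lo + hi) // 2

    def gcoord(f: Feature, p: IntronFragment) -> int:
        if f.strand == "+":
            return f.start + (t - p.scaffold_start)
        return f.start + (p.scaffold_end - t)

    return gcoord(f1, p1), gcoord(f2, p2)


def host_recombination(
    mol: Molecule,
    min_homology: int = 200,
    adjacent_gap: int = 100,
    scar_len: int = 40,
) -> list[tuple[HostEvent, Molecule]]:
    """Host (RecA-type) recombination events between homologous intron
    scaffold copies on one molecule.

    Direct repeats collapse, deleting one repeat and the intervening
    sequence.  Inverted repeats separated by no more than ``adjacent_gap``
    (e.g. flanking only a lox scar) are removed wholesale, leaving a
    ``scar_len``-nt scaffold remnant carrying no lox site.  Inverted repeats
    further apart invert the intervening segment (a reversible event).
    Homology requires the same scaffold type with at least ``min_homology``
    nt of shared scaffold range; scaffolds of different intron types have no
    usable homology.
    """
    if min_homology < 1:
        raise ValueError("min_homology must be >= 1")
    mol = _unwrapped(mol)
    introns = [
        (f, f.payload)
        for f in mol.features_of(FeatureKind.INTRON)
        if isinstance(f.payload, IntronFragment)
    ]
    out: list[tuple[HostEvent, Molecule]] = []
    for i in range(len(introns)):
        for j in range(i + 1, len(introns)):
            (f1, p1), (f2, p2) = introns[i], introns[j]
            if f2.start < f1.start:
                (f1, p1), (f2, p2) = (f2, p2), (f1, p1)
            if p1.overlap(p2) < min_homology:
                continue
            inner_gap = f2.start - f1.end
            outer_gap = (
                mol.length - f2.end + f1.start if mol.is_circular else None
            )
            if f1.strand == f2.strand:
                x1, x2 = _aligned_crossover(f1, p1, f2, p2)
                if x2 <= x1:
                    continue
                if mol.is_circular:
                    prod = assemble(mol.id, [part_of(mol, x2, x1 + mol.length)], "circular")
                else:
                    prod = assemble(
                        mol.id, [part_of(mol, 0, x1), part_of(mol, x2, mol.length)], "linear"
                    )
                out.append((HostEvent("collapse", f1.label, f2.label), prod))
            elif inner_gap <= adjacent_gap or (
                outer_gap is not None and outer_gap <= adjacent_gap
            ):
                remnant = Part(
                    seq=mol.sequence[f1.start : f1.start + scar_len],
                    features=[
                        Feature(FeatureKind.SCAR, 0, scar_len, "+", "intron_scar")
                    ],
                )
                if inner_gap <= adjacent_gap:
                    if mol.is_circular:
                        parts = [remnant, part_of(mol, f2.end, f1.start + mol.length)]
                    else:
                        parts = [
                            part_of(mol, 0, f1.start),
                            remnant,
                            part_of(mol, f2.end, mol.length),
                        ]
                else:
                    # repeats adjacent across the circular origin: remove the
                    # wrap-spanning repeat structure, keep the inner arc
                    parts = [remnant, part_of(mol, f1.end, f2.start)]
                prod = assemble(mol.id, parts, mol.topology)
                out.append((HostEvent("ir_removal", f1.label, f2.label), prod))
            else:
                x1, x2 = _aligned_crossover(f1, p1, f2, p2)
                if x2 <= x1:
                    continue
                if mol.is_circular:
                    parts = [
                        rc_part(part_of(mol, x1, x2)),
                        part_of(mol, x2, x1 + mol.length),
                    ]
                else:
                    parts = [
                        part_of(mol, 0, x1),
                        rc_part(part_of(mol, x1, x2)),
                        part_of(mol, x2, mol.length),
                    ]
                prod = assemble(mol.id, parts, mol.topology)
                out.append((HostEvent("inversion", f1.label, f2.label), prod))
    out.sort(key=lambda em: (str(em[0]), em[1].canonical_key()))
    return out


def host_closure(state: SystemState, **kwargs) -> SystemState:
    """Deterministic post-Cre pass applying irreversible host events
    (adjacent inverted-repeat removal first, then direct-repeat collapse of
    *identical adjacent* leftovers is left alone: only ``ir_removal`` events
    are applied, repeatedly, until none remain)."""
    mols = list(state.molecules)
    changed = True
    while changed:
        changed = False
        for idx, m in enumerate(mols):
            evs = [em for em in host_recombination(m, **kwargs) if em[0].kind == "ir_removal"]
            if evs:
                mols[idx] = evs[0][1]
                changed = True
                break
    return SystemState(tuple(mols))


def find_inverted_scaffold_repeats(
    mol: Molecule, min_homology: int = 200, max_gap: int = 100
) -> list[tuple[str, str]]:
    """Adjacent inverted repeats of intron scaffold sequence (the structures
    the host subsequently deletes)."""
    mol = _unwrapped(mol)
    introns = [
        (f, f.payload)
        for f in mol.features_of(FeatureKind.INTRON)
        if isinstance(f.payload, IntronFragment)
    ]
    introns.sort(key=lambda fp: fp[0].start)
    pairs = []
    for i in range(len(introns)):
        for j in range(i + 1, len(introns)):
            (f1, p1), (f2, p2) = introns[i], introns[j]
            if f1.strand == f2.strand or p1.overlap(p2) < min_homology:
                continue
            inner_gap = f2.start - f1.end
            adjacent = 0 <= inner_gap <= max_gap
            if mol.is_circular and not adjacent:
                adjacent = 0 <= mol.length - f2.end + f1.start <= max_gap
            if adjacent:
                pairs.append((f1.label, f2.label))
    return pairs


def describe_scar(state: SystemState) -> tuple[int | None, bool | None]:
    """Length of the largest contiguous non-native run (intron/lox/scar
    features) on the first chromosome-like molecule, and whether it contains
    a lox site."""
    chroms = [m for m in state.molecules if ".circle" not in m.id]
    mol = max(chroms or state.molecules, key=lambda m: m.length)
    marks = sorted(
        (f.start, f.end, f.kind)
        for f in mol.features
        if f.kind in (FeatureKind.INTRON, FeatureKind.LOX, FeatureKind.SCAR)
    )
    if not marks:
        return None, None
    runs: list[list] = []  # [start, end, has_lox]
    for s, e, kind in marks:
        if runs and s <= runs[-1][1]:
            runs[-1][1] = max(runs[-1][1], e)
            runs[-1][2] = runs[-1][2] or kind is FeatureKind.LOX
        else:
            runs.append([s, e, kind is FeatureKind.LOX])
    if (
        mol.is_circular
        and len(runs) > 1
        and runs[0][0] == 0
        and runs[-1][1] >= mol.length
    ):
        # merge the run spanning the circular origin
        runs[0] = [runs[-1][0] - mol.length, runs[0][1], runs[0][2] or runs[-1][2]]
        runs.pop()
    length, has_lox = max((e - s, lox) for s, e, lox in runs)
    return length, has_lox


def base_counts(state: SystemState) -> dict[str, int]:
    """Base-pair composition over all molecules, counted double-strandedly
    (A with T, G with C), which every Cre event conserves — segments are
    rearranged or flipped, never created or destroyed."""
    counts = {"A/T": 0, "G/C": 0}
    for m in state.molecules:
        for c in m.sequence:
            counts["A/T" if c in "AT" else "G/C"] += 1
    return counts


# ---------------------------------------------------------------------------
# Edit plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Participant:
    locus: str
    design: "IntronDesign"


@dataclass(frozen=True)
class DeliveryDesign:
    """Synthetic delivery plasmid for cassette exchange: cargo flanked by a
    pair of lox sites, on a circular backbone."""

    sites: tuple[LoxSite, LoxSite]
    cargo_length: int = 1000
    backbone_length: int = 3000


@dataclass(frozen=True)
class EditPlan:
    """Declarative description of one genome edit.

    ``regions`` holds (upstream, downstream) participant pairs flanking each
    region to be deleted/inverted/cut; ``target`` is the landing participant
    for cut-and-paste or the lox-delivering participant for cassette
    exchange; ``delivery`` describes the exchange plasmid.
    """

    operation: str  # 'rmce_insertion' | 'deletion' | 'inversion' | 'cut_and_paste'
    regions: tuple[tuple[Participant, Participant], ...] = ()
    target: Participant | None = None
    delivery: DeliveryDesign | None = None

    def participants(self) -> list[Participant]:
        out = [p for pair in self.regions for p in pair]
        if self.target is not None:
            out.append(self.target)
        return out


def _genomic_orientation(design) -> Orientation:
    """Genomic orientation of a single-lox cargo: cargo orientation composed
    with the insertion strand."""
    (site,) = design.cargo
    if design.target_strand == "a":
        return site.orientation.flipped()
    return site.orientation


def _symbolic_pair(up, down):
    """Site-frame normalized (upstream, downstream) sites as they will sit on
    the genome, for symbolic product prediction."""
    u = up.design.cargo[0].oriented(_genomic_orientation(up.design))
    d = down.design.cargo[0].oriented(_genomic_orientation(down.design))
    return u, d


def _symbolic_excision_products(u: LoxSite, d: LoxSite) -> tuple[LoxSite, LoxSite]:
    """(chromosomal scar, circle site) for a same-orientation pair."""
    ul = _gsplit(u)
    dl = _gsplit(d)
    scar = _gjoin(ul[0], ul[1], dl[2], ul[3], dl[4], u.linker_class, u.linker)
    circ = _gjoin(dl[0], dl[1], ul[2], dl[3], ul[4], u.linker_class, u.linker)
    return scar, circ


def validate_plan(plan: EditPlan) -> None:
    """Check the operation's lox compatibility pattern before simulation.

    Raises :class:`DesignError` with an explanation on any violation;
    cross-reactivity between simultaneous edits is an error, not a warning.
    """
    op = plan.operation
    if op not in ("rmce_insertion", "deletion", "inversion", "cut_and_paste"):
        raise DesignError(f"unknown operation {op!r}")

    if op == "deletion":
        if not plan.regions:
            raise DesignError("deletion plan needs at least one region")
        classes = []
        for up, down in plan.regions:
            u, d = _symbolic_pair(up, down)
            if u.orientation is not d.orientation:
                raise DesignError(
                    f"region {up.locus}-{down.locus}: deletion requires both lox sites "
                    "in the same genomic orientation"
                )
            if not linker_compatible(u, d):
                raise DesignError(
                    f"region {up.locus}-{down.locus}: lox linker classes "
                    f"{u.linker_class!r}/{d.linker_class!r} cannot recombine"
                )
            if not (u.is_active and d.is_active):
                raise DesignError(f"region {up.locus}-{down.locus}: inactive lox site in plan")
            scar, _ = _symbolic_excision_products(u, d)
            if scar.is_active:
                raise DesignError(
                    f"region {up.locus}-{down.locus}: the chromosomal scar would stay "
                    "Cre-active; place the mutant arms outside the region "
                    "(left-arm mutant upstream, right-arm mutant downstream) so the "
                    "scar is a double-mutant lox72-type site"
                )
            classes.append(u.linker_class)
        if len(plan.regions) > 1 and len(set(classes)) != len(classes):
            dup = sorted({c for c in classes if classes.count(c) > 1})
            raise DesignError(
                "simultaneous deletions must use mutually incompatible linker "
                f"classes; class(es) {dup} re-used across regions"
            )

    elif op == "inversion":
        if len(plan.regions) != 1:
            raise DesignError("inversion plan needs exactly one region")
        up, down = plan.regions[0]
        u, d = _symbolic_pair(up, down)
        if u.orientation is d.orientation:
            raise DesignError("inversion requires opposing lox orientations")
        if not linker_compatible(u, d):
            raise DesignError("inversion lox pair has incompatible linkers")
        if not (u.is_active and d.is_active):
            raise DesignError("inactive lox site in inversion plan")

    elif op == "cut_and_paste":
        if len(plan.regions) != 1 or plan.target is None:
            raise DesignError("cut-and-paste needs one flanked region plus a target site")
        up, down = plan.regions[0]
        u, d = _symbolic_pair(up, down)
        t = plan.target.design.cargo[0].oriented(_genomic_orientation(plan.target.design))
        if u.orientation is not d.orientation:
            raise DesignError("cut-and-paste flanking sites must share an orientation")
        if not (linker_compatible(u, d) and linker_compatible(u, t)):
            raise DesignError("all three cut-and-paste sites must share a linker class")
        scar, circ = _symbolic_excision_products(u, d)
        if not (scar.is_active and circ.is_active):
            raise DesignError(
                "the cut must stay reversible: neither the cut scar nor the excised "
                "circle's site may be a double mutant"
            )
        try:
            p1, p2 = recombine(circ, t)
        except RecombinationError as exc:
            raise DesignError(f"excised circle cannot re-insert at target: {exc}") from exc
        if p1.is_active and p2.is_active:
            raise DesignError(
                "reinsertion at the target must form a lox72-type site to lock the "
                "paste; pair complementary arm mutants on the circle-borne site and "
                "the target site"
            )

    elif op == "rmce_insertion":
        if plan.target is None or plan.delivery is None:
            raise DesignError("cassette exchange needs a genomic target and a delivery design")
        cargo = plan.target.design.cargo
        if len(cargo) != 2:
            raise DesignError("cassette exchange delivers exactly two lox sites to the genome")
        g1, g2 = cargo
        if linker_compatible(g1, g2):
            raise DesignError(
                "the genomic lox pair must use incompatible linker classes to prevent "
                "deletion/inversion between them"
            )
        d1, d2 = plan.delivery.sites
        by_class = {s.linker_class: s for s in (d1, d2)}
        for g in (g1, g2):
            partner = by_class.get(g.linker_class)
            if partner is None:
                raise DesignError(
                    f"delivery plasmid lacks a partner for genomic class {g.linker_class!r}"
                )
            p1, p2 = recombine(g, partner)
            if p1.is_active and p2.is_active:
                raise DesignError(
                    f"class {g.linker_class!r}: genomic/delivery pair must carry "
                    "complementary arm mutants so exchange forms a lox72-type site"
                )


def apply_plan(genome: Molecule, plan: EditPlan, delivery_molecule: Molecule | None = None):
    """Place the plan's introns on the genome (the 'uninduced' state).

    Returns a :class:`SystemState` containing the edited genome plus the
    delivery molecule for cassette exchange plans.
    """
    from .genome import insert_intron

    mol = genome
    for part in plan.participants():
        genes = [f for f in mol.features_of(FeatureKind.GENE) if f.label == part.locus]
        if not genes:
            raise DesignError(f"genome has no locus named {part.locus!r}")
        gene = genes[0]
        pos = part.design.target_position
        if not 1 <= pos <= gene.length:
            raise DesignError(
                f"{part.locus}: position {pos} outside gene of length {gene.length}"
            )
        coord = gene.start + pos if gene.strand == "+" else gene.end - pos
        mol = insert_intron(mol, coord, part.design)
    mols = [mol]
    if plan.operation == "rmce_insertion":
        if delivery_molecule is None:
            from .fixtures import make_delivery_plasmid

            delivery_molecule = make_delivery_plasmid(plan.delivery)
        mols.append(delivery_molecule)
    return SystemState(tuple(mols))


def _intron_instances(state: SystemState):
    """Group intron fragments by intron instance (label prefix); return
    [(label, scaffold_id, genomic strand of the scaffold 5' fragment)]."""
    out = []
    for mol in state.molecules:
        groups: dict[str, list[Feature]] = {}
        for f in mol.features_of(FeatureKind.INTRON):
            groups.setdefault(f.label.rsplit(":", 1)[0], []).append(f)
        for label, feats in groups.items():
            frag = feats[0].payload
            out.append((label, frag.scaffold_id, feats[0].strand))
    return out


def classify_design(
    plan: EditPlan,
    genome: Molecule | None = None,
    max_states: int = 10_000,
    min_homology: int = 200,
) -> OutcomeReport:
    """Predict the qualitative outcome of an edit plan.

    Simulates Cre closure from the uninduced state, scans the terminal
    states for inverted scaffold repeats, and decides whether host
    recombination alone (no Cre) could produce the designed class of event:
    that requires homologous introns *and* an orientation permitting the
    event (direct repeats for a deletion-like collapse, inverted repeats for
    an inversion).  For cut-and-paste, host recombination can at most mimic
    part of the rearrangement, reported as ``'some'``.
    """
    validate_plan(plan)
    if genome is None:
        from .fixtures import FixtureSpec, make_genome

        loci = sorted({p.locus for p in plan.participants()})
        genome, _ = make_genome(FixtureSpec(seed=0, loci=tuple(loci)))
    state = apply_plan(genome, plan)
    report = cre_closure(state, max_states=max_states)

    instances = _intron_instances(state)
    direct = inverted = False
    for i in range(len(instances)):
        for j in range(i + 1, len(instances)):
            la, sa, stra = instances[i]
            lb, sb, strb = instances[j]
            if sa != sb:
                continue
            if stra == strb:
                direct = True
            else:
                inverted = True
    if plan.operation == "deletion":
        report.cre_independent_recombination = "yes" if direct else "no"
    elif plan.operation == "inversion":
        report.cre_independent_recombination = "yes" if inverted else "no"
    elif plan.operation == "cut_and_paste":
        report.cre_independent_recombination = "some" if (direct or inverted) else "no"
    else:
        report.cre_independent_recombination = "no"
    return report
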