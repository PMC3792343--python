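"""Diagnostic colony-PCR planning and exact in-silico PCR.

Each edit is characterized across three strain states: W (wild type),
U (uninduced: introns and lox sites placed, no Cre) and I (induced: after
Cre).  Primer names follow the locus-letter + u/d grammar (first letter =
genomic location, 'u'/'d' = up/down primer); products are named
``<fwd>/<rev>``.  Assay structure per operation:

* deletion: two amplicons bridging the flanking insertion sites plus one
  bridging the expected deletion junction (3 assays)
* inversion: the two insertion bridges plus two amplicons bridging the new
  ends of the inversion (4 assays)
* cut-and-paste: three insertion bridges, one cut bridge, two paste
  boundary bridges (6 assays)
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import FeatureKind, Molecule
from .lox import revcomp
from .simulate import (
    DesignError,
    EditPlan,
    SystemState,
    apply_plan,
    cre_closure,
    host_closure,
    validate_plan,
)

__all__ = [
    "PrimerPair",
    "Assay",
    "AssayPlan",
    "insilico_pcr",
    "design_assays",
    "predict_signature",
    "simulate_states",
]

STATES = ("W", "U", "I")


@dataclass(frozen=True)
class PrimerPair:
    forward_name: str
    forward_seq: str
    reverse_name: str
    reverse_seq: str

    @property
    def name(self) -> str:
        return f"{self.forward_name}/{self.reverse_name}"


@dataclass(frozen=True)
class Assay:
    pair: PrimerPair
    role: str  # 'insertion_bridge' | 'junction' | 'cut_bridge' | 'paste_bridge'
    locus: str


@dataclass
class AssayPlan:
    operation: str
    assays: list[Assay]

    def __len__(self) -> int:
        return len(self.assays)


# ---------------------------------------------------------------------------
# Exact in-silico PCR
# ---------------------------------------------------------------------------


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def insilico_pcr(
    mol: Molecule, pair: PrimerPair, max_product: int = 5000
) -> list[tuple[int, int, int]]:
    """All products of exact-match PCR on one molecule.

    A product forms when the forward primer anneals on one strand and the
    reverse primer on the other, convergently, within ``max_product``.
    Circular molecules are searched across the origin.  Returns
    ``(start, end, size)`` triplets in reference coordinates (end may exceed
    the length for origin-spanning products on circles); an empty list means
    no band.
    """
    f, r = pair.forward_seq.upper(), pair.reverse_seq.upper()
    if min(len(f), len(r)) < 15:
        raise ValueError("primers must be at least 15 nt")
    L = mol.length
    seq = mol.sequence
    hay = seq + seq[: min(L, max_product)] if mol.is_circular else seq
    products = set()
    # forward primer on + strand extends right; reverse primer site is where
    # rc(reverse) occurs on the + strand.  Also try the swapped assignment
    # (forward on - strand), which is the same product scanned from the
    # other side.
    for fs, rs in ((f, r), (r, f)):
        starts = _find_all(hay, fs)
        ends = _find_all(hay, revcomp(rs))
        for i in starts:
            if i >= L:
                continue
            for j in ends:
                size = j + len(rs) - i
                if i <= j and 0 < size <= max_product and size <= L:
                    products.add((i, i + size, size))
    return sorted(products)


# ---------------------------------------------------------------------------
# Primer placement
# ---------------------------------------------------------------------------


def _unique_kmer(
    genome: Molecule, lo: int, hi: int, k: int, strand: str, leftmost: bool = True
) -> str | None:
    """Leftmost k-mer in genome window [lo, hi) that occurs exactly once
    genome-wide (both strands); returned in primer (5'->3') orientation."""
    seq = genome.sequence
    both = seq + ("" if not genome.is_circular else seq[: k - 1])
    rc_both = revcomp(both)
    positions = range(lo, hi - k) if leftmost else range(hi - k - 1, lo - 1, -1)
    for s in positions:
        kmer = seq[s : s + k]
        if len(kmer) < k or "N" in kmer:
            continue
        if both.count(kmer) + rc_both.count(kmer) == 1:
            return kmer if strand == "+" else revcomp(kmer)
    return None


def _locus_primers(genome: Molecule, locus: str, window: int = 300, k: int = 20):
    """(u, d) primers flanking a locus: 'u' anneals upstream pointing into
    the locus (+ strand), 'd' downstream pointing back (- strand)."""
    genes = [f for f in genome.features_of(FeatureKind.GENE) if f.label == locus]
    if not genes:
        raise DesignError(f"no locus {locus!r} for primer design")
    g = genes[0]
    up = _unique_kmer(genome, max(0, g.start - window), g.start, k, "+")
    down = _unique_kmer(genome, g.end, min(genome.length, g.end + window), k, "-", leftmost=False)
    if up is None or down is None:
        raise DesignError(f"no unique primer placement within {window} nt of locus {locus!r}")
    letter = locus[0].upper() if locus != "lacZ" else "L"
    return (f"{letter}u", up), (f"{letter}d", down)


# ---------------------------------------------------------------------------
# Assay design and signatures
# ---------------------------------------------------------------------------


def simulate_states(
    plan: EditPlan, genome: Molecule, max_states: int = 10_000
) -> dict[str, SystemState]:
    """W/U/I states for a plan: wild type, introns placed, post-Cre (with the
    host inverted-repeat removal pass applied)."""
    validate_plan(plan)
    u_state = apply_plan(genome, plan)
    report = cre_closure(u_state, max_states=max_states)
    induced = host_closure(report.terminal_states[0])
    return {
        "W": SystemState((genome,)),
        "U": u_state,
        "I": induced,
    }


def _bridge(genome: Molecule, a: str, b: str) -> PrimerPair:
    (fa_name, fa), _ = _locus_primers(genome, a)
    _, (rb_name, rb) = _locus_primers(genome, b)
    return PrimerPair(fa_name, fa, rb_name, rb)


def design_assays(
    plan: EditPlan, genome: Molecule, max_product: int = 5000
) -> AssayPlan:
    """PCR plan for one edit: primers in unique flanking sequence outside
    the introns, with assay structure fixed by the operation type."""
    validate_plan(plan)
    assays: list[Assay] = []

    def primers(locus):
        return _locus_primers(genome, locus)

    if plan.operation == "deletion":
        for up, down in plan.regions:
            (xu, xus), (xd, xds) = primers(up.locus)
            (yu, yus), (yd, yds) = primers(down.locus)
            assays.append(Assay(PrimerPair(xu, xus, xd, xds), "insertion_bridge", up.locus))
            assays.append(Assay(PrimerPair(yu, yus, yd, yds), "insertion_bridge", down.locus))
            assays.append(
                Assay(PrimerPair(xu, xus, yd, yds), "junction", f"{up.locus}-{down.locus}")
            )
    elif plan.operation == "inversion":
        (up, down), = plan.regions
        (xu, xus), (xd, xds) = primers(up.locus)
        (yu, yus), (yd, yds) = primers(down.locus)
        assays.append(Assay(PrimerPair(xu, xus, xd, xds), "insertion_bridge", up.locus))
        assays.append(Assay(PrimerPair(yu, yus, yd, yds), "insertion_bridge", down.locus))
        # After inversion the segment between the sites flips, so the 'u'
        # primer of one locus converges with the 'u' primer of the other
        # (and 'd' with 'd') across the new ends.
        assays.append(Assay(PrimerPair(xu, xus, yu, yus), "junction", f"{up.locus}-{down.locus}:left"))
        assays.append(Assay(PrimerPair(xd, xds, yd, yds), "junction", f"{up.locus}-{down.locus}:right"))
    elif plan.operation == "cut_and_paste":
        (up, down), = plan.regions
        tgt = plan.target
        (xu, xus), (xd, xds) = primers(up.locus)
        (yu, yus), (yd, yds) = primers(down.locus)
        (zu, zus), (zd, zds) = primers(tgt.locus)
        assays.append(Assay(PrimerPair(xu, xus, xd, xds), "insertion_bridge", up.locus))
        assays.append(Assay(PrimerPair(yu, yus, yd, yds), "insertion_bridge", down.locus))
        assays.append(Assay(PrimerPair(zu, zus, zd, zds), "insertion_bridge", tgt.locus))
        assays.append(Assay(PrimerPair(xu, xus, yd, yds), "cut_bridge", f"{up.locus}-{down.locus}"))
        # Paste boundaries: pick the two convergent combinations of target
        # primers with cut-region flanking primers that actually produce a
        # band on the simulated induced state.
        states = simulate_states(plan, genome)
        induced = states["I"]
        flank_primers = ((xu, xus), (xd, xds), (yu, yus), (yd, yds))
        hits = []
        for zn, zs in ((zu, zus), (zd, zds)):
            for on, os_ in flank_primers:
                cand = PrimerPair(zn, zs, on, os_)
                if any(insilico_pcr(m, cand, max_product) for m in induced.molecules):
                    hits.append(cand)
                    break
        if len(hits) < 2:
            raise DesignError("could not find two paste-boundary amplicons on the induced state")
        for cand in hits:
            assays.append(Assay(cand, "paste_bridge", tgt.locus))
    elif plan.operation == "rmce_insertion":
        tgt = plan.target
        (zu, zus), (zd, zds) = primers(tgt.locus)
        assays.append(Assay(PrimerPair(zu, zus, zd, zds), "insertion_bridge", tgt.locus))
    else:
        raise DesignError(f"no assay template for operation {plan.operation!r}")
    return AssayPlan(plan.operation, assays)


def predict_signature(
    plan: EditPlan,
    states: dict[str, SystemState],
    assay_plan: AssayPlan | None = None,
    genome: Molecule | None = None,
    max_product: int = 5000,
) -> dict[str, dict[str, list[int]]]:
    """Band sizes per assay per strain state.

    Returns ``{assay name: {state: [sizes]}}``; an empty list is no band.
    An insertion bridge gains roughly the intron insert length between W and
    U and disappears in I when the bridged region is deleted or inverted.
    """
    if assay_plan is None:
        if genome is None:
            raise ValueError("need either an assay plan or a genome to design one")
        assay_plan = design_assays(plan, genome, max_product)
    table: dict[str, dict[str, list[int]]] = {}
    for assay in assay_plan.assays:
        row: dict[str, list[int]] = {}
        for state_name in STATES:
            sizes: set[int] = set()
            for mol in states[state_name].molecules:
                for _, _, size in insilico_pcr(mol, assay.pair, max_product):
                    sizes.add(size)
            row[state_name] = sorted(sizes)
        table[assay.pair.name] = row
    return table
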