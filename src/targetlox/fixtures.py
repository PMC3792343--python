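"""Deterministic seeded generators for every input class.

Everything here is a pure function of (spec, seed): synthetic circular
chromosomes with named loci and unique primer-design flanks, delivery
plasmids for cassette exchange, ready-made edit plans for the method's four
operations, and three-phase plate-reader growth curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import (
    Feature,
    FeatureKind,
    GenomeError,
    IntronDesign,
    Molecule,
)
from .lox import LoxCatalog, LoxSite, Orientation
from .simulate import DeliveryDesign, EditPlan, Participant

__all__ = [
    "FixtureSpec",
    "GrowthSpec",
    "make_genome",
    "make_delivery_plasmid",
    "make_growth_curves",
    "make_plan",
    "rearrangement_panel",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic circular chromosome with named loci."""

    seed: int = 0
    length: int = 30_000
    topology: str = "circular"
    # physical order around the circle; lacZ sits next to A as in the real
    # locus layout, so A-lacZ regions are short arcs
    loci: tuple[str, ...] = ("A", "lacZ", "B", "C", "D", "E")
    gene_length: int = 900
    barcode_length: int = 25

    def __post_init__(self):
        if self.length < len(self.loci) * (self.gene_length + 4 * self.barcode_length):
            raise GenomeError("loci do not fit in the requested genome length")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def make_genome(spec: FixtureSpec) -> tuple[Molecule, dict]:
    """Random circular chromosome with uniformly spaced gene loci.

    Each locus is a gene flanked by distinct random barcodes, which makes
    primer design trivially unique.  Returns the molecule plus a manifest
    recording every planted feature.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xF1C5]))
    seq = list(_random_seq(rng, spec.length))
    n = len(spec.loci)
    spacing = spec.length // n
    feats: list[Feature] = []
    manifest: dict = {"seed": spec.seed, "length": spec.length, "loci": {}}
    for i, locus in enumerate(spec.loci):
        start = i * spacing + spacing // 4
        end = start + spec.gene_length
        # Distinct barcodes just outside the gene guarantee unique 20-mers for
        # primer placement on both sides of every locus.
        up_bc = _random_seq(rng, spec.barcode_length)
        down_bc = _random_seq(rng, spec.barcode_length)
        seq[start - spec.barcode_length : start] = list(up_bc)
        seq[end : end + spec.barcode_length] = list(down_bc)
        feats.append(Feature(FeatureKind.GENE, start, end, "+", locus))
        manifest["loci"][locus] = {"start": start, "end": end, "strand": "+"}
    mol = Molecule("synthetic_chromosome", "".join(seq), spec.topology, feats)
    return mol, manifest


def make_delivery_plasmid(
    design: DeliveryDesign, seed: int = 1729, plasmid_id: str = "delivery"
) -> Molecule:
    """Circular delivery plasmid: random backbone, then lox-cargo-lox."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDE11]))
    backbone = _random_seq(rng, design.backbone_length)
    cargo = _random_seq(rng, design.cargo_length)
    s1, s2 = design.sites
    seq = backbone + s1.sequence() + cargo + s2.sequence()
    b = design.backbone_length
    feats = [
        Feature(
            FeatureKind.LOX,
            b,
            b + 34,
            "+" if s1.orientation is Orientation.FORWARD else "-",
            s1.name or "lox_left",
            payload=s1,
        ),
        Feature(FeatureKind.GENE, b + 34, b + 34 + design.cargo_length, "+", "cargo"),
        Feature(
            FeatureKind.LOX,
            b + 34 + design.cargo_length,
            b + 68 + design.cargo_length,
            "+" if s2.orientation is Orientation.FORWARD else "-",
            s2.name or "lox_right",
            payload=s2,
        ),
    ]
    return Molecule(plasmid_id, seq, "circular", feats)


# ---------------------------------------------------------------------------
# Plan builders
# ---------------------------------------------------------------------------


def _participant(
    locus: str,
    site: LoxSite | str,
    intron_type: str = "EcI5",
    strand: str = "s",
    cargo_orientation: str = "forward",
    position: int = 450,
    catalog: LoxCatalog | None = None,
) -> Participant:
    catalog = catalog or LoxCatalog.default()
    if isinstance(site, str):
        site = catalog[site]
    site = site.oriented(Orientation(cargo_orientation))
    design = IntronDesign(
        intron_type=intron_type,
        target_gene=locus,
        target_position=position,
        target_strand=strand,
        cargo=(site,),
    )
    return Participant(locus, design)


def make_plan(
    operation: str,
    loci: tuple[str, ...] = ("A", "lacZ"),
    intron_types: tuple[str, ...] | None = None,
    strands: tuple[str, ...] | None = None,
    catalog: LoxCatalog | None = None,
) -> EditPlan:
    """Canonical edit plan for one operation on the named loci.

    Deletion/cut regions carry the mutant arms arranged so Cre leaves a
    lox72-type scar (deletion) or keeps the cut reversible and locks the
    paste (cut-and-paste); inversions use the lox71/lox66 pair in opposing
    orientations.  ``strands`` sets each intron's insertion strand ('s'/'a');
    cargo orientations are then chosen to satisfy the operation's required
    genomic lox orientations.
    """
    catalog = catalog or LoxCatalog.default()
    n = len(loci)
    intron_types = intron_types or ("EcI5",) * n
    strands = strands or ("s",) * n

    def orient_for(genomic: str, strand: str) -> str:
        # cargo orientation that yields the requested genomic orientation
        if strand == "s":
            return genomic
        return "reverse" if genomic == "forward" else "forward"

    if operation == "deletion":
        if n % 2:
            raise ValueError("deletion loci come in flanking pairs")
        classes = ["", "2272", "N"]  # mutually incompatible linker classes
        regions = []
        for r in range(n // 2):
            cls = classes[r % 3]
            up_name = "lox71" if not cls else f"lox{cls}"
            # Per-class arm-mutant pair: left-arm mutant upstream, right-arm
            # mutant downstream.  For non-P classes the catalogue wild-type
            # site is substituted by on-the-fly arm variants.
            if not cls:
                up_site, down_site = catalog["lox71"], catalog["lox66"]
            else:
                base = catalog[f"lox{cls}"]
                p71, p66 = catalog["lox71"], catalog["lox66"]
                up_site = replace(
                    base,
                    left_arm=p71.left_arm,
                    left_arm_state=p71.left_arm_state,
                    name=f"lox{cls}/71",
                )
                down_site = replace(
                    base,
                    right_arm=p66.right_arm,
                    right_arm_state=p66.right_arm_state,
                    name=f"lox{cls}/66",
                )
            i, j = 2 * r, 2 * r + 1
            regions.append(
                (
                    _participant(
                        loci[i], up_site, intron_types[i], strands[i],
                        orient_for("forward", strands[i]), catalog=catalog,
                    ),
                    _participant(
                        loci[j], down_site, intron_types[j], strands[j],
                        orient_for("forward", strands[j]), catalog=catalog,
                    ),
                )
            )
        return EditPlan("deletion", tuple(regions))

    if operation == "inversion":
        up = _participant(
            loci[0], "lox71", intron_types[0], strands[0],
            orient_for("forward", strands[0]), catalog=catalog,
        )
        down = _participant(
            loci[1], "lox66", intron_types[1], strands[1],
            orient_for("reverse", strands[1]), catalog=catalog,
        )
        return EditPlan("inversion", ((up, down),))

    if operation == "cut_and_paste":
        if n != 3:
            raise ValueError("cut-and-paste needs (upstream, downstream, target) loci")
        up = _participant(
            loci[0], "lox66", intron_types[0], strands[0],
            orient_for("forward", strands[0]), catalog=catalog,
        )
        down = _participant(
            loci[1], "loxP", intron_types[1], strands[1],
            orient_for("forward", strands[1]), catalog=catalog,
        )
        target = _participant(
            loci[2], "lox71", intron_types[2], strands[2],
            orient_for("reverse", strands[2]), catalog=catalog,
        )
        return EditPlan("cut_and_paste", ((up, down),), target=target)

    if operation == "rmce_insertion":
        # Class order and arm mutants arranged so the exchanged cassette ends
        # up flanked by the two dead sites (lox72-type and m2 double mutant)
        # while the released backbone circle carries the active ones.
        g1 = catalog["loxm2/71"].oriented(Orientation.FORWARD)
        g2 = catalog["lox66"].oriented(Orientation.FORWARD)
        design = IntronDesign(
            intron_type=intron_types[0],
            target_gene=loci[0],
            target_position=450,
            target_strand=strands[0],
            cargo=(g1, g2),
        )
        delivery = DeliveryDesign(
            sites=(
                catalog["loxm2/66"].oriented(Orientation.FORWARD),
                catalog["lox71"].oriented(Orientation.FORWARD),
            )
        )
        return EditPlan(
            "rmce_insertion", (), target=Participant(loci[0], design), delivery=delivery
        )

    raise ValueError(f"unknown operation {operation!r}")


def rearrangement_panel() -> list[tuple[str, EditPlan]]:
    """The twelve characterized intragenomic rearrangement designs.

    Loci, operation and intron types follow the published strain panel; the
    insertion strands are reconstructed so that each design's repeat
    geometry matches its characterization (intron identities and
    orientations beyond the main text live in supplementary material, so
    orientation is the reconstructed degree of freedom).
    """
    rows = [
        # (label, op, loci, intron types, strands)
        ("del_A_lacZ_homologous", "deletion", ("A", "lacZ"), ("Ll.LtrB", "Ll.LtrB"), ("s", "s")),
        ("del_A_lacZ_nonhomologous", "deletion", ("A", "lacZ"), ("Ll.LtrB", "EcI5"), ("s", "s")),
        ("del_B_C", "deletion", ("B", "C"), ("EcI5", "EcI5"), ("s", "a")),
        ("del_D_E", "deletion", ("D", "E"), ("EcI5", "EcI5"), ("s", "a")),
        ("inv_A_lacZ_unstable", "inversion", ("A", "lacZ"), ("EcI5", "EcI5"), ("s", "s")),
        ("inv_A_lacZ_stable", "inversion", ("A", "lacZ"), ("EcI5", "Ll.LtrB"), ("s", "a")),
        ("inv_B_lacZ", "inversion", ("B", "lacZ"), ("EcI5", "EcI5"), ("s", "s")),
        ("inv_E_lacZ_reversible", "inversion", ("E", "lacZ"), ("EcI5", "EcI5"), ("s", "a")),
        ("inv_E_lacZ_stable", "inversion", ("E", "lacZ"), ("EcI5", "Ll.LtrB"), ("s", "a")),
        ("inv_D_E", "inversion", ("D", "E"), ("EcI5", "EcI5"), ("s", "a")),
        ("cnp_A_lacZ_to_E", "cut_and_paste", ("A", "lacZ", "E"), ("EcI5", "EcI5", "EcI5"), ("s", "a", "s")),
        ("cnp_D_E_to_B", "cut_and_paste", ("D", "E", "B"), ("EcI5", "EcI5", "EcI5"), ("s", "a", "s")),
    ]
    return [
        (label, make_plan(op, loci, types, strands))
        for label, op, loci, types, strands in rows
    ]


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthSpec:
    """Three-phase growth-curve recipe emulating a plate-reader run:
    lag, exponential growth at a fixed doubling time, stationary cap."""

    seed: int = 0
    doubling_time: float = 33.25  # minutes per doubling
    lag: float = 60.0  # minutes
    od_start: float = 0.001
    od_max: float = 1.0
    sampling_interval: float = 560.0 / 60.0  # minutes (560-s plate reader cycle)
    duration: float = 600.0  # minutes
    noise: float = 0.01  # multiplicative log-normal noise fraction
    replicates: int = 3


def make_growth_curves(spec: GrowthSpec) -> tuple[np.ndarray, np.ndarray]:
    """Simulate replicate OD600 curves.

    Returns ``(times_minutes, od)`` with ``od`` shaped
    (replicates, n_points).  Noise is multiplicative log-normal with
    sigma = ``spec.noise``; per-replicate streams are spawned from the
    master seed, so a spec is a pure function of its seed.
    """
    n = int(spec.duration // spec.sampling_interval) + 1
    times = np.arange(n) * spec.sampling_interval
    growing = np.clip(times - spec.lag, 0.0, None)
    clean = np.minimum(spec.od_start * 2.0 ** (growing / spec.doubling_time), spec.od_max)
    streams = np.random.SeedSequence([spec.seed, 0x600D]).spawn(spec.replicates)
    rows = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        factor = (
            np.exp(rng.normal(0.0, spec.noise, size=n)) if spec.noise > 0 else np.ones(n)
        )
        rows.append(clean * factor)
    return times, np.array(rows)
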