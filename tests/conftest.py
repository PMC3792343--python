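import numpy as np
import pytest

from targetlox.fixtures import FixtureSpec, make_genome
from targetlox.genome import Feature, FeatureKind, Molecule
from targetlox.lox import LoxCatalog, Orientation, parse_lox


@pytest.fixture(scope="session")
def catalog() -> LoxCatalog:
    return LoxCatalog.default()


@pytest.fixture(scope="session")
def genome():
    """Standard six-locus 30-kb synthetic chromosome."""
    mol, manifest = make_genome(FixtureSpec(seed=1))
    return mol, manifest


@pytest.fixture(scope="session")
def small_genome():
    mol, manifest = make_genome(
        FixtureSpec(seed=2, length=9000, loci=("A", "lacZ", "E"))
    )
    return mol, manifest


def random_background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def plant_sites(
    background: str,
    placements: list[tuple[int, str, str]],
    topology: str = "circular",
    catalog: LoxCatalog | None = None,
    mol_id: str = "toy",
) -> Molecule:
    """Overwrite 34-nt windows of a background with catalogue lox sites.

    ``placements`` holds (position, catalogue name, 'forward'|'reverse');
    positions must be >= 34 apart.
    """
    catalog = catalog or LoxCatalog.default()
    seq = list(background)
    feats = []
    for pos, name, orientation in placements:
        site = catalog[name].oriented(Orientation(orientation))
        s = site.sequence()
        seq[pos : pos + 34] = list(s)
        feats.append(
            Feature(
                FeatureKind.LOX,
                pos,
                pos + 34,
                "+" if orientation == "forward" else "-",
                name,
                payload=site,
            )
        )
    return Molecule(mol_id, "".join(seq), topology, feats)
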