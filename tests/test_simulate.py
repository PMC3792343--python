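"""Cre-event simulation, closure, host recombination, and oracle checks."""

import numpy as np
import pytest

from conftest import plant_sites, random_background
from oracles import canon, closure_oracle
from targetlox.fixtures import FixtureSpec, make_genome, make_plan
from targetlox.genome import FeatureKind, Molecule, insert_intron, locate_lox
from targetlox.lox import LoxCatalog, Orientation
from targetlox.simulate import (
    DesignError,
    EditPlan,
    SystemState,
    apply_plan,
    base_counts,
    cre_closure,
    cre_step,
    describe_scar,
    host_closure,
    host_recombination,
    validate_plan,
)

CAT = LoxCatalog.default()


def as_raw(state: SystemState):
    return tuple((m.sequence, m.is_circular) for m in state.molecules)


class TestCreStep:
    def test_single_site_no_events(self):
        rng = np.random.default_rng(0)
        mol = plant_sites(random_background(rng, 400), [(100, "loxP", "forward")])
        assert cre_step(SystemState((mol,))) == []

    def test_incompatible_pair_no_events(self):
        rng = np.random.default_rng(1)
        mol = plant_sites(
            random_background(rng, 500),
            [(100, "loxP", "forward"), (300, "lox2272", "forward")],
        )
        assert cre_step(SystemState((mol,))) == []

    def test_dead_site_no_events(self):
        rng = np.random.default_rng(2)
        mol = plant_sites(
            random_background(rng, 500),
            [(100, "lox72", "forward"), (300, "loxP", "forward")],
        )
        assert cre_step(SystemState((mol,))) == []

    def test_excision_leaves_dead_scar_and_wild_circle(self):
        """The canonical deletion setup: lox71 upstream, lox66 downstream,
        same orientation -> excision leaving a lox72 scar; the excised
        circle carries the wild-type-arm site."""
        rng = np.random.default_rng(3)
        mol = plant_sites(
            random_background(rng, 900),
            [(100, "lox71", "forward"), (600, "lox66", "forward")],
            topology="linear",
        )
        (event, succ), = cre_step(SystemState((mol,)))
        assert event.kind == "excision" and event.forms_inactive
        chrom = next(m for m in succ.molecules if not m.is_circular)
        circle = next(m for m in succ.molecules if m.is_circular)
        (_, scar), = locate_lox(chrom)
        (_, carried), = locate_lox(circle)
        assert CAT.name_of(scar) == "lox72" and not scar.is_active
        assert CAT.name_of(carried) == "loxP" and carried.is_wild_type_arms
        assert chrom.length == mol.length - 500  # region (466) + one site (34)
        assert circle.length == 500

    def test_inversion_is_involution(self):
        """Applying the opposite-orientation event twice restores the
        molecule exactly (wild-type sites)."""
        rng = np.random.default_rng(4)
        mol = plant_sites(
            random_background(rng, 700),
            [(100, "loxP", "forward"), (500, "loxP", "reverse")],
            topology="linear",
        )
        st = SystemState((mol,))
        (e1, s1), = cre_step(st)
        assert e1.kind == "inversion"
        (e2, s2), = cre_step(s1)
        assert s2.molecules[0].sequence == mol.sequence
        assert s1.molecules[0].sequence != mol.sequence

    def test_base_pair_conservation(self):
        """Double-stranded base content is invariant under every successor."""
        rng = np.random.default_rng(5)
        for i in range(20):
            names = rng.choice(["loxP", "lox66", "lox71", "lox2272"], size=2)
            oris = rng.choice(["forward", "reverse"], size=2)
            mol = plant_sites(
                random_background(rng, 600),
                [(100, names[0], oris[0]), (400, names[1], oris[1])],
                topology=str(rng.choice(["circular", "linear"])),
            )
            st = SystemState((mol,))
            for _, succ in cre_step(st):
                assert base_counts(succ) == base_counts(st)

    def test_integration_of_plasmid(self):
        """Intermolecular event between two circles fuses them."""
        rng = np.random.default_rng(6)
        chrom = plant_sites(random_background(rng, 800), [(200, "lox66", "forward")], mol_id="chrom")
        plasmid = plant_sites(random_background(rng, 300), [(50, "lox71", "reverse")], mol_id="plasmid")
        (event, succ), = cre_step(SystemState((chrom, plasmid)))
        assert event.kind == "integration"
        (fused,) = succ.molecules
        assert fused.length == 1100
        sites = locate_lox(fused)
        assert len(sites) == 2
        assert {CAT.name_of(s) for _, s in sites} == {"lox72", "loxP"}


class TestClosure:
    def test_deletion_closure_single_terminal(self, genome):
        mol, _ = genome
        plan = make_plan("deletion", ("A", "lacZ"))
        rep = cre_closure(apply_plan(mol, plan))
        assert len(rep.terminal_states) == 1
        assert not rep.reversible
        chrom = next(m for m in rep.terminal_states[0].molecules if ".circle" not in m.id)
        # the deleted region (between the locus genes) is gone
        labels = {f.label for f in chrom.features_of(FeatureKind.GENE)}
        assert "B" in labels and "E" in labels

    def test_deletion_scar_is_single_double_mutant_site(self, genome):
        """After deletion the chromosome carries exactly one lox: a 34-nt
        double-arm-mutant (Cre-dead) site."""
        mol, _ = genome
        rep = cre_closure(apply_plan(mol, make_plan("deletion", ("A", "lacZ"))))
        chrom = next(m for m in rep.terminal_states[0].molecules if ".circle" not in m.id)
        sites = locate_lox(chrom)
        assert len(sites) == 1
        f, s = sites[0]
        assert f.length == 34
        assert not s.is_active
        assert CAT.name_of(s) == "lox72"

    def test_incompatible_sites_initial_state_terminal(self):
        rng = np.random.default_rng(7)
        mol = plant_sites(
            random_background(rng, 500),
            [(100, "loxP", "forward"), (300, "loxN", "forward")],
        )
        rep = cre_closure(SystemState((mol,)))
        assert rep.n_states == 1
        assert len(rep.terminal_states) == 1
        assert not rep.reversible

    def test_cut_and_paste_single_absorbing_outcome(self, genome):
        """Three-site cut-and-paste: one absorbing outcome with the region
        translocated and a dead lox72 at the join."""
        mol, _ = genome
        plan = make_plan(
            "cut_and_paste", ("A", "lacZ", "E"), ("EcI5",) * 3, ("s", "a", "s")
        )
        rep = cre_closure(apply_plan(mol, plan))
        assert len(rep.terminal_states) == 1
        assert rep.reversible  # the cut itself is reversible
        (chrom,) = rep.terminal_states[0].molecules
        names = [CAT.name_of(s) for _, s in locate_lox(chrom)]
        assert "lox72" in names
        # the whole genome stays one molecule: region moved, nothing lost
        u_state = apply_plan(mol, plan)
        assert chrom.length == u_state.molecules[0].length
        # residual active pair is in opposing orientations (invert-only)
        active = [(f, s) for f, s in locate_lox(chrom) if s.is_active]
        assert len(active) == 2
        assert active[0][1].orientation is not active[1][1].orientation

    def test_max_states_truncation(self, genome):
        from targetlox.simulate import StateSpaceExceeded

        mol, _ = genome
        plan = make_plan(
            "cut_and_paste", ("A", "lacZ", "E"), ("EcI5",) * 3, ("s", "a", "s")
        )
        with pytest.raises(StateSpaceExceeded):
            cre_closure(apply_plan(mol, plan), max_states=2)

    def test_rmce_locks_cassette_in_genome(self, genome):
        """Cassette exchange ends with the cargo flanked by the two dead
        sites and the backbone released as an inert circle."""
        mol, _ = genome
        plan = make_plan("rmce_insertion", ("lacZ",))
        rep = cre_closure(apply_plan(mol, plan))
        assert len(rep.terminal_states) == 1
        final = rep.terminal_states[0]
        chrom = max(final.molecules, key=lambda m: m.length)
        backbone = min(final.molecules, key=lambda m: m.length)
        assert any(f.label == "cargo" for f in chrom.features)
        assert all(not s.is_active for _, s in locate_lox(chrom))
        assert all(s.is_active for _, s in locate_lox(backbone))
        assert {s.linker_class for _, s in locate_lox(chrom)} == {"P", "m2"}


@pytest.mark.parametrize(
    "placements,topology,extra",
    [
        ([(80, "lox71", "forward"), (420, "lox66", "forward")], "circular", None),
        ([(80, "loxP", "forward"), (420, "loxP", "reverse")], "linear", None),
        ([(80, "lox71", "forward"), (420, "lox66", "reverse")], "circular", None),
        ([(80, "loxP", "forward"), (300, "loxP", "forward"), (520, "loxP", "reverse")], "circular", None),
        ([(80, "lox66", "forward"), (300, "loxP", "forward"), (520, "lox71", "reverse")], "circular", None),
        ([(80, "lox66", "forward")], "circular", (150, "lox71", "reverse")),
        ([(80, "loxP", "forward"), (420, "lox2272", "forward")], "circular", None),
    ],
    ids=[
        "deletion-pair",
        "wt-inversion",
        "lock-inversion",
        "three-wt",
        "cut-and-paste-like",
        "integration",
        "incompatible",
    ],
)
def test_closure_matches_string_splice_oracle(placements, topology, extra):
    """On small molecules with <= 3 sites, the reachable states, transition
    structure and terminal outcomes equal those of an independent
    brute-force enumerator that splices raw strings."""
    rng = np.random.default_rng(hash(str(placements)) % 2**32)
    mols = [plant_sites(random_background(rng, 700), placements, topology)]
    if extra is not None:
        mols.append(
            plant_sites(random_background(rng, 400), [extra], "circular", mol_id="ep")
        )
    state = SystemState(tuple(mols))

    oracle_states, _, oracle_term_sccs = closure_oracle(as_raw(state))

    # walk the implementation's graph explicitly to expose all states
    import networkx as nx

    seen = {state.key(): state}
    graph = nx.DiGraph()
    graph.add_node(state.key())
    frontier = [state]
    while frontier:
        nxt = []
        for st in frontier:
            for _, succ in cre_step(st):
                k = succ.key()
                graph.add_edge(st.key(), k)
                if k not in seen:
                    seen[k] = succ
                    nxt.append(succ)
        frontier = nxt

    impl_keys = {canon(as_raw(s)) for s in seen.values()}
    assert impl_keys == set(oracle_states)

    impl_term = set()
    for comp in nx.strongly_connected_components(graph):
        if all(v in comp for u in comp for v in graph.successors(u)):
            impl_term.add(frozenset(canon(as_raw(seen[k])) for k in comp))
    assert impl_term == {frozenset(c) for c in oracle_term_sccs}


class TestHostRecombination:
    def _two_intron_molecule(self, strands=("s", "s"), types=("EcI5", "EcI5")):
        rng = np.random.default_rng(11)
        mol = Molecule("m", random_background(rng, 8000), "circular", [])
        from test_genome import design

        mol = insert_intron(mol, 2000, design(intron_type=types[0], strand=strands[0]))
        mol = insert_intron(mol, 6000, design(intron_type=types[1], strand=strands[1]))
        return mol

    def test_non_homologous_introns_inert(self):
        """An Ll.LtrB / EcI5 pair offers no homology to the host."""
        mol = self._two_intron_molecule(types=("Ll.LtrB", "EcI5"))
        assert host_recombination(mol) == []

    def test_direct_repeats_collapse(self):
        """Identical direct-repeat scaffolds collapse, deleting one repeat
        plus the intervening sequence (checked against splice arithmetic)."""
        mol = self._two_intron_molecule(strands=("s", "s"))
        events = host_recombination(mol)
        collapses = [m for e, m in events if e.kind == "collapse"]
        assert collapses
        # aligned crossover deletes one full repeat plus the intervening
        # sequence, i.e. exactly the spacing between the repeat starts
        assert all(mol.length - m.length == 4000 for m in collapses)

    def test_separated_inverted_repeats_invert_reversibly(self):
        mol = self._two_intron_molecule(strands=("s", "a"))
        events = host_recombination(mol)
        kinds = {e.kind for e, _ in events}
        assert kinds == {"inversion"}
        _, inverted = events[0]
        back = [m for e, m in host_recombination(inverted) if e.kind == "inversion"]
        assert any(m.canonical_key() == mol.canonical_key() for m in back)

    def test_adjacent_inverted_repeats_removed_to_tiny_scar(self, genome):
        """The post-deletion inverted repeat is removed wholesale: the scar
        drops from hundreds of bp (with a lox) to tens of bp (without)."""
        mol, _ = genome
        plan = make_plan("deletion", ("D", "E"), ("EcI5", "EcI5"), ("s", "a"))
        rep = cre_closure(apply_plan(mol, plan))
        assert rep.inverted_repeat_generated
        before_len, before_lox = rep.scar_length, rep.scar_contains_lox
        assert before_len > 100 and before_lox
        collapsed = host_closure(rep.terminal_states[0])
        after_len, after_lox = describe_scar(collapsed)
        assert after_len < 100 and not after_lox
        chrom = next(m for m in collapsed.molecules if ".circle" not in m.id)
        assert locate_lox(chrom) == []
        assert after_len < default_scaffold_len()

    def test_min_homology_gate(self):
        mol = self._two_intron_molecule()
        assert host_recombination(mol, min_homology=2000) == []
        with pytest.raises(ValueError):
            host_recombination(mol, min_homology=0)


def default_scaffold_len():
    from targetlox.genome import default_scaffold

    return default_scaffold("EcI5").length


class TestValidation:
    def test_triple_deletion_needs_three_classes(self, catalog):
        """Simultaneous triple deletion uses three mutually incompatible
        linker classes; re-using a class is rejected."""
        plan = make_plan("deletion", ("A", "lacZ", "B", "C", "D", "E"))
        validate_plan(plan)  # P + 2272 + N: fine
        classes = {
            r[0].design.cargo[0].linker_class for r in plan.regions
        }
        assert len(classes) == 3
        # force a re-used class
        bad = EditPlan("deletion", (plan.regions[0], plan.regions[0], plan.regions[2]))
        with pytest.raises(DesignError, match="re-used"):
            validate_plan(bad)

    def test_deletion_wrong_orientation_rejected(self):
        plan = make_plan("inversion", ("A", "lacZ"))
        bad = EditPlan("deletion", plan.regions)
        with pytest.raises(DesignError, match="orientation"):
            validate_plan(bad)

    def test_deletion_active_scar_rejected(self):
        """Mutant arms pointing inward would leave an active scar."""
        good = make_plan("deletion", ("A", "lacZ"))
        (up, down), = good.regions
        bad = EditPlan("deletion", ((down, up),))  # lox66 upstream, lox71 downstream
        with pytest.raises(DesignError, match="scar"):
            validate_plan(bad)

    def test_cut_and_paste_patterns(self):
        plan = make_plan("cut_and_paste", ("A", "lacZ", "E"))
        validate_plan(plan)
        # target without a complementary arm mutant cannot lock
        bad = EditPlan("cut_and_paste", plan.regions, target=plan.regions[0][1])
        with pytest.raises(DesignError):
            validate_plan(bad)

    def test_unknown_locus(self, genome):
        mol, _ = genome
        plan = make_plan("deletion", ("A", "nope"))
        with pytest.raises(DesignError, match="locus"):
            apply_plan(mol, plan)


class TestRotationInvariance:
    def test_closure_invariant_under_rotation(self, small_genome):
        """Rotating the circular chromosome does not change any outcome."""
        mol, _ = small_genome
        plan = make_plan("deletion", ("A", "lacZ"))
        base = cre_closure(apply_plan(mol, plan))
        base_keys = {
            tuple(sorted(m.canonical_key() for m in s.molecules))
            for s in base.terminal_states
        }
        for off in (517, 4444):
            rot = mol.rotated(off)
            rep = cre_closure(apply_plan(rot, plan))
            keys = {
                tuple(sorted(m.canonical_key() for m in s.molecules))
                for s in rep.terminal_states
            }
            assert keys == base_keys
            assert rep.inverted_repeat_generated == base.inverted_repeat_generated
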