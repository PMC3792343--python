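"""In-silico PCR and diagnostic assay planning."""

import numpy as np
import pytest

from conftest import plant_sites, random_background
from oracles import pcr_oracle, rc
from targetlox.fixtures import FixtureSpec, make_genome, make_plan
from targetlox.genome import Molecule
from targetlox.simulate import DesignError
from targetlox.verify import (
    PrimerPair,
    design_assays,
    insilico_pcr,
    predict_signature,
    simulate_states,
)


def _pair(f, r):
    return PrimerPair("f", f, "r", r)


class TestInsilicoPcr:
    def test_absent_primer_no_band(self):
        mol = Molecule("m", "ACGT" * 200, "linear", [])
        assert insilico_pcr(mol, _pair("TTTTTTTTTTTTTTTTTTTT", "GGGGGGGGGGGGGGGGGGGG")) == []

    def test_planted_convergent_pair(self):
        """Convergent primers 500 nt apart give one product of size 500."""
        rng = np.random.default_rng(0)
        seq = random_background(rng, 2000)
        f = seq[300:320]
        r = rc(seq[780:800])
        mol = Molecule("m", seq, "linear", [])
        prods = insilico_pcr(mol, _pair(f, r))
        assert prods == [(300, 800, 500)]

    def test_origin_spanning_product_on_circle(self):
        """Primers that look divergent in the stored linearization amplify
        across the origin of a circular molecule."""
        rng = np.random.default_rng(1)
        seq = random_background(rng, 1500)
        f = seq[1300:1320]
        r = rc(seq[180:200])
        mol = Molecule("m", seq, "circular", [])
        prods = insilico_pcr(mol, _pair(f, r))
        assert prods == [(1300, 1700, 400)]
        # same primers on the linear form: no product
        assert insilico_pcr(Molecule("m", seq, "linear", []), _pair(f, r)) == []

    def test_short_primer_rejected(self):
        mol = Molecule("m", "ACGT" * 100, "linear", [])
        with pytest.raises(ValueError, match="15"):
            insilico_pcr(mol, _pair("ACGTACGT", "ACGTACGTACGTACGTAC"))

    @pytest.mark.parametrize("topology", ["linear", "circular"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_window_oracle(self, topology, seed):
        """Exact-match PCR equals the brute-force window enumerator,
        including multi-site primers and both orientations."""
        rng = np.random.default_rng(seed)
        seq = random_background(rng, 3000)
        # plant a repeated primer site to force multiple products
        f = seq[100:120]
        seq = seq[:1500] + f + seq[1520:]
        r = rc(seq[900:920])
        mol = Molecule("m", seq, topology, [])
        got = insilico_pcr(mol, _pair(f, r), max_product=2500)
        assert got == pcr_oracle(seq, topology == "circular", f, r, 2500)


class TestAssayDesign:
    def test_deletion_three_assays(self, genome):
        mol, _ = genome
        plan = make_plan("deletion", ("A", "lacZ"))
        ap = design_assays(plan, mol)
        assert len(ap) == 3
        assert [a.role for a in ap.assays] == [
            "insertion_bridge",
            "insertion_bridge",
            "junction",
        ]

    def test_inversion_four_assays(self, genome):
        mol, _ = genome
        plan = make_plan("inversion", ("D", "E"), ("EcI5", "EcI5"), ("s", "a"))
        ap = design_assays(plan, mol)
        assert len(ap) == 4
        assert sum(a.role == "junction" for a in ap.assays) == 2

    def test_cut_and_paste_six_assays(self, genome):
        mol, _ = genome
        plan = make_plan("cut_and_paste", ("A", "lacZ", "E"), ("EcI5",) * 3, ("s", "a", "s"))
        ap = design_assays(plan, mol)
        assert len(ap) == 6
        roles = [a.role for a in ap.assays]
        assert roles.count("insertion_bridge") == 3
        assert roles.count("cut_bridge") == 1
        assert roles.count("paste_bridge") == 2

    def test_primer_naming_grammar(self, genome):
        """Primer names are locus letter + u/d; lacZ maps to L."""
        mol, _ = genome
        ap = design_assays(make_plan("deletion", ("A", "lacZ")), mol)
        names = {a.pair.name for a in ap.assays}
        assert names == {"Au/Ad", "Lu/Ld", "Au/Ld"}

    def test_assay_counts_over_random_plans(self):
        """Assay-count post-conditions hold across many generated plans."""
        ops = {"deletion": 3, "inversion": 4, "cut_and_paste": 6}
        rng = np.random.default_rng(7)
        checked = 0
        for seed in range(34):
            mol, _ = make_genome(
                FixtureSpec(seed=100 + seed, length=12_000, loci=("A", "lacZ", "E"))
            )
            for op, expected in ops.items():
                loci = ("A", "lacZ", "E") if op == "cut_and_paste" else ("A", "lacZ")
                n = len(loci)
                strands = tuple(rng.choice(["s", "a"], size=n))
                plan = make_plan(op, loci, ("EcI5",) * n, strands)
                assert len(design_assays(plan, mol)) == expected
                checked += 1
        assert checked >= 100

    def test_missing_locus_fails_with_locus_name(self, genome):
        mol, _ = genome
        plan = make_plan("deletion", ("A", "Q"))
        with pytest.raises(DesignError, match="Q"):
            design_assays(plan, mol)


class TestSignatures:
    @pytest.fixture(scope="class")
    @staticmethod
    def deletion_setup(genome):
        mol, _ = genome
        plan = make_plan("deletion", ("A", "lacZ"))
        ap = design_assays(plan, mol)
        states = simulate_states(plan, mol)
        return plan, ap, states, predict_signature(plan, states, ap)

    def test_junction_band_only_after_induction(self, deletion_setup):
        _, ap, _, table = deletion_setup
        junction = next(a for a in ap.assays if a.role == "junction")
        row = table[junction.pair.name]
        assert row["W"] == [] and row["U"] == []
        assert len(row["I"]) == 1

    def test_insertion_bridges_grow_by_intron_length_then_vanish(self, deletion_setup):
        """U-state bands exceed W-state bands by the intron insert length
        (~1 kb); after deletion the bridges disappear."""
        plan, ap, _, table = deletion_setup
        insert_len = len(plan.regions[0][0].design.insert_sequence())
        for assay in ap.assays:
            if assay.role != "insertion_bridge":
                continue
            row = table[assay.pair.name]
            assert len(row["W"]) == 1 and len(row["U"]) == 1
            assert row["U"][0] - row["W"][0] == insert_len
            assert row["I"] == []

    def test_collapsed_inverted_repeat_shrinks_junction_band(self, genome):
        """When the deletion leaves an inverted repeat, the host removes it
        and the junction band is smaller than the uncollapsed prediction by
        at least one scaffold length."""
        from targetlox.genome import default_scaffold
        from targetlox.simulate import SystemState, apply_plan, cre_closure

        mol, _ = genome
        plan = make_plan("deletion", ("D", "E"), ("EcI5", "EcI5"), ("s", "a"))
        ap = design_assays(plan, mol)
        states = simulate_states(plan, mol)  # induced state includes IR removal
        table = predict_signature(plan, states, ap)
        junction = next(a for a in ap.assays if a.role == "junction")
        collapsed_size = table[junction.pair.name]["I"][0]

        raw_terminal = cre_closure(apply_plan(mol, plan)).terminal_states[0]
        uncollapsed = predict_signature(
            plan, {"W": states["W"], "U": states["U"], "I": raw_terminal}, ap
        )
        uncollapsed_size = uncollapsed[junction.pair.name]["I"][0]
        # the repeat structure (two half-scaffold fragments + the 34-nt lox)
        # is replaced by a 40-nt remnant
        sc = default_scaffold("EcI5")
        assert uncollapsed_size - collapsed_size == sc.length + 34 - 40

    def test_induced_bands_come_from_simulated_terminal_states(self, deletion_setup):
        """Every band predicted in state I is producible from the simulated
        post-Cre (plus host collapse) state."""
        _, ap, states, table = deletion_setup
        for assay in ap.assays:
            for size in table[assay.pair.name]["I"]:
                found = any(
                    any(p[2] == size for p in insilico_pcr(m, assay.pair))
                    for m in states["I"].molecules
                )
                assert found
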