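import itertools

import numpy as np
import pytest

from _util import random_dna
from recseq.errors import DesignInfeasibleError, InputError
from recseq.genome import DEFAULT_ENZYMES, find_recognition_sites
from recseq.libsim import (
    CircularSpecies,
    EnzymePanel,
    Molecule,
    MoleculePool,
    ReadPairSet,
    build_library_pool,
    choose_enzyme_panel,
    digest,
    excise_species,
    exonuclease_select,
    generate_reads,
    panel_from_names,
    run_recseq,
    species_molecule,
    survives_complete_digestion,
)

STANDARD = ("EagI", "PvuI", "PvuII")


class TestExcision:
    def test_three_unit_circle_length(self, reference):
        (arr,) = reference.features_by_label("tandem_array")
        sp = excise_species(reference, arr, 3)
        assert len(sp.sequence) == 6000
        unit = reference.contig(arr.contig).sequence[arr.start : arr.start + 2000]
        assert sp.sequence == unit * 3  # junction at a unit boundary

    def test_single_unit_and_whole_array_allowed(self, reference):
        (arr,) = reference.features_by_label("tandem_array")
        assert len(excise_species(reference, arr, 1).sequence) == 2000
        assert len(excise_species(reference, arr, 9).sequence) == 18000

    def test_exceeding_array_rejected(self, reference):
        (arr,) = reference.features_by_label("tandem_array")
        with pytest.raises(InputError):
            excise_species(reference, arr, 10)
        with pytest.raises(InputError):
            excise_species(reference, arr, 2, start_unit=8)


class TestDigest:
    def test_circle_without_sites_stays_circular(self):
        mol = Molecule("A" * 2000, "circular", "x")
        out = digest(mol, "GAATTC", 1.0)
        assert out == [mol]

    def test_circle_two_sites_fragment_lengths(self):
        seq = list("A" * 2000)
        seq[100:106] = "GAATTC"
        seq[600:606] = "GAATTC"
        mol = Molecule("".join(seq), "circular", "x")
        out = digest(mol, "GAATTC", 1.0)
        assert sorted(len(m) for m in out) == [500, 1500]
        assert all(m.topology == "linear" for m in out)

    def test_linear_one_site_two_fragments(self):
        seq = "A" * 300 + "GAATTC" + "A" * 200
        out = digest(Molecule(seq, "linear", "x"), "GAATTC", 1.0)
        assert len(out) == 2
        assert sum(len(m) for m in out) == len(seq)

    def test_length_conservation_random(self, rng):
        """Fragment lengths always sum to the molecule length."""
        for _ in range(300):
            n = int(rng.integers(50, 500))
            seq = random_dna(rng, n)
            motif = random_dna(rng, int(rng.integers(2, 4)))
            topo = ["linear", "circular"][int(rng.integers(0, 2))]
            p_cut = float(rng.random())
            out = digest(Molecule(seq, topo, "x"), motif, p_cut, rng)
            assert sum(len(m) for m in out) == n

    def test_full_cut_is_deterministic(self, rng):
        seq = random_dna(rng, 400)
        a = digest(Molecule(seq, "circular", "x"), "AC", 1.0)
        b = digest(Molecule(seq, "circular", "x"), "AC", 1.0)
        assert [m.sequence for m in a] == [m.sequence for m in b]


class TestExonuclease:
    def test_removes_linear_keeps_circular(self):
        pool = MoleculePool(
            [
                (Molecule("ACGT" * 100, "circular", "c"), 2.0),
                (Molecule("ACGT" * 10, "linear", "l1"), 1.0),
                (Molecule("AAAA", "linear", "l2"), 1.0),
                (Molecule("CCCC", "linear", "l3"), 1.0),
            ]
        )
        out = exonuclease_select(pool)
        assert len(out) == 1 and out.total_weight() == 2.0

    def test_idempotent_and_identity_on_circles(self):
        pool = MoleculePool([(Molecule("ACGT" * 50, "circular", "c"), 3.0)])
        once = exonuclease_select(pool)
        twice = exonuclease_select(once)
        assert [(m.sequence, w) for m, w in once] == [(m.sequence, w) for m, w in twice]

    def test_empty_pool(self):
        assert len(exonuclease_select(MoleculePool())) == 0

    def test_weight_monotone(self, rng):
        pool = MoleculePool(
            [
                (Molecule(random_dna(rng, 100), ["linear", "circular"][i % 2], f"s{i}"), i + 0.5)
                for i in range(6)
            ]
        )
        before = pool.weight_by_provenance()
        after = exonuclease_select(pool).weight_by_provenance()
        assert all(after.get(k, 0.0) <= v for k, v in before.items())


class TestRunRecseq:
    def test_cut_by_all_three_is_eliminated(self, reference):
        """rDNA-like and episome circles carry sites for all panel enzymes."""
        panel = panel_from_names(STANDARD)
        (rdna,) = reference.features_by_label("rDNA_like")
        erc = excise_species(reference, rdna, 1)
        (tm,) = reference.features_by_label("two_micron")
        episome = excise_species(reference, tm, 1)
        pool = MoleculePool(
            [(species_molecule(erc), 100.0), (species_molecule(episome), 50.0)]
        )
        out = run_recseq(pool, panel, p_cut=1.0)
        assert out.total_weight() == 0.0

    def test_two_of_three_survives_one_third(self, rng):
        # a circle with EagI and PvuI sites but no PvuII site
        seq = list(random_dna(rng, 1000))
        while any(
            find_recognition_sites("".join(seq), DEFAULT_ENZYMES[e], "circular")
            for e in STANDARD
        ):
            seq = list(random_dna(rng, 1000))
        seq[100:106] = DEFAULT_ENZYMES["EagI"]
        seq[500:506] = DEFAULT_ENZYMES["PvuI"]
        pool = MoleculePool([(Molecule("".join(seq), "circular", "t"), 300.0)])
        out = run_recseq(pool, panel_from_names(STANDARD), p_cut=1.0)
        assert out.total_weight() == pytest.approx(100.0)

    def test_survival_rule_oracle_random_species(self, rng):
        """Complete digestion agrees with the brute-force site-enumeration rule."""
        panel = panel_from_names(STANDARD)
        mols = []
        expected = {}
        for i in range(300):
            # mix of clean and site-planted sequences to hit all survival classes
            seq = list(random_dna(rng, int(rng.integers(300, 1500))))
            for e in STANDARD:
                if rng.random() < 0.5:
                    p = int(rng.integers(0, len(seq) - 6))
                    seq[p : p + 6] = DEFAULT_ENZYMES[e]
            s = "".join(seq)
            mols.append((Molecule(s, "circular", f"sp{i}"), 3.0))
            _, free = survives_complete_digestion(s, panel)
            expected[f"sp{i}"] = free  # weight 3 -> surviving weight == free count
        out = run_recseq(MoleculePool(mols), panel, p_cut=1.0)
        got = out.weight_by_provenance()
        for k, free in expected.items():
            assert got.get(k, 0.0) == pytest.approx(float(free)), k

    def test_partial_digestion_matches_closed_form(self, rng):
        """Expected surviving weight = (1/3) sum_i (1-q)^(rounds * s_i)."""
        seq = list(random_dna(rng, 2000))
        for e, pos in zip(STANDARD, (100, 700, 1300)):
            seq[pos : pos + 6] = DEFAULT_ENZYMES[e]
        seq = "".join(seq)
        panel = panel_from_names(STANDARD)
        sites = [len(find_recognition_sites(seq, m, "circular")) for m in panel.motifs]
        q = 0.4
        closed = sum((1 - q) ** (2 * s) for s in sites) / 3
        n = 1500
        total = 0.0
        for k in range(n):
            pool = MoleculePool([(Molecule(seq, "circular", "x"), 1.0)])
            total += run_recseq(pool, panel, rounds=2, p_cut=q, seed=k).total_weight()
        mc = total / n
        # survival indicator variance bound gives SE <= 0.5/sqrt(n)
        assert abs(mc - closed) < 3 * 0.5 / np.sqrt(n)


class TestPanelDesign:
    def _species(self, seq, sid):
        return CircularSpecies(sid, "c", (0, len(seq)), seq, 1.0)

    def test_unique_valid_triple_found(self, rng):
        cands = {k: DEFAULT_ENZYMES[k] for k in ("EagI", "PvuI", "PvuII", "SmaI")}
        base = random_dna(rng, 600)
        while any(find_recognition_sites(base, m, "circular") for m in cands.values()):
            base = random_dna(rng, 600)
        nuis_seq = list(base)
        for e, pos in zip(("EagI", "PvuI", "PvuII"), (10, 200, 400)):
            nuis_seq[pos : pos + 6] = cands[e]
        nuisance = [self._species("".join(nuis_seq), "nuis")]
        targ_seq = list(base)
        targ_seq[50:56] = cands["SmaI"]
        target = [self._species("".join(targ_seq), "targ")]
        panel = choose_enzyme_panel(nuisance, target, cands)
        # brute-force: the only triple cutting the nuisance 3x is (EagI,PvuI,PvuII)
        valid = []
        for triple in itertools.combinations(sorted(cands), 3):
            ok_n = all(
                find_recognition_sites(nuisance[0].sequence, cands[e], "circular")
                for e in triple
            )
            ok_t = any(
                not find_recognition_sites(target[0].sequence, cands[e], "circular")
                for e in triple
            )
            if ok_n and ok_t:
                valid.append(triple)
        assert valid == [("EagI", "PvuI", "PvuII")]
        assert tuple(sorted(panel.names)) == valid[0]

    def test_target_with_all_motifs_is_infeasible(self, rng):
        cands = {k: DEFAULT_ENZYMES[k] for k in ("EagI", "PvuI", "PvuII")}
        allm = "".join(cands.values()) + random_dna(rng, 100)
        nuisance = [self._species(allm, "n")]
        target = [self._species(allm, "t")]
        with pytest.raises(DesignInfeasibleError) as err:
            choose_enzyme_panel(nuisance, target, cands)
        assert err.value.best_partial is not None

    def test_spare_constraint_places_sparing_enzyme(self, reference):
        motifs = reference.enzyme_motifs
        (rdna,) = reference.features_by_label("rDNA_like")
        (tm,) = reference.features_by_label("two_micron")
        (arr,) = reference.features_by_label("tandem_array")
        nuisance = [excise_species(reference, rdna, 1)]
        target = [excise_species(reference, arr, 1)]
        episome = excise_species(reference, tm, 1)
        cands = {k: motifs[k] for k in ("EagI", "PvuI", "PvuII", "SmaI")}
        panel = choose_enzyme_panel(nuisance, target, cands, spare=episome)
        # SmaI cuts the rDNA-like unit but not the episome -> constrained slot
        assert panel.names[-1] == "SmaI"
        assert not find_recognition_sites(episome.sequence, motifs["SmaI"], "circular")

    def test_panel_validation(self):
        with pytest.raises(InputError):
            EnzymePanel((("A", "GAATTC"), ("A", "CTCGAG"), ("B", "CAGCTG")))
        with pytest.raises(InputError):
            EnzymePanel((("A", "GAATTC"), ("B", "CTCGAG")))


class TestGenerateReads:
    def test_contracts(self, reference, rng):
        (arr,) = reference.features_by_label("tandem_array")
        sp = excise_species(reference, arr, 2, abundance=5.0)
        pool = MoleculePool([(species_molecule(sp), sp.abundance)])
        reads = generate_reads(pool, depth=1000, error_rate=0.0, seed=1)
        assert len(reads) == 1000
        assert reads.seq1.shape == (1000, 75) and reads.seq2.shape == (1000, 75)
        assert set(reads.sources) == {sp.id}

    def test_error_free_reads_match_reference(self, reference):
        contig = reference.contig("chrI")
        frag = contig.sequence[40000:40400]  # unique background region
        pool = MoleculePool([(Molecule(frag, "linear", "u"), 1.0)])
        reads = generate_reads(pool, depth=50, error_rate=0.0, seed=2)
        from recseq.genome import decode_sequence, reverse_complement

        for i in range(50):
            m1, m2 = reads.mate_strings(i)
            assert m1 in frag
            assert reverse_complement(m2) in frag

    def test_deterministic_under_seed(self, reference):
        (tm,) = reference.features_by_label("two_micron")
        sp = excise_species(reference, tm, 1, abundance=2.0)
        pool = MoleculePool([(species_molecule(sp), 2.0)])
        a = generate_reads(pool, depth=200, seed=7)
        b = generate_reads(pool, depth=200, seed=7)
        assert np.array_equal(a.seq1, b.seq1) and np.array_equal(a.seq2, b.seq2)

    def test_empty_pool_rejected(self):
        with pytest.raises(InputError):
            generate_reads(MoleculePool(), depth=10)

    def test_fastq_round_trip(self, reference, tmp_path):
        (tm,) = reference.features_by_label("two_micron")
        pool = MoleculePool([(species_molecule(excise_species(reference, tm, 1)), 1.0)])
        reads = generate_reads(pool, depth=30, seed=3)
        for suffix in (".fastq", ".fastq.gz"):
            p1 = tmp_path / f"r1{suffix}"
            p2 = tmp_path / f"r2{suffix}"
            reads.to_fastq(p1, p2)
            back = ReadPairSet.from_fastq(p1, p2)
            assert np.array_equal(back.seq1, reads.seq1)
            assert np.array_equal(back.seq2, reads.seq2)
            assert list(back.source_labels()) == list(reads.source_labels())


class TestLibraryPool:
    def test_total_mode_keeps_everything(self, reference):
        (arr,) = reference.features_by_label("tandem_array")
        sp = excise_species(reference, arr, 1, abundance=4.0)
        pool = build_library_pool(reference, [sp], "total")
        prov = pool.weight_by_provenance()
        assert prov[sp.id] == 4.0
        assert prov["chromosomal:chrI"] == 1.0

    def test_recseq_mode_keeps_leakthrough_background(self, reference):
        (arr,) = reference.features_by_label("tandem_array")
        sp = excise_species(reference, arr, 1, abundance=4.0)
        panel = panel_from_names(STANDARD, reference.enzyme_motifs)
        pool = build_library_pool(reference, [sp], "recseq", panel=panel, leak_fraction=0.001)
        prov = pool.weight_by_provenance()
        assert prov[sp.id] == pytest.approx(4.0)  # site-free: survives all 3 aliquots
        assert prov["chromosomal:chrI"] == pytest.approx(0.001)
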