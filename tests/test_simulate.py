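import math

import numpy as np
import pytest

from trfm1a import simulate
from trfm1a.core import frag_to_mature_coord
from trfm1a.simulate import (
    PSII,
    TGIRT,
    MoleculePool,
    PoolEntry,
    RIPConfig,
    RTModel,
    apply_rt_model,
    build_reference,
    build_utrs,
    expected_site_mismatch_rate,
    simulate_expression_table,
    simulate_fragment_pool,
    simulate_rip,
    site_motif,
)


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestBuildReference:
    def test_determinism_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        build_reference(11, 4, 5, 2, 1, 1).to_dir(str(a))
        build_reference(11, 4, 5, 2, 1, 1).to_dir(str(b))
        for f in ("trnas.fa", "trailers.fa", "mirnas.fa", "spikeins.fa",
                  "mod_sites.tsv"):
            assert (a / f).read_bytes() == (b / f).read_bytes()

    def test_trna_invariants_and_site_placement(self, gen_ref):
        for t in gen_ref.tRNAs:
            assert t.sequence.endswith("CCA") and 72 <= t.length <= 90
            tloop = [s for s in gen_ref.sites_on(t.name)
                     if s.position == t.length - 18]
            assert len(tloop) == 1
            # the annotated site is fragment position 4 of the 22-nt tRF-3b
            assert frag_to_mature_coord(t.length, 22, "3prime", 4) == \
                tloop[0].position
            assert t.sequence[tloop[0].position - 1] == "A"

    def test_mitochondrial_trnas_carry_position9_site(self, gen_ref):
        mito = [t for t in gen_ref.tRNAs if t.compartment == "mitochondrial"]
        assert mito
        for t in mito:
            assert any(s.position == 9 for s in gen_ref.sites_on(t.name))
            assert t.sequence[8] == "A"

    def test_spike_ins_map_nowhere_else(self, gen_ref):
        """No 15-nt window of a spike-in aligns (within 1 mismatch) to any
        tRNA or miRNA reference — brute-force check."""
        hosts = [t.sequence for t in gen_ref.tRNAs] + [s for _, s in gen_ref.miRNAs]
        for _, spike, _ in gen_ref.spike_ins:
            for i in range(len(spike) - 14):
                win = spike[i:i + 15]
                for h in hosts:
                    assert all(_hamming(win, h[j:j + 15]) > 1
                               for j in range(len(h) - 14))


class TestFragmentPool:
    def test_zero_stoichiometry_means_no_modified_molecules(self, gen_ref):
        pool, truth = simulate_fragment_pool(gen_ref, {"tRF-3b": 1.0}, 0.0,
                                             n_molecules=2000, seed=1)
        assert pool.n_molecules == 2000 and pool.n_modified == 0
        assert (truth.stoichiometry == 0).all()

    def test_full_stoichiometry_trf3b_modified_at_position4(self, gen_ref):
        pool, _ = simulate_fragment_pool(gen_ref, {"tRF-3b": 1.0}, 1.0,
                                         n_molecules=1000, seed=1)
        nuclear = {t.name for t in gen_ref.tRNAs if t.compartment == "nuclear"}
        for e in pool.entries:
            assert e.annotation.size_isoform == "3b"
            if e.annotation.parent in nuclear:
                assert e.mod_status == {4: True}

    def test_modified_fraction_within_binomial_error(self, gen_ref):
        p, n = 0.6, 10_000
        pool, _ = simulate_fragment_pool(gen_ref, {"tRF-3b": 1.0}, p,
                                         n_molecules=n, seed=5)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(pool.n_modified / n - p) < 3 * se

    def test_fragment_sequences_are_exact_suffixes_and_prefixes(self, gen_ref):
        pool, _ = simulate_fragment_pool(
            gen_ref, {"tRF-3b": 0.3, "tRF-3a": 0.2, "tRF-5": 0.3, "tRF-1": 0.2},
            0.5, n_molecules=2000, seed=3)
        for e in pool.entries:
            parent_seq = gen_ref.sequence(e.annotation.parent)
            if e.annotation.trf_class == "tRF-3":
                assert parent_seq.endswith(e.sequence)
                assert len(e.sequence) in (18, 22)
            elif e.annotation.trf_class in ("tRF-5", "tRF-1"):
                assert parent_seq.startswith(e.sequence)

    def test_empty_profile_rejected(self, gen_ref):
        with pytest.raises(ValueError, match="profile"):
            simulate_fragment_pool(gen_ref, {}, 0.5, seed=1)


def _single_entry_pool(seq="GCTAACGTACGTACGTACGTCA", copies=1000, mod_pos=4):
    # position 4 is an A, mimicking the tRF-3b m1A site
    from trfm1a.core import FragmentAnnotation
    ann = FragmentAnnotation("x", "other", "none", 1, len(seq))
    status = {mod_pos: True} if mod_pos else {}
    return MoleculePool([PoolEntry(seq, ann, copies, status)])


class TestRTModel:
    def test_total_stall_discards_modified_molecules(self):
        rt = RTModel("stall", p_mis=0.0, p_stall=1.0, eps_bg=0.0)
        reads, stats = apply_rt_model(_single_entry_pool(copies=500), rt, 1)
        assert stats == {"molecules": 500, "stalled": 500, "emitted": 0}
        assert not reads

    def test_certain_misincorporation_marks_every_read(self):
        rt = RTModel("mis", p_mis=1.0, p_stall=0.0, eps_bg=0.0)
        pool = _single_entry_pool(copies=300)
        ref_seq = pool.entries[0].sequence
        reads, stats = apply_rt_model(pool, rt, 1)
        assert sum(reads.values()) == 300
        for seq in reads:
            assert seq[3] != ref_seq[3] and seq[3] in "CGT"
            assert _hamming(seq, ref_seq) == 1

    def test_read_count_conservation(self):
        pool = _single_entry_pool(copies=5000)
        reads, stats = apply_rt_model(pool, TGIRT, 2)
        assert stats["emitted"] == stats["molecules"] - stats["stalled"]
        assert sum(reads.values()) == stats["emitted"]

    def test_background_rate_matches_tgirt_default(self):
        """Unmodified molecules under TGIRT show ~0.2% per-base mismatch."""
        pool = _single_entry_pool(copies=50_000, mod_pos=None)
        ref_seq = pool.entries[0].sequence
        reads, _ = apply_rt_model(pool, TGIRT, 3)
        bases = mismatches = 0
        for seq, n in reads.items():
            bases += len(seq) * n
            mismatches += _hamming(seq, ref_seq) * n
        rate = mismatches / bases
        se = math.sqrt(0.002 * 0.998 / bases)
        assert abs(rate - 0.002) < 4 * se

    def test_site_mismatch_rate_converges_to_closed_form(self):
        p, copies = 0.7, 100_000
        pool, _ = None, None
        entry_mod = _single_entry_pool(copies=int(copies * p))
        entry_unmod = _single_entry_pool(copies=copies - int(copies * p),
                                         mod_pos=None)
        pool = MoleculePool(entry_mod.entries + entry_unmod.entries)
        ref_seq = pool.entries[0].sequence
        reads, _ = apply_rt_model(pool, TGIRT, 4)
        total = sum(reads.values())
        mis = sum(n for seq, n in reads.items() if seq[3] != ref_seq[3])
        expected = expected_site_mismatch_rate(p, TGIRT)
        se = math.sqrt(expected * (1 - expected) / total)
        assert abs(mis / total - expected) < 4 * se

    def test_expected_rate_monotone_in_stoichiometry(self):
        grid = np.linspace(0, 1, 11)
        for rt in (TGIRT, PSII):
            vals = [expected_site_mismatch_rate(p, rt) for p in grid]
            assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestRIP:
    def _two_fragment_pool(self, n_mod=50, n_unmod=9950, modified=True):
        mod = _single_entry_pool("GCTAACGTACGTACGTACGTCA", n_mod,
                                 4 if modified else None)
        unmod = _single_entry_pool("TTGACCGTAGGCATCAGATCAC", n_unmod, None)
        return MoleculePool(mod.entries + unmod.entries)

    def test_no_enrichment_factor_keeps_ratios(self):
        pool = self._two_fragment_pool(2000, 8000)
        clean = RTModel("clean", 0.0, 0.0, 0.0)
        arms = simulate_rip(pool, RIPConfig(1.0, 1.0, 20_000), clean, 1)
        mod_seq = pool.entries[0].sequence
        f_in = arms["input"][mod_seq] / sum(arms["input"].values())
        f_rip = arms["m1A_RIP"][mod_seq] / sum(arms["m1A_RIP"].values())
        se = math.sqrt(0.2 * 0.8 / 20_000)
        assert abs(f_in - f_rip) < 4 * se

    def test_planted_eightfold_enrichment_recovers_log2_of_3(self):
        """A fully modified minor fragment planted at 8x RIP preference shows
        ~3 log2 fold enrichment after depth normalization (3 replicates)."""
        clean = RTModel("clean", 0.0, 0.0, 0.0)
        pool = self._two_fragment_pool(50, 9950)
        mod_seq = pool.entries[0].sequence
        log2fes = []
        for seed in (1, 2, 3):
            arms = simulate_rip(pool, RIPConfig(8.0, 1.0, 50_000), clean, seed)
            f_in = arms["input"][mod_seq] / sum(arms["input"].values())
            f_rip = arms["m1A_RIP"][mod_seq] / sum(arms["m1A_RIP"].values())
            log2fes.append(math.log2(f_rip / f_in))
        # compositional expectation for a 0.5% spike at 8x preference
        w_mod = 8 * 50
        expect = math.log2((w_mod / (w_mod + 9950)) / (50 / 10_000))
        assert abs(expect - 3.0) < 0.1
        assert abs(np.mean(log2fes) - expect) < 3 * np.std(log2fes) / math.sqrt(3) + 0.05

    def test_unmodified_fragment_not_enriched(self):
        clean = RTModel("clean", 0.0, 0.0, 0.0)
        pool = self._two_fragment_pool(2000, 8000, modified=False)
        arms = simulate_rip(pool, RIPConfig(8.0, 1.0, 30_000), clean, 2)
        seq = pool.entries[0].sequence
        f_in = arms["input"][seq] / sum(arms["input"].values())
        f_rip = arms["m1A_RIP"][seq] / sum(arms["m1A_RIP"].values())
        assert abs(math.log2(f_rip / f_in)) < 0.05

    def test_igg_arm_depth_scales_with_capture(self):
        clean = RTModel("clean", 0.0, 0.0, 0.0)
        pool = self._two_fragment_pool(100, 900)
        arms = simulate_rip(pool, RIPConfig(4.0, 0.25, 10_000), clean, 3)
        assert sum(arms["IgG_RIP"].values()) == 2500


class TestExpressionTable:
    def test_empty_targets_are_pure_null(self):
        df = simulate_expression_table([f"g{i}" for i in range(3000)], {}, {},
                                       sigma=0.4, seed=1)
        assert (df.true_type == "non-target").all()
        assert abs(df.log2FC.mean()) < 4 * 0.4 / math.sqrt(3000)
        assert abs(df.log2FC.std() - 0.4) < 0.03

    def test_planted_shift_and_strongest_type_resolution(self):
        genes = [f"g{i}" for i in range(400)]
        table = simulate_expression_table(
            genes, {"8mer-A1": genes[:100], "6mer": genes[:200]},
            {"8mer-A1": -0.5, "6mer": -0.1}, sigma=0.3, seed=2)
        top = table[table.gene.isin(genes[:100])]
        assert (top.true_type == "8mer-A1").all()  # overlap -> strongest type
        assert abs(top.log2FC.mean() + 0.5) < 4 * 0.3 / 10
        frac_low = (table.baseMean <= 100).mean()
        assert 0.1 < frac_low < 0.3

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate_expression_table(["g"], {}, {}, sigma=0.0, seed=1)


class TestUTRPlanting:
    @pytest.mark.parametrize("site_type,expect_sub", [
        ("8mer-A1", None), ("7mer-m8", None), ("7mer-A1", None), ("6mer", None),
    ])
    def test_site_motif_realizes_its_definition(self, site_type, expect_sub):
        seed7 = "AGCTTAT"
        rng = np.random.default_rng(0)
        motif = site_motif(seed7, site_type, rng)
        core7 = simulate.revcomp(seed7)
        core6 = simulate.revcomp(seed7[:6])
        if site_type == "8mer-A1":
            assert motif == core7 + "A"
        elif site_type == "7mer-m8":
            assert motif.startswith(core7) and not motif.endswith("A")
        elif site_type == "7mer-A1":
            assert motif[1:7] == core6 and motif[0] != core7[0] and motif[-1] == "A"
        else:
            assert motif[1:7] == core6 and motif[0] != core7[0] and motif[-1] != "A"

    def test_planted_motifs_are_present_in_utrs(self):
        seed7 = "TAGCTTA"
        planted = {"g0": [(seed7, "8mer-A1")], "g1": [(seed7, "6mer")]}
        utrs = build_utrs(["g0", "g1", "g2"], planted, seed=3)
        assert simulate.revcomp(seed7) + "A" in utrs["g0"]
        assert simulate.revcomp(seed7[:6]) in utrs["g1"]
        assert len(utrs["g2"]) == 500
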