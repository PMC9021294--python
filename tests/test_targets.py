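import numpy as np
import pandas as pd
import pytest

from trfm1a import simulate
from trfm1a.targets import (
    SITE_TYPE_RANK,
    TargetGene,
    TargetSite,
    classify_gene_targets,
    cluster_seeds,
    extract_seed,
    repression_analysis,
    scan_utr,
    seed_overlap_with_mirnas,
    _revcomp,
)


# ---------------------------------------------------------------------------
# brute-force site oracle: test every offset against the four definitions
# ---------------------------------------------------------------------------

def scan_oracle(seed, utr):
    core7 = _revcomp(seed)
    core6 = _revcomp(seed[:6])
    sites = []
    # core7-anchored types
    for i in range(len(utr) - 7 + 1):
        if utr[i:i + 7] == core7:
            if i + 7 < len(utr) and utr[i + 7] == "A":
                sites.append((i + 1, "8mer-A1"))
            else:
                sites.append((i + 1, "7mer-m8"))
    core7_core6_starts = {s for s, _ in sites}  # 1-based core7 starts
    for j in range(len(utr) - 6 + 1):
        if utr[j:j + 6] == core6:
            if j in core7_core6_starts:   # 0-based j == core7 start (1-based j)
                continue                   # part of a core7 match
            if j + 6 < len(utr) and utr[j + 6] == "A":
                sites.append((j + 1, "7mer-A1"))
            else:
                sites.append((j + 1, "6mer"))
    return sorted(sites)


class TestExtractSeed:
    def test_examples(self):
        assert extract_seed("TAGCTTATCAGACTGATGTTGA") == "AGCTTAT"
        assert extract_seed("AAGCTTATC") == "AGCTTAT"

    def test_identical_2_to_8_share_seed(self):
        a = "TAGCTTATCAGACTGATGTTGA"
        b = "GAGCTTATTTTTTTTTTTTTTT"
        assert extract_seed(a) == extract_seed(b)

    def test_short_guide_rejected(self):
        with pytest.raises(ValueError):
            extract_seed("TAGCTTA")


class TestClusterSeeds:
    def test_arithmetic_example(self):
        counts = {"TAGCTTATCAGACTGATGTCCA": 60.0,   # seed X
                  "GAGCTTATCCCACTGATGTCCA": 30.0,   # seed X
                  "TTTTGGGACAGACTGATGTCCA": 10.0}   # seed Y
        families, k = cluster_seeds(counts, 0.90)
        assert [(f.seed, f.coverage_share) for f in families] == [
            ("AGCTTAT", 0.9), ("TTTGGGA", 0.1)]
        assert k == 1  # a 0.9 share meets the 0.90 coverage threshold

    def test_below_threshold_share_needs_more_seeds(self):
        counts = {"TAGCTTATCAGACTGATGTCCA": 89.0, "TTTTGGGACAGACTGATGTCCA": 11.0}
        _, k = cluster_seeds(counts, 0.90)
        assert k == 2

    def test_equal_counts_equal_shares(self):
        counts = {f"T{'ACGT' * 2}{i}CGTACGTACGTA".replace(str(i), "ACGT"[i]): 5.0
                  for i in range(4)}
        families, _ = cluster_seeds(counts)
        assert all(f.coverage_share == pytest.approx(1 / len(families))
                   for f in families)

    def test_single_and_empty(self):
        families, k = cluster_seeds({"TAGCTTATCAGACTGATGTCCA": 7.0})
        assert len(families) == 1 and families[0].coverage_share == 1.0 and k == 1
        assert cluster_seeds({}) == ([], 0)


class TestScanUTR:
    def test_canonical_examples(self):
        sites = scan_utr("AGCTTAT", "GGATAAGCTAGG")
        assert [(s.utr_position, s.site_type) for s in sites] == [(3, "8mer-A1")]
        sites = scan_utr("AGCTTAT", "GGATAAGCTGGG")
        assert [(s.utr_position, s.site_type) for s in sites] == [(3, "7mer-m8")]

    def test_core6_types(self):
        # core6 = TAAGCT; precede with non-A (not core7), follow with A / non-A
        sites = scan_utr("AGCTTAT", "GGTAAGCTAGG")
        assert [(s.utr_position, s.site_type) for s in sites] == [(3, "7mer-A1")]
        sites = scan_utr("AGCTTAT", "GGTAAGCTGGG")
        assert [(s.utr_position, s.site_type) for s in sites] == [(3, "6mer")]

    def test_n_never_matches(self):
        assert scan_utr("AGCTTAT", "GGATAAGCTNGG")[0].site_type == "7mer-m8"
        assert scan_utr("AGCTTAT", "GGATNAGCTAGG") == []

    def test_site_at_utr_end_lacks_a1(self):
        # core7 flush with the 3' end: no position for the A1 adenosine
        sites = scan_utr("AGCTTAT", "GGATAAGCT")
        assert [(s.utr_position, s.site_type) for s in sites] == [(3, "7mer-m8")]

    def test_oracle_equivalence_on_random_pairs(self):
        """Scanner output matches the brute-force four-definition oracle on
        100 random (seed, UTR) pairs with planted and background sites."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            seed = "".join("ACGT"[i] for i in rng.integers(0, 4, 7))
            utr = list("".join("ACGT"[i] for i in rng.integers(0, 4, 300)))
            # plant a couple of motifs to guarantee matches
            for st in ("8mer-A1", "6mer"):
                pos = int(rng.integers(0, 250))
                motif = simulate.site_motif(seed, st, rng)
                utr[pos:pos + len(motif)] = list(motif)
            utr = "".join(utr[:300])
            got = sorted((s.utr_position, s.site_type)
                         for s in scan_utr(seed, utr))
            assert got == scan_oracle(seed, utr), (seed, utr)

    def test_invalid_seed_length(self):
        with pytest.raises(ValueError):
            scan_utr("AGCTTA", "ACGT" * 10)


class TestClassifyGeneTargets:
    def _expr(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2FC", "baseMean"])

    def test_highest_rank_and_multi_site(self):
        sites = {"g1": [TargetSite("g1", 1, "8mer-A1", "AGCTTAT")]
                 + [TargetSite("g1", i, "6mer", "AGCTTAT") for i in (30, 60, 90)],
                 "g2": []}
        expr = self._expr([("g1", -0.4, 500.0), ("g2", 0.1, 500.0)])
        targets, nontargets = classify_gene_targets(sites, expr, {"g1", "g2"})
        assert targets == [TargetGene("g1", "8mer-A1", 4)]
        assert targets[0].multi_site
        assert nontargets == ["g2"]

    def test_expression_filter_is_strict(self):
        sites = {"g1": [TargetSite("g1", 1, "6mer", "AGCTTAT")],
                 "g2": [TargetSite("g2", 1, "6mer", "AGCTTAT")]}
        expr = self._expr([("g1", 0.0, 100.0), ("g2", 0.0, 100.5)])
        targets, nontargets = classify_gene_targets(sites, expr, {"g1", "g2"})
        assert [t.gene for t in targets] == ["g2"]  # baseMean 100 excluded
        assert "g1" not in nontargets

    def test_gene_without_utr_excluded_entirely(self):
        expr = self._expr([("g1", 0.0, 500.0)])
        targets, nontargets = classify_gene_targets({}, expr, set())
        assert targets == [] and nontargets == []

    def test_duplicate_genes_rejected(self):
        expr = self._expr([("g1", 0.0, 500.0), ("g1", 0.1, 600.0)])
        with pytest.raises(ValueError, match="duplicate"):
            classify_gene_targets({}, expr, {"g1"})

    def test_partition_property(self):
        """Every expressed gene with a UTR lands in exactly one class."""
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        sites = {}
        for g in genes:
            k = int(rng.integers(0, 3))
            sites[g] = [TargetSite(g, 1 + 10 * j,
                                   SITE_TYPE_RANK[rng.integers(0, 4)], "X" * 7)
                        for j in range(k)]
        expr = self._expr([(g, 0.0, float(rng.uniform(10, 1000)))
                           for g in genes])
        targets, nontargets = classify_gene_targets(sites, expr, set(genes))
        eligible = set(expr[expr.baseMean > 100].gene)
        assert {t.gene for t in targets} | set(nontargets) == eligible
        assert not ({t.gene for t in targets} & set(nontargets))


def _planted_result(deltas, n_per_class=300, n_nontarget=1000, sigma=0.4, seed=0):
    rng = np.random.default_rng(seed)
    log2fc = {}
    targets = []
    for cls, delta in deltas.items():
        for i in range(n_per_class):
            g = f"{cls}_{i}"
            log2fc[g] = rng.normal(delta, sigma)
            targets.append(TargetGene(g, cls, 1))
    nontargets = [f"nt_{i}" for i in range(n_nontarget)]
    for g in nontargets:
        log2fc[g] = rng.normal(0, sigma)
    return targets, nontargets, log2fc


class TestRepressionAnalysis:
    def test_nontarget_centered_median_is_zero(self):
        tg, nt, fc = _planted_result({"6mer": -0.1}, seed=1)
        res = repression_analysis(tg, nt, fc)
        assert np.median(res.centered_values["non-target"]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_type_one_error_controlled(self):
        """Null targets (no shift): at most ~5% of 200 seeds reach p<0.05."""
        hits = 0
        n_seeds = 200
        for s in range(n_seeds):
            tg, nt, fc = _planted_result({"8mer-A1": 0.0}, n_per_class=100,
                                         n_nontarget=300, seed=s)
            res = repression_analysis(tg, nt, fc)
            p = res.classes.set_index("site_type").loc["8mer-A1", "p"]
            if p < 0.05:
                hits += 1
        assert hits / n_seeds <= 0.07

    def test_power_at_planted_shift(self):
        """delta = -0.5, sigma = 0.4, n = 300: one-sided K-S p < 0.01 in
        >90% of seeds."""
        detected = 0
        n_seeds = 50
        for s in range(n_seeds):
            tg, nt, fc = _planted_result({"8mer-A1": -0.5}, seed=300 + s)
            res = repression_analysis(tg, nt, fc)
            p = res.classes.set_index("site_type").loc["8mer-A1", "p"]
            if p < 0.01:
                detected += 1
        assert detected / n_seeds > 0.9

    def test_stronger_sites_more_significant(self):
        """Planted 8/7mer shifts stronger than 6mer: their K-S p is smaller
        than the 6mer p in >=90% of seeds."""
        wins = 0
        n_seeds = 40
        for s in range(n_seeds):
            tg, nt, fc = _planted_result(
                {"8mer-A1": -0.5, "7mer-m8": -0.3, "6mer": -0.1}, seed=600 + s)
            res = repression_analysis(tg, nt, fc)
            p = res.classes.set_index("site_type")["p"]
            if max(p["8mer-A1"], p["7mer-m8"]) < p["6mer"]:
                wins += 1
        assert wins / n_seeds >= 0.9

    def test_derepression_direction(self):
        tg, nt, fc = _planted_result({"8mer-A1": +0.5}, seed=7)
        up = repression_analysis(tg, nt, fc, direction="derepressed")
        down = repression_analysis(tg, nt, fc, direction="repressed")
        p_up = up.classes.set_index("site_type").loc["8mer-A1", "p"]
        p_down = down.classes.set_index("site_type").loc["8mer-A1", "p"]
        assert p_up < 0.01 < p_down

    def test_small_class_reports_na(self):
        tg, nt, fc = _planted_result({"8mer-A1": -0.5}, n_per_class=5, seed=8)
        res = repression_analysis(tg, nt, fc)
        assert np.isnan(res.classes.set_index("site_type").loc["8mer-A1", "p"])

    def test_ecdf_table_monotone(self):
        tg, nt, fc = _planted_result({"6mer": -0.2}, seed=9)
        res = repression_analysis(tg, nt, fc)
        ecdf = res.ecdf_table("6mer")
        assert ecdf.ecdf.is_monotonic_increasing
        assert ecdf.ecdf.iloc[-1] == 1.0

    def test_unknown_direction_rejected(self):
        tg, nt, fc = _planted_result({"6mer": 0.0}, seed=10)
        with pytest.raises(ValueError):
            repression_analysis(tg, nt, fc, direction="sideways")


class TestMiRNAOverlap:
    def test_expressed_mirna_seed_matches(self):
        mirs = {"miR-X": ("TAGCTTATCAGACTGATGTTGA", 50.0)}
        assert seed_overlap_with_mirnas("AGCTTAT", mirs)

    def test_below_threshold_mirna_ignored(self):
        mirs = {"miR-X": ("TAGCTTATCAGACTGATGTTGA", 10.0)}  # not > 10
        assert not seed_overlap_with_mirnas("AGCTTAT", mirs)

    def test_empty_list(self):
        assert not seed_overlap_with_mirnas("AGCTTAT", {})
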