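"""End-to-end orchestration: configuration, simulation and analysis runs.

A single structured YAML configuration drives every generator and every
threshold; each stochastic stage must name an explicit seed, and a run is
refused otherwise.  All output tables carry the configuration hash in a
leading ``# config_hash:`` comment line, and a manifest records seeds,
thresholds and stage tallies with read-count conservation checkpoints.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from collections import Counter
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from trfm1a import annotate, calibration, enrichment, mismatch, simulate, targets
from trfm1a.core import ReferenceSet

logger = logging.getLogger(__name__)

REQUIRED_SEEDS = ("reference", "pool", "rt", "rip_ab1", "rip_ab2", "expression", "utr")


class ConfigurationError(ValueError):
    pass


class DataError(ValueError):
    pass


class ContractError(RuntimeError):
    pass


@dataclass
class RunConfig:
    seeds: dict[str, int] = field(default_factory=dict)
    reference: dict = field(default_factory=lambda: dict(
        n_trna=6, n_mir=8, n_spike=2, n_control=1, n_mito=1))
    pool: dict = field(default_factory=lambda: dict(
        n_molecules=40_000, stoichiometry=0.8, profile=None))
    rt_model: str = "TGIRT"
    rt_overrides: dict = field(default_factory=dict)
    rip: dict = field(default_factory=lambda: dict(
        enrichment_factor=8.0, igg_capture=1.0, lib_depth=40_000))
    expression: dict = field(default_factory=lambda: dict(
        n_genes=1000, sigma=0.4, frac_low_expr=0.2, n_targets_per_type=60,
        shifts={"8mer-A1": -0.5, "7mer-m8": -0.3, "7mer-A1": -0.3, "6mer": -0.1}))
    thresholds: dict = field(default_factory=lambda: dict(
        min_reads=50, min_count=10, padj_cut=0.1, strict_padj_cut=1e-5,
        min_expr=100, halves_cutoff=30, seed_coverage=0.90,
        mismatch_evidence=10.0))

    def __post_init__(self) -> None:
        missing = [s for s in REQUIRED_SEEDS if s not in self.seeds]
        if missing:
            raise ConfigurationError(
                f"every stochastic stage needs an explicit seed; missing: {missing}")
        for k, v in self.thresholds.items():
            if not isinstance(v, (int, float)) or v <= 0:
                raise ConfigurationError(f"threshold {k} must be positive, got {v!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def default(cls, master_seed: int = 0) -> "RunConfig":
        rng = np.random.SeedSequence(master_seed)
        seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                 for name, s in zip(REQUIRED_SEEDS, rng.spawn(len(REQUIRED_SEEDS)))}
        return cls(seeds=seeds)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def rt(self) -> simulate.RTModel:
        if self.rt_model not in simulate.RT_PRESETS:
            raise ConfigurationError(f"unknown RT model {self.rt_model!r}")
        base = simulate.RT_PRESETS[self.rt_model]
        if not self.rt_overrides:
            return base
        kwargs = dict(name=base.name, p_mis=base.p_mis, p_stall=base.p_stall,
                      eps_bg=base.eps_bg, mis_spectrum=base.mis_spectrum)
        kwargs.update(self.rt_overrides)
        return simulate.RTModel(**kwargs)


def _write_tsv(df: pd.DataFrame, path: str, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _read_fastq_counts(path: str) -> Counter:
    reads: Counter = Counter()
    for rec in SeqIO.parse(path, "fastq"):
        seq = str(rec.seq)
        if not seq or not set(seq) <= set("ACGTN"):
            raise DataError(f"corrupted FASTQ record {rec.id} in {path}")
        reads[seq] += 1
    return reads


# ---------------------------------------------------------------------------
# Simulation run
# ---------------------------------------------------------------------------

def run_simulate(config: RunConfig, outdir: str) -> dict:
    """Generate a full synthetic dataset under the configured conditions.

    Produces reference FASTAs, truth tables, FASTQ libraries for input /
    two m1A-antibody RIP arms / IgG control, planted-site 3' UTRs and a
    gene expression table, plus a manifest.  Deterministic under the
    config's seeds.
    """
    os.makedirs(outdir, exist_ok=True)
    ref = simulate.build_reference(config.seeds["reference"], **config.reference)
    ref.to_dir(os.path.join(outdir, "reference"))

    profile = config.pool.get("profile") or simulate.DEFAULT_PROFILE
    pool, truth = simulate.simulate_fragment_pool(
        ref, profile, config.pool.get("stoichiometry", 0.8),
        n_molecules=config.pool.get("n_molecules", 40_000),
        seed=config.seeds["pool"])
    _write_tsv(truth, os.path.join(outdir, "truth_pool.tsv"), config.config_hash)

    rt = config.rt()
    rip_cfg = simulate.RIPConfig(
        enrichment_factor=config.rip.get("enrichment_factor", 8.0),
        igg_capture=config.rip.get("igg_capture", 1.0),
        lib_depth=config.rip.get("lib_depth", 40_000))
    arms1 = simulate.simulate_rip(pool, rip_cfg, rt, config.seeds["rip_ab1"])
    arms2 = simulate.simulate_rip(pool, rip_cfg, rt, config.seeds["rip_ab2"])
    libraries = {"input": arms1["input"], "ab1_RIP": arms1["m1A_RIP"],
                 "ab2_RIP": arms2["m1A_RIP"], "IgG_RIP": arms1["IgG_RIP"]}
    read_counts = {}
    for arm, reads in libraries.items():
        read_counts[arm] = simulate.write_fastq(
            reads, os.path.join(outdir, f"{arm}.fastq"), prefix=arm)

    # seed-target arm: plant sites for the top tRF-3b seeds
    exp_cfg = config.expression
    trf3b_seqs = sorted({e.sequence for e in pool.entries
                         if e.annotation.size_isoform == "3b"})
    seeds7 = sorted({targets.extract_seed(s) for s in trf3b_seqs})
    genes = [f"gene{i:04d}" for i in range(exp_cfg.get("n_genes", 1000))]
    rng = np.random.default_rng(config.seeds["utr"])
    shifts = exp_cfg.get("shifts", {})
    n_per_type = exp_cfg.get("n_targets_per_type", 60)
    planted: dict[str, list[tuple[str, str]]] = {}
    targets_by_type: dict[str, list[str]] = {}
    free = list(genes)
    rng.shuffle(free)
    for site_type in targets.SITE_TYPE_RANK:
        chosen, free = free[:n_per_type], free[n_per_type:]
        targets_by_type[site_type] = chosen
        for g in chosen:
            seed7 = seeds7[int(rng.integers(0, len(seeds7)))]
            planted[g] = [(seed7, site_type)]
    utrs = simulate.build_utrs(genes, planted, seed=rng)
    with open(os.path.join(outdir, "utrs.fa"), "w") as fh:
        for g in genes:
            fh.write(f">{g}\n{utrs[g]}\n")
    expr = simulate.simulate_expression_table(
        genes, targets_by_type, shifts, sigma=exp_cfg.get("sigma", 0.4),
        seed=config.seeds["expression"],
        frac_low_expr=exp_cfg.get("frac_low_expr", 0.2),
        min_expr=config.thresholds["min_expr"])
    _write_tsv(expr, os.path.join(outdir, "expression.tsv"), config.config_hash)

    manifest = dict(config=asdict(config), config_hash=config.config_hash,
                    n_molecules=pool.n_molecules, n_modified=pool.n_modified,
                    library_reads=read_counts, trf3b_seeds=seeds7)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Analysis run
# ---------------------------------------------------------------------------

def run_analyze(config: RunConfig, dataset: str, outdir: str) -> dict:
    """Run annotation -> mismatch -> enrichment -> targets on a dataset.

    Stages whose inputs are absent are skipped with an explicit note in
    the summary.  Contract violations (count conservation, coverage
    accounting) abort with the violated invariant named.
    """
    os.makedirs(outdir, exist_ok=True)
    th = config.thresholds
    ref = ReferenceSet.from_dir(os.path.join(dataset, "reference"))
    index = annotate.build_index(ref)
    policy = annotate.MappingPolicy()
    summary: dict = {"config_hash": config.config_hash, "skipped": [],
                     "stages": {}}

    arms = {}
    for arm in ("input", "ab1_RIP", "ab2_RIP", "IgG_RIP"):
        path = os.path.join(dataset, f"{arm}.fastq")
        if os.path.exists(path):
            arms[arm] = _read_fastq_counts(path)
    if "input" not in arms:
        raise DataError("dataset has no input.fastq")

    aligned_by_arm, tables = {}, {}
    for arm, reads in arms.items():
        aligned, tally = annotate.annotate_reads(reads, index, policy)
        table = annotate.make_count_table(aligned, min_count=th["min_count"])
        total = table["count"].sum()
        if abs(total - tally["mapped"]) > 1e-6 * max(1, tally["mapped"]):
            raise ContractError(
                f"count conservation violated in {arm}: "
                f"fractional total {total} != mapped {tally['mapped']}")
        aligned_by_arm[arm] = aligned
        tables[arm] = table
        _write_tsv(table, os.path.join(outdir, f"counts_{arm}.tsv"),
                   config.config_hash)
        annotate.write_annotation_tsv(
            aligned, os.path.join(outdir, f"annotation_{arm}.tsv"))
        summary["stages"][f"annotate_{arm}"] = tally

    # mismatch profiles on the input arm
    aligned_input = aligned_by_arm["input"]
    profiles = {t.name: mismatch.pileup(aligned_input, t.name, frame="mature")
                for t in ref.tRNAs}
    profiles.update({n: mismatch.pileup(aligned_input, n, frame="mature")
                     for n, _, _ in ref.spike_ins})
    pooled_3b = mismatch.pileup(
        aligned_input, {"parent": None, "trf_class": "tRF-3",
                        "size_isoform": "3b"}, frame="fragment")
    _write_tsv(pooled_3b.to_frame(), os.path.join(outdir, "mismatch_trf3b.tsv"),
               config.config_hash)
    site_tbl = mismatch.site_report(profiles, ref.mod_sites, th["min_reads"])
    _write_tsv(site_tbl, os.path.join(outdir, "site_mismatch.tsv"),
               config.config_hash)
    summary["stages"]["mismatch"] = {
        "trf3b_peak_position": mismatch.peak_position(pooled_3b, th["min_reads"])}

    # spike-in normalization
    if (tables["input"]["trf_class"] == "spikeIn").any():
        freq = calibration.spikein_normalized_frequency(tables["input"], "input")
        _write_tsv(freq, os.path.join(outdir, "spikein_normalized_input.tsv"),
                   config.config_hash)
    else:
        summary["skipped"].append("spike-in normalization: no spike-in counts")

    # enrichment + candidate calls
    ab_arms = [a for a in ("ab1_RIP", "ab2_RIP") if a in tables]
    if ab_arms:
        def group_counts(table: pd.DataFrame) -> dict[str, float]:
            # clustered on parental gene level: (parent, class) groups
            g = table.groupby(["parent", "trf_class"])["count"].sum()
            return {f"{p}|{c}": float(v) for (p, c), v in g.items()}

        input_counts = group_counts(tables["input"])
        ab_tables = {}
        for arm in ab_arms:
            tbl = enrichment.enrichment_table(
                input_counts, group_counts(tables[arm]),
                min_count=th["min_count"])
            ab_tables[arm] = tbl
            _write_tsv(tbl, os.path.join(outdir, f"enrichment_{arm}.tsv"),
                       config.config_hash)
            volcano = tbl.assign(neg_log10_padj=-np.log10(tbl["padj"]))
            _write_tsv(volcano[["key", "log2fe", "neg_log10_padj"]],
                       os.path.join(outdir, f"volcano_{arm}.tsv"),
                       config.config_hash)
        igg_tbl = None
        if "IgG_RIP" in tables:
            igg_tbl = enrichment.enrichment_table(
                input_counts, group_counts(tables["IgG_RIP"]),
                min_count=th["min_count"])
        else:
            summary["skipped"].append("IgG control arm absent")
        site_mm = {}
        for _, row in site_tbl.iterrows():
            if row["defined"]:
                for cls_key in _classes_containing_site(ref, row, tables["input"]):
                    site_mm[cls_key] = max(site_mm.get(cls_key, 0.0),
                                           row["mismatch_index"])
        calls = enrichment.call_m1a_candidates(
            ab_tables, igg_tbl, site_mm, padj_cut=th["padj_cut"],
            mismatch_cut=th["mismatch_evidence"])
        _write_tsv(enrichment.calls_to_frame(calls),
                   os.path.join(outdir, "m1a_candidates.tsv"), config.config_hash)
        summary["stages"]["enrichment"] = {
            "n_candidates": sum(c.verdict == "candidate" for c in calls)}
    else:
        summary["skipped"].append("enrichment: no antibody RIP arms")

    # seed targets
    utr_path = os.path.join(dataset, "utrs.fa")
    expr_path = os.path.join(dataset, "expression.tsv")
    if os.path.exists(utr_path) and os.path.exists(expr_path):
        t3b = tables["input"]
        mask = (t3b["trf_class"] == "tRF-3") & (t3b["size_isoform"] == "3b")
        guide_counts: dict[str, float] = {}
        for ar in aligned_input:
            for h in ar.hits:
                a = h.annotation
                if a and a.trf_class == "tRF-3" and a.size_isoform == "3b":
                    # alignment-corrected guide: the reference sequence under
                    # the hit, so RT misincorporations (which fall inside the
                    # seed region) do not fragment seed families
                    alen = len(ar.sequence) - h.clip
                    seq = ref.sequence(h.reference)[h.start - 1:h.start - 1 + alen]
                    guide_counts[seq] = guide_counts.get(seq, 0.0) + h.weight * ar.count
        families, k_cover = targets.cluster_seeds(guide_counts,
                                                  th["seed_coverage"])
        fam_df = pd.DataFrame([dict(seed=f.seed, n_members=len(f.members),
                                    coverage_share=f.coverage_share)
                               for f in families])
        _write_tsv(fam_df, os.path.join(outdir, "seed_families.tsv"),
                   config.config_hash)
        utrs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(utr_path, "fasta")}
        expr = read_tsv(expr_path)
        top_seeds = [f.seed for f in families[:max(k_cover, 1)]]
        sites_by_gene = {
            g: [s for sd in top_seeds for s in targets.scan_utr(sd, utr, g)]
            for g, utr in utrs.items()}
        tg, nt = targets.classify_gene_targets(sites_by_gene, expr,
                                               set(utrs), th["min_expr"])
        tg_df = pd.DataFrame([dict(gene=t.gene, best_type=t.best_type,
                                   site_count=t.site_count,
                                   multi_site=t.multi_site) for t in tg])
        _write_tsv(tg_df, os.path.join(outdir, "target_genes.tsv"),
                   config.config_hash)
        rep = targets.repression_analysis(tg, nt, expr, direction="repressed")
        _write_tsv(rep.classes, os.path.join(outdir, "ks_summary.tsv"),
                   config.config_hash)
        for cls, vals in rep.centered_values.items():
            if len(vals):
                _write_tsv(rep.ecdf_table(cls),
                           os.path.join(outdir, f"ecdf_{cls.replace('/', '_')}.tsv"),
                           config.config_hash)
        with open(os.path.join(outdir, "ks_summary.json"), "w") as fh:
            json.dump({"direction": rep.direction, "center": rep.center,
                       "n_seeds_for_coverage": k_cover,
                       "classes": rep.classes.to_dict("records"),
                       "multiple_testing": "none (per-class K-S p reported)"},
                      fh, indent=2)
        summary["stages"]["targets"] = {
            "n_trf3b_guides": int(mask.sum()), "n_seed_families": len(families),
            "k_seeds_covering": k_cover, "n_targets": len(tg),
            "n_non_targets": len(nt)}
    else:
        summary["skipped"].append("targets: no UTR/expression inputs")

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _classes_containing_site(ref: ReferenceSet, site_row, count_table: pd.DataFrame
                             ) -> list[str]:
    """Group keys (parent|class) whose fragments cover an annotated site."""
    parent = site_row["reference"]
    out = []
    for _, row in count_table.iterrows():
        if row["parent"] == parent:
            out.append(f"{row['parent']}|{row['trf_class']}")
    return sorted(set(out))


# ---------------------------------------------------------------------------
# Calibration run (stoichiometry gradient on the control oligo)
# ---------------------------------------------------------------------------

def run_calibration(config: RunConfig, outdir: str,
                    levels=(0, 20, 40, 60, 80, 100),
                    reads_per_level: int = 10_000) -> dict:
    """Simulate a control-oligo stoichiometry gradient and fit the curve.

    Mirrors the benchtop design: the m1A-modified and unmodified control
    oligos are mixed at each stated ratio, sequenced with the configured
    RT, and the observed mismatch% at the annotated site is regressed on
    the known stoichiometry% with a zero-intercept fit.
    """
    os.makedirs(outdir, exist_ok=True)
    ref = simulate.build_reference(config.seeds["reference"], **config.reference)
    controls = [(n, s) for n, s, qc in ref.spike_ins if not qc]
    if not controls:
        raise ConfigurationError("reference has no m1A control oligo")
    name, _ = controls[0]
    site = ref.sites_on(name)[0]
    rt = config.rt()
    rng = np.random.default_rng(config.seeds["rt"])
    points = []
    for level in levels:
        pool, _ = simulate.simulate_fragment_pool(
            ref, {"spikeIn": 1.0}, {(name, site.position): level / 100.0},
            n_molecules=reads_per_level, seed=rng)
        reads, _ = simulate.apply_rt_model(pool, rt, rng)
        aligned, _ = annotate.annotate_reads(reads, annotate.build_index(ref))
        prof = mismatch.pileup(aligned, name, frame="mature")
        idx = mismatch.mismatch_index(prof, site.position,
                                      config.thresholds["min_reads"])
        if idx.defined:
            points.append((float(level), idx.value))
    fit = calibration.fit_calibration(points)
    out = dict(slope=fit.slope, r2=fit.r2, background=fit.background,
               points=list(fit.points), rt_model=rt.name,
               config_hash=config.config_hash)
    with open(os.path.join(outdir, "calibration.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    return out
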