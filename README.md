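# trfm1a

Mapping N¹-methyladenosine (m¹A) in small RNAs — tRNA-derived fragments in
particular — from reverse-transcriptase misincorporation signatures combined
with antibody (RIP) enrichment, plus the downstream seed-based analysis of
tRF-3 target repression.

## Who this is for

Small-RNA / epitranscriptomics researchers who want a tested, transparent
implementation of the misincorporation-based m¹A calling workflow:
hierarchical mismatch-tolerant mapping of trimmed small-RNA reads, tRF
taxonomy (tRF-5 / tRF-3 / tRF-1 / halves, with the 18-nt tRF-3a and 22-nt
tRF-3b size isoforms), per-position mismatch statistics, spike-in
calibration of modification stoichiometry, RIP-vs-input enrichment calls,
and seed-match (8mer-A1 / 7mer-m8 / 7mer-A1 / 6mer) target prediction with
a centered-CDF Kolmogorov–Smirnov repression test. A synthetic-data module
generates benchmark datasets with known ground truth, so every stage can be
exercised and validated at desk scale.

## The model in brief

m¹A blocks Watson–Crick pairing. During library preparation a reverse
transcriptase (RT) hitting an m¹A base either stalls — and in a
ligation-first protocol the truncated cDNA is never amplified, so the
molecule vanishes from the library — or reads through with a
misincorporation. For a site of stoichiometry *p*, RT misincorporation
probability *m*, stall probability *s* and per-base background error ε, the
expected mismatch fraction among emitted reads is

    f(p) = φ·(m + (1 − m)·ε) + (1 − φ)·ε,   φ = p(1 − s) / (1 − p·s)

The **mismatch index** at a position is 100 × (reads with a non-reference
base) / (total reads), defined only above 50-read coverage. A zero-intercept
least-squares fit of observed mismatch% against known stoichiometry%
(slope = Σxy/Σx², uncentered R²) calibrates the curve on synthetic spike-in
gradients; inverting it gives a semi-quantitative stoichiometry estimate.

On a canonical 76-nt mature tRNA (CCA included), the T-loop m¹A₅₈ falls at
**fragment position 4 of the 22-nt tRF-3b** — inside the seed region
(guide positions 2–8) used for target prediction, which is why the
modification interferes with tRF-3 gene silencing.

## Worked example

```python
from trfm1a import pipeline

cfg = pipeline.RunConfig.default(1)          # explicit seeds for every stage

# calibrate: simulate the control-oligo stoichiometry gradient (0–100% m1A)
fit = pipeline.run_calibration(cfg, "out/cal")
print(f"slope={fit['slope']:.3f} r2={fit['r2']:.4f} "
      f"background={fit['background']:.3f}")
# slope=0.831 r2=0.9998 background=0.239

# simulate a full dataset and analyze it end to end
pipeline.run_simulate(cfg, "out/dataset")
summary = pipeline.run_analyze(cfg, "out/dataset", "out/results")
print(summary["stages"]["mismatch"])   # {'trf3b_peak_position': 4}
print(summary["stages"]["targets"])
# {'n_trf3b_guides': 6, 'n_seed_families': 6, 'k_seeds_covering': 6,
#  'n_targets': 489, 'n_non_targets': 285}
```

What the numbers mean: the calibration slope ≈ 0.83 mismatch% per
stoichiometry% is the effective misincorporation rate of the TGIRT error
model (p_mis = 0.85, slightly attenuated by stalling and mapping losses)
with R² ≈ 1 on a forced-through-zero fit; the ~0.24% background is the
TGIRT per-base error. The pooled tRF-3b mismatch index peaks at fragment
position 4 — the A₅₈-equivalent site. Six seed families (one per simulated
tRNA 3′ end) cover the Ago-bound tRF-3b pool, and the K-S summary
(`out/results/ks_summary.tsv`) shows the planted repression ordering:

```
site_type     n   ks_stat        p
8mer-A1      78   0.356    9.9e-08
7mer-m8     115   0.237    7.5e-05
7mer-A1     108   0.233    1.6e-04
6mer        188   0.084    0.19
```

Stronger site types are more significantly repressed, the expected behavior
for seed-mediated silencing (the 6mer class is diluted by accidental
background matches, as with real UTRs).

The same pipeline is available from the shell:

```
trfm1a run-all --seed 1 --out out/
trfm1a simulate | analyze | calibrate   # individual stages; --config cfg.yaml
```

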