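# gdnet — phenotype-specific gene dependency networks

`gdnet` infers *gene dependency pairs*: directed relations B → A meaning
that the association between gene A and a binary phenotype (e.g. distant
metastasis vs. none in breast cancer) depends on the expression level of a
modulator gene B. Classical co-expression or regulatory-network methods ask
whether A controls B; this method asks whether B *gates* the A–phenotype
link, which surfaces driver-like modulators that are themselves only weakly
correlated with outcome. It is aimed at computational biologists working
with sample-based expression cohorts plus clinical follow-up.

## Method

For each candidate pair {A, B} (typically restricted to protein–protein
interaction partners), with A and the phenotype P median-binarized and
samples sorted by the continuous level of B:

```
I_low  = I(A ; P | B in bottom 35% of samples)
I_high = I(A ; P | B in top 35% of samples)
CMI    = | I_high − I_low |          (plug-in MI, bits)
```

Significance of each direction comes from a permutation null (default 1000
draws) that jointly shuffles the (A, P) pairs against B, with
p = (1 + #{null ≥ observed}) / N. Significant pairs form a directed,
CMI-weighted network whose out-degree hubs (top ~20%, out-degree ≥ 4) are
candidate drivers. A prognostic signature is then built by resampled
univariate Cox selection (400 runs × 75% subsamples, keeping genes with
p < 0.05 in ≥ 90% of runs), intersected with the hubs, and each patient is
scored GGI-style:

```
RiskScore = Σ x_i (positive Cox β)  −  Σ x_j (negative Cox β)
```

Cohorts are split at the risk-score median, compared with the log-rank
test, and multi-cohort discrimination is summarized by
`Dscore = Σ −log10 max(p_i, 1e-17)`, with Fisher's combined test
(X = 2 ln 10 · Dscore ~ χ²(2n)) and an empirical random-signature null for
significance.

Everything is testable offline: `gdnet.simulate` generates seeded datasets
with planted modulator gates and planted hazard genes.

## Worked example

```python
from gdnet import (CMIParams, GeneratorConfig, generate_dependency_dataset,
                   screen_pairs)

cfg = GeneratorConfig(n_samples=300, n_genes=220, n_modulated_pairs=10,
                      n_null_pairs=90, gate_strength=1.0, seed=7)
expr, phen, candidates, truth = generate_dependency_dataset(cfg)
pairs = screen_pairs(expr, phen, candidates, CMIParams(seed=3))
print(f"{len(pairs)} significant directed pairs")
planted = {(m, t) for m, t, _ in truth.modulated_pairs}
print(f"recovered {sum((p.modulator, p.target) in planted for p in pairs)}/10 planted directions")
top = max(pairs, key=lambda p: p.cmi)
print(f"strongest dependency: {top.modulator} -> {top.target} "
      f"(CMI {top.cmi:.3f} bits, p = {top.p_value})")
```

prints

```
31 significant directed pairs
recovered 10/10 planted modulator->target directions
strongest dependency: G0015 -> G0016 (CMI 0.998 bits, p = 0.001)
```

All 10 planted gated pairs pass the screen at α = 0.05; the ~21 additional
directions are the reverse orientations of planted pairs (which carry real
signal under a symmetric gate) plus false positives among the 180 null
directions at roughly the nominal rate. The strongest pair's CMI of ~1 bit
means the target–phenotype association is perfect in one modulator stratum
and absent in the other.

The survival half, on three synthetic cohorts sharing 5 planted hazard
genes (log-HR 0.6, n = 200 each):

```python
from gdnet import (generate_survival_family, resampled_candidate_selection,
                   ResamplingParams, Signature, evaluate_family, fisher_combined)

cohorts, truth = generate_survival_family(cfg)
candidates = resampled_candidate_selection(*cohorts[0], ResamplingParams(n_runs=100, seed=2))
sig = Signature(candidates)
report, d = evaluate_family(sig, cohorts[1:], names=["cohort2", "cohort3"])
print(report.to_string(index=False))
print(f"Dscore = {d:.4f}")
```

prints (with `cfg = GeneratorConfig(n_samples=200, n_genes=50,
n_hazard_genes=5, hazard_beta=0.6, n_datasets=3, seed=11)`)

```
dataset       HR  HR_CI_low  HR_CI_high    logrank_p
cohort2 5.387948   3.356646    8.648509 1.238051e-14
cohort3 3.505046   2.302934    5.334648 6.138709e-10
Dscore = 23.1192
```

The signature separates high- from low-risk halves in both held-out cohorts
(HR ≈ 3.5–5.4) and each cohort contributes −log10 p to the Dscore.

The same pipeline is scriptable from the shell: `gdnet make-fixtures`,
`gdnet network`, `gdnet signature`, `gdnet evaluate` (see `gdnet --help`);
every run writes a `manifest.json` with parameters, seed and input digests.

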