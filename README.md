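# ddmcn

Absolute mitochondrial DNA copy number (mCN) from single-dye multiplex
droplet digital PCR (ddPCR), plus a quantal-imaging estimator for
single-cell mCN.

`ddmcn` is aimed at labs measuring mCN with EvaGreen duplex ddPCR on
QX200-class instruments: it covers Poisson quantification of gated droplet
counts, automated amplitude gating, the primer-concentration calibration
model used to design intensity-separated duplex assays,
pseudogene-corrected copy-number arithmetic, dynamic-range planning, and a
quantal Gaussian-mixture analysis of imaged nucleoid puncta. Every stage can
be exercised on seeded synthetic data, so the full pipeline is testable
without instrument exports.

## The model

**Poisson quantification.** Template partitions into droplets so that the
negative fraction is `exp(-λ)`; the mean copies per droplet is

    λ = -ln(n_negative / n_total),     c = λ / V_d

with `V_d` the droplet volume (default 0.85 nl) and `c` in copies/µl of
reaction. Confidence intervals are Wilson intervals on the negative
fraction mapped through `-ln`.

**mCN arithmetic.** With a nuclear reference amplifying
`1 + pseudogenes` loci per genome,

    mCN = (c_mt / c_ref) · ploidy · (1 + pseudogenes)

A known-multi-copy reference (e.g. β-actin at 3 targets/genome) runs at
three times the concentration of a single-copy locus, tightening the
denominator and extending the usable dynamic range: for a 3000 copies/cell
tissue, the reference may run up to 6 copies/µl instead of 2 before the
mitochondrial target exceeds a 3000 copies/µl precision cap.

**Duplex design.** EvaGreen droplet intensity follows
`I = plateau · (1 − exp(−k·[primer]))` with `k = (L / (a·E))²` in amplicon
length `L`, primer efficiency `E` and a detector constant `a`; fitting
four-point calibration curves per primer pair lets you pick concentrations
that separate the two positive populations by a chosen multiple of their
spread, no more.

**Quantal imaging.** Nucleoid puncta intensities in a batch are modelled as
`Σₙ Aₙ·N(n·q, σ₁√n)` for `n = 1..10` genomes per punctum; a cell's mCN is
`Σ intensities / q`, which is invariant to how clustered nucleoids are
segmented.

## Worked example

Simulate a duplex well (mitochondrial target 2700 copies/µl, 3-copy
reference at 20 copies/µl, 16,000 droplets), gate it, and compute mCN:

```python
from ddmcn import (DuplexSimConfig, simulate_duplex_droplets, cluster_droplets,
                   quantify, ratio_estimate, mcn_from_ratio)

cfg = DuplexSimConfig(conc_a=2700.0, conc_b=20.0, seed=1)
table, labels, truth = simulate_duplex_droplets(cfg)
gates, counts = cluster_droplets(table, n_populations=4, seed=0)
est_mt = quantify(counts.negatives_for_target("posA"), counts.n_total)
est_ref = quantify(counts.negatives_for_target("posB"), counts.n_total)
res = mcn_from_ratio(ratio_estimate(est_mt, est_ref),
                     pseudogene_count=2, ploidy=2)
print(f"mt  {est_mt.concentration:.1f} copies/ul "
      f"(95% CI {est_mt.ci_low:.1f}-{est_mt.ci_high:.1f})")
print(f"ref {est_ref.concentration:.2f} copies/ul "
      f"(95% CI {est_ref.ci_low:.2f}-{est_ref.ci_high:.2f})")
print(f"mCN {res.mcn:.0f} copies/cell (CI {res.ci_low:.0f}-{res.ci_high:.0f})")
```

prints

```
mt  2725.2 copies/ul (95% CI 2670.3-2780.5)
ref 21.29 copies/ul (95% CI 18.97-23.90)
mCN 768 copies/cell (CI 683-864)
```

The configured truth is mCN = 2700/20 · 2 · 3 = 810, inside the propagated
interval; the reference's width dominates because at 20 copies/µl only a
few hundred droplets are positive.

The same conditions are reachable from the shell:

```bash
ddmcn simulate droplets --conc-a 2700 --conc-b 20 --seed 1 --out well.csv
ddmcn gate well.csv --populations 4
ddmcn mcn --ratio 128.0 --pseudogenes 2
ddmcn plan-range --mcn 3000 --ref-copies 3
```

The quantal-imaging side, on a simulated 36-cell batch
(`ddmcn quantal-fit puncta.csv`), prints the fitted quantal intensity and
the batch mCN summary, e.g. `q=992.6 sigma1=172.3 mCN 1024 +/- 246 (n=36)`
for a batch generated at q=1000, σ₁=150.

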