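# mmpsim

Modelling mitochondrial-membrane-potential (ΔΨ<sub>m</sub>) heterogeneity in
naive embryonic stem cells.

A bulk culture of naive ESCs shows a broad, multimodal distribution of
mitochondrial membrane potential, measured per cell as TMRM fluorescence by
flow cytometry. Cells sorted from the bottom ~5% of that distribution
(low-ΔΨ<sub>m</sub>, quiescence-prone) do not stay low: within a few cell
divisions their progeny re-establish the full parental distribution.
`mmpsim` packages the quantitative side of that observation for
computational biologists:

1. **Mixture decomposition** — the TMRM intensity distribution is fitted as
   a K-component univariate Gaussian mixture
   f(x) = Σ<sub>k</sub> w<sub>k</sub> N(x | μ<sub>k</sub>, σ<sub>k</sub>²)
   by expectation–maximization, with BIC component selection, and the
   high/low-ΔΨ<sub>m</sub> subpopulation probabilities read off as mixture
   tail mass.
2. **Percentile gating** — rank-based bottom/top fraction gates
   (floor rounding, stable ties), mirroring FACS sorting practice.
3. **Division simulation** — a stochastic model in which every daughter
   cell's activity *a* takes one of three outcomes per division:
   decreased (*a* ← max(1, *a*·U[m, 1])), unchanged, or increased
   (*a* ← *a*·U[1, t]), with outcome probabilities conditioned on the
   parent's activity stratum. Low-ΔΨ<sub>m</sub> daughters increase with
   probability P<sub>k</sub> = 0.8; the activity-fluctuation coefficient
   t = 1.25 means activity alters up to ~25% per division.
4. **Inference** — grid-search estimation of t from per-generation mean
   activities (the absolute-mean-difference objective, common random
   numbers across the grid), and quantification of how many divisions a
   gated low subpopulation needs to regain the parental distribution.

Raw sorted-FACS event tables for the original study are not publicly
deposited, so a synthetic-data module generates flow samples and division
lineages with known ground truth; every analysis is exercised end-to-end
against that ground truth.

## Worked example (library)

```python
import numpy as np, mmpsim as M

rng = np.random.default_rng(42)
parental = M.FlowSample("bulk", np.maximum(rng.normal(10, 1, 10_000), 1.0))

params = M.default_division_params(parental, t=1.25, m=0.8)
report = M.regeneration_analysis(parental, 0.05, params, n_reps=50, seed=7)
print("median distance per generation:",
      [round(d, 3) for d in report.per_generation_distance])
print("median divisions to convergence:", report.divisions_to_convergence)
```

prints

```
median distance per generation: [0.137, 0.063, 0.007, 0.037, 0.074, 0.108]
median divisions to convergence: 3.0
```

The bottom-5% gate of a Normal(10, 1) bulk population starts ~14% below the
parental mean; with t = 1.25 and an 0.8 increase probability for
below-average daughters, the relative mean deficit falls within the 5%
tolerance at generation 3 — the sorted low cells regain the parental
distribution within three divisions.

## Worked example (CLI)

```bash
mmpsim synth --preset bimodal --size 10000 --seed 1 -o events.csv
mmpsim fit   --events events.csv --k-max 4 -o fit.json
mmpsim gate  --events events.csv -o gate.json
```

`fit.json` reports the BIC-selected mixture (k = 2, weights 0.152/0.848,
means 2.97/11.98, sds 0.80/1.98 — the generating fixture is weights
0.15/0.85, means 3/12, sds 0.8/2.0), and `gate.json` the bottom/top-5%
thresholds (2.603 and 15.112, 500 events each at N = 10,000). Other
subcommands: `simulate` (per-generation summary and lineage CSVs),
`estimate` (coefficient grid search), `regenerate` (convergence report).
Every JSON report embeds the seed, package version, and a hash of the
resolved configuration; re-running with identical inputs is byte-identical.

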