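# carebandit

Simulation framework for **personalized digital care-program allocation**
in older-adult populations, built around a linear Thompson Sampling
contextual bandit.

Public AI care-call services typically assign programs by fixed rules. This
package asks, by simulation, how much is lost by not personalizing: it
generates synthetic older-adult populations with realistic marginal
structure, defines ground-truth models linking user × program features to
three care outcomes — call success, PHQ-2 depressive symptoms (0–6, lower
better) and self-rated health (SRH, 1–5, higher better) — and compares four
allocation policies over repeated interaction sequences:

| policy | information used |
|---|---|
| systematic (cyclic) | none — fixed rotation |
| single best | population-average effects (an idealized RCT) |
| optimal (oracle) | the true individual-level model (upper bound) |
| **linear Thompson Sampling** | learned online from observed outcomes |

## Model

Each (user, arm) pair is encoded as a context
`x = [1 | user features | arm dummies | user×arm interactions]` (d = 22 by
default: 9 binary features, 24 arms from content × frequency × duration ×
voice, 7 interaction terms). Outcomes follow
`P(success) = σ(βᵀx)` (logistic) or `E[score] = clip(βᵀx)` with
mean-preserving probabilistic rounding (ordinal scales). Thompson Sampling
maintains the Bayesian linear posterior `N(B⁻¹f, v²B⁻¹)` with
`B = λI + Σxxᵀ`, `f = Σrx`, samples one coefficient vector per decision and
plays the best-scoring arm. Regret is measured against the oracle on
noiseless expected rewards, oriented to a common [0, 1] benefit scale.

See `docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

```python
from carebandit import RunConfig, run_experiment, compare_policies

cfg = RunConfig("chs", "call_success", horizon=3000, replications=20,
                master_seed=0)
res = run_experiment(cfg)
print(res.aggregate())
print(compare_policies(res, "cyclic", "lin_ts"))
```

```
        policy      mean        sd
0       cyclic  0.563383  0.008748
1  single_best  0.784150  0.006495
2       oracle  0.860333  0.005950
3       lin_ts  0.825000  0.007129
ComparisonResult(test='chi_square', statistic=9672.157473778912, p_value=0.0,
                 groups=('cyclic', 'lin_ts'))
```

Systematic rotation succeeds on 56% of calls in this survey-based
population; Thompson Sampling reaches 82% — most of the way to the
perfect-knowledge oracle's 86% — having started with no knowledge of the
reward structure, and the difference is highly significant. The
`res.regret_trace` frame holds the average cumulative-regret curves: linear
for the static policies, zero for the oracle, tapering for the bandit.

The same study is available from the shell:

```bash
carebandit simulate --outcome call_success --dataset chs --out runs/chs_call
carebandit report --in runs/chs_call --out report/
```

which writes `summary.csv`, `regret.csv` and a manifest, then a
Table-style CSV, test results and figures.

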