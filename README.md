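# iatkit

Scoring algorithms for the Implicit Association Test (IAT), the
psychometric machinery to evaluate them, and rank-based robust statistics
to compare them — for researchers who study *how* indirect reaction-time
measures should be scored, and for anyone who wants a well-tested,
reproducible IAT scoring pipeline.

## The problem

An IAT session yields latencies and error flags from two critical block
pairings (compatible vs. incompatible category–key assignments). Turning
that record into one score per subject requires four decisions, each with
several defensible options:

| Parameter | Options |
|---|---|
| Extreme-latency treatment | none · drop < 400 ms · clip to [300, 3000] ms · 10% trim · 10% winsorize · 10% inverse trim |
| Error treatment | ignore · exclude · recode to correct M + 2·SD · treat separately · recode to correct M + 600 ms |
| Score formula | D · G (Gaussian ranks) · Worst Performance Rule · mini differences (plain / trimmed / winsorized / inverse-trimmed) |
| Practice/test trials | pooled · scored separately and averaged |

The cross is 420 algorithms (378 after merging provably identical
Ignore/Separate pairs). The flagship formula is the **D score**,

D = (M_incompatible − M_compatible) / SD_pooled,

an individualized effect size; the **G score** replaces latencies by
normal quantiles of their pooled fractional ranks, Φ⁻¹((r − ½)/N), making
it invariant to any monotone distortion of the latency scale. `iatkit`
implements every option, the classic presets D₂/D₅/D₆ and their improved
variants (statistical winsorizing, no practice/test distinction), and the
evaluation chain: split-half and test–retest reliability, convergent and
predictive validity, per-dataset rank scores, and a rank-based robust
inference layer — the Brunner–Dette–Munk ANOVA-type statistic with
fractional degrees of freedom, Tukey-type simultaneous contrasts of
relative effects, the Patel–Hoel 2×2 interaction test, and transitively
reduced "T-graphs" of significant outperformance relations. A seeded
synthetic-data module generates realistic heavy-tailed IAT sessions
(ex-Gaussian latencies, contamination, built-in-penalty or not, criterion
panels, retest sessions) so the whole chain runs without any external
data.

## Worked example

```python
import iatkit as ik

# simulate one built-in-penalty dataset with a retest session
cfg = ik.SynthConfig(n_subjects=60, built_in=True, n_sessions=2, seed=12)
table, panel = ik.generate(cfg)

# score the classic and improved presets
specs = [ik.preset(n) for n in ("D2", "D2_improved", "G_standard")]
matrix = ik.score_table(table, specs)
print(matrix.scores.describe().loc[["mean", "std"]].round(3))

# psychometric indicators and rank scores
indicators = ik.compute_indicators(table, panel, specs, scores=matrix)
ranks = ik.rank_and_compose(indicators)
print(ranks[["reliability", "overall_validity"]].round(2))
```

Output:

```
      P1.2-P2.1-P3.1-P4.2  P1.5-P2.1-P3.1-P4.1  P1.1-P2.1-P3.2-P4.1
mean                0.004                0.091                0.072
std                 0.417                0.718                0.603
property             reliability  overall_validity
algorithm
P1.1-P2.1-P3.2-P4.1          3.0              1.67
P1.2-P2.1-P3.1-P4.2          1.0              2.00
P1.5-P2.1-P3.1-P4.1          2.0              2.33
```

Columns are canonical algorithm ids (`P1.2-P2.1-P3.1-P4.2` is the classic
D₂: fixed-value trimming, errors ignored, D formula, practice/test
distinction). Scores are dimensionless effect sizes, positive when the
subject is slower in the incompatible pairing. The rank table gives each
algorithm's rank score per property (higher = better): here the improved
D₂ (`P1.5-…-P4.1`) has the best overall validity and the plain G the best
reliability, while classic D₂ trails — the qualitative pattern that
motivates the improved presets.

The same pipeline is scriptable from the shell:

```bash
iatkit simulate --seed 42 --n-subjects 50 --out demo
iatkit score --input demo_trials.csv --algorithms unique --out scores.csv
iatkit evaluate --scores scores.csv --trials demo_trials.csv \
       --criteria demo_criteria.csv --out demo
iatkit compare --ranks demo_ranks.csv --parameter 4 --out p4
iatkit enumerate --unique | wc -l   # 378
```

Every output file gets a `.manifest.json` sibling (command, parameters,
input digests, seed, version) sufficient to reproduce it.

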