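# groupitizing

Simulation and analysis of **groupitizing** — the gain in numerosity-
estimation precision when items are spatially clustered — under dual-task
attentional load.

When a briefly flashed array of 5–16 squares is organized into 2–4 small
subgroups, observers estimate its numerosity more precisely than when the
same items are scattered at random. The package implements the complete
analysis used to ask *why*: if the advantage rests on attention-dependent
subitizing of the subgroups plus fast arithmetic on them, then concurrent
tasks that load auditory attention, visuo-spatial attention, or calculation
should erase more of the precision for grouped than for ungrouped arrays.

It is intended for numerical-cognition researchers who want to (a) generate
the stimulus arrays and the full 1296-trial single/dual-task design,
(b) simulate observer cohorts with known parameters to validate analysis
choices, and (c) run the precision pipeline and its statistics on real or
synthetic trial tables.

## The quantities

For each participant, task condition (single task; single task with ignored
distractors, grouped only; auditory, visuo-spatial and arithmetic dual
tasks), spatial arrangement and numerosity *N*, precision is the **Weber
fraction**

    Wf = SD_i / N

(response SD normalized by numerosity — constant over N under scalar
variability). Summary precision is the mean Wf over numerosities 5–8, the
range showing the grouping advantage. The **attentional cost** of a
concurrent task and its grouped-ungrouped **delta** are

    AC  = (Wf_DT − Wf_ST) / (Wf_ST + Wf_DT) × 100        (percent)
    ΔAC = AC_grouped − AC_ungrouped

with the grouped single-task reference taken from the grouped-with-ignored-
distractors condition (matching the dual tasks' visual stimulation).
Positive ΔAC means the concurrent task hurt grouped arrays more. The
statistical layer provides repeated-measures ANOVA (any number of within
factors, Mauchly test, Greenhouse–Geisser correction, η²), Bonferroni
post-hoc and one-sample t tests with Cohen's d, JZS Bayes factors
(log₁₀ BF₁₀, Cauchy prior r = √2/2), BIC-approximated inclusion Bayes
factors for ANOVA terms, PCA with oblimin rotation and Kaiser retention,
and exact noncentral-t power/sample-size computation.

## Worked example

One full study — 28 simulated participants, 1296 trials each, seed 1 —
from the shell:

```sh
groupitizing run --participants 28 --seed 1 --out results/
```

or in Python:

```python
from groupitizing import RunConfig, run_end_to_end, render_report

bundle = run_end_to_end(RunConfig(seed=1, n_participants=28))
print(render_report(bundle))
```

Excerpts of the report this prints:

```
outliers removed (|z| > 3.0 on responses per cell, log-RT per participant x task): 229 (0.63%)

Single-task Weber fractions (grouping advantage, range (5, 16))
             task arrangement    mean      sd
           single     grouped 0.08687 0.02876
           single   ungrouped  0.1054 0.03653
single_distractor     grouped 0.08613 0.02958

Delta attentional cost vs 0 (alpha = 0.017)
condition  mean   sem  df     t         p   alpha  significant      d   lbf
   aud_dt 9.614 2.042  27 4.707 6.685e-05 0.01667         True 0.8896 2.578
   vsp_dt 21.23 1.562  27 13.59 1.363e-13 0.01667         True  2.569 10.72
arithm_dt 20.79  2.08  27 9.996 1.432e-10 0.01667         True  1.889 7.849

PCA of grouped Wfs (visuo-spatial & arithmetic dual tasks): 2 component(s)
with eigenvalue > 1, 83.2% of total variance
```

Reading it: grouped arrays are estimated more precisely than ungrouped ones
under full attention (Wf 0.087 vs 0.105); about 0.6% of trials fall to the
3-SD outlier filter; the attentional cost is larger for grouped than
ungrouped arrays under every concurrent task, and the cost delta ΔAC is
largest for the visuo-spatial and arithmetic tasks (~21 percentage points
each) — the signature of groupitizing drawing on visuo-spatial attention
and calculation. The PCA of grouped dual-task Weber fractions retains two
oblimin-rotated components, arithmetic and visuo-spatial variables loading
on separate factors: the two tasks tap partially independent noise sources
even though both are visually presented.

Other entry points: `groupitizing gen-stimuli` emits stimulus arrays as
JSON records (positions in degrees of visual angle); `groupitizing
simulate` writes a trial-table CSV; `groupitizing analyze --trials
trials.csv --out results/` runs the pipeline on any table matching the
documented schema (a `--column-map` YAML adapts externally deposited
tables); `groupitizing report` prints the report of a finished run.

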