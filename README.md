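# sizeval

**Is the sample size you settled on actually big enough for your two-class
machine-learning study?**

`sizeval` answers that question retrospectively, from the data you already
have, instead of from effect sizes copied out of earlier publications. It
is aimed at biomedical ML studies — patient vs. control classification
from clinical, physiological or diary-style feature tables — where both
under-sampling (overfitting, inflated effects) and over-sampling (wasted
cost) are real risks.

## The method

For a dataset with two classes (sizes $n_1$, $n_2$) and $v$ variables, the
per-variable standardized mean difference is Cohen's d,

$$d_j = \frac{\bar{x}_{1j} - \bar{x}_{2j}}{S_{pooled,j}}, \qquad
S_{pooled,j} = \sqrt{\frac{(n_1-1)\,s_{1j}^2 + (n_2-1)\,s_{2j}^2}{n_1+n_2-2}},$$

with sample SDs throughout. Two aggregates summarise the dataset:

* **average effect size** $\bar{d} = \frac{1}{v}\sum_j |d_j|$, and
* **grand effect size** $d_g = |\mu_{g1}-\mu_{g2}| / S_{pooled,g}$, where
  $\mu_{gc}$ is the mean over variables of the class-$c$ per-variable
  means and the class SDs entering $S_{pooled,g}$ are the means over
  variables of the per-variable SDs.

The two coincide for homogeneous variables and diverge sharply when
variable effects point in opposite directions (they cancel in $d_g$ but
not in $\bar{d}$) — a pattern that by itself can invalidate a naive power
calculation based on a single effect size.

On top of the effect sizes, a learning-curve protocol draws repeated
balanced subsamples at increasing total sizes (16, 32, 64, … by default,
100 repetitions per size) and scores five classifier families — linear
SVM, L2 logistic regression, decision tree, one-hidden-layer neural
network, Gaussian naive Bayes — by stratified ten-fold cross-validation.
A decided sample size $n$ is judged **adequate** when

1. $\max(\bar{d}, d_g) \ge 0.5$ (Cohen's "significant" bound), and
2. the best family's mean CV accuracy at $n$ is $\ge 80\%$, and, where
   larger sizes above that accuracy were evaluated, the relative accuracy
   change to the next one is $< 10\%$.

When a size fails, the accuracy and effect-size *trends* across the
schedule map onto a remediation: collect more samples and better features
(accuracy rises, effect size doesn't), revise the design (neither rises),
or simply add samples (effect size rising but not yet over the bar).

A built-in simulator generates two-class Gaussian feature matrices whose
per-variable population d is controlled exactly, in "good" (d ∈ 0.5–1.4)
and "poor" (d ∈ 0.01–0.2) regimes, plus a data-quality manipulation that
substitutes a chosen fraction of poor variables with good ones.

## Worked example

```python
from sizeval import RunConfig, run_pipeline, render_report

config = RunConfig(
    simulation={"n_per_class": 256, "n_variables": 50, "regime": "good"},
    sizes=[16, 32, 64, 128, 256, 512],
    repetitions=10,
    seed=7,
    output_dir="scratch/demo",
)
print(render_report(run_pipeline(config)))
```

prints

```
sample-size adequacy report
===========================
decided sample size: 512

criterion 1 (effect size >= 0.5): PASS [max(d_average=0.9526, d_grand=0.9507) = 0.9526]
criterion 2 (accuracy >= 80%, change < 10%): PASS [accuracy 0.9980; accuracy level met; stability clause vacuous (no larger qualifying size)]

overall: the decided sample size is ADEQUATE
The decided sample size meets both criteria; additional samples are unlikely
to change the effect sizes or accuracy materially.

mean accuracy by classifier and size:
classifier       DT      LR      NB      NN     SVM
sample_size
16           0.6688  1.0000  0.9625  1.0000  0.9938
32           0.7062  0.9969  0.9938  0.9969  1.0000
64           0.7391  1.0000  0.9984  0.9984  0.9984
128          0.8039  0.9977  0.9969  0.9992  0.9953
256          0.8340  0.9984  0.9984  0.9988  0.9977
512          0.8475  0.9980  0.9980  0.9977  0.9963

effect sizes by size (mean +/- SD across subsamples):
 sample_size  d_average_mean  d_average_sd  d_grand_mean  d_grand_sd
          16          1.0130        0.0828        0.9790      0.0825
          ...
         512          0.9526        0.0000        0.9507      0.0000
```

Both aggregate effect sizes sit near 0.95 (well over the 0.5 bar), the
best family's accuracy is 99.8%, and the report's per-size tables show the
classic learning-curve signature: accuracy and effect-size spread shrink
as the subsample size grows (SD 0.083 at n = 16 down to 0 at the full
n = 512).

The same analysis runs from the shell on your own CSV
(numeric feature columns plus one label column):

```bash
sizeval run --input mystudy.csv --label-column diagnosis \
            --decided-size 128 --seed 7 --out-dir results/mystudy
sizeval report --bundle-dir results/mystudy --plots
```

and the stages are available individually as `sizeval simulate`,
`effect-size`, `evaluate` and `decide`.

## Documentation

`docs/methods.md` describes the statistical model, every default and
threshold with its rationale, what the simulator does and does not
emulate, and the package's numerical conventions.
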