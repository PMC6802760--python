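# visualspan

Analysis pipeline for **visual-span** experiments with the trigram
character-recognition paradigm, built for studies of aging and pattern
complexity in reading (e.g. Chinese character recognition in young vs older
adults).

The visual span is the number of adjacent characters a reader can recognize
reliably in one fixation. In the trigram task, three characters are flashed
briefly at varying horizontal positions around fixation and the observer
reports them; correctness is scored at each character's position. The
pipeline turns trial-level records into:

1. **Span profiles** — percent correct at positions −7…+7 per participant ×
   complexity level (balanced 27 observations/position under the default
   459-trial design);
2. **Span size** — a single Gaussian `A·e^{−(x−μ)²/2σ²}` and a sum of two
   Gaussians are fitted to each profile, the better admissible model is
   selected by an r² rule, and span is the width of the curve at the 80%
   criterion (for a single Gaussian, `2σ√(2 ln(A/80))`); profiles that never
   reach 80% get span 0. Span is also expressed in **bits** by summing the
   information transmitted `I(p) = log₂N + p log₂p + (1−p) log₂((1−p)/(N−1))`
   over positions (0 bits at chance 1/26 ≈ 3.8%, 4.7 bits at 100%);
3. **Group statistics** — 2 (age) × 3 (complexity) mixed ANOVA with optional
   Greenhouse–Geisser correction, Bonferroni-corrected age contrasts per
   complexity level with Cohen's d, left/right span asymmetry, and accuracy
   at fixation by trigram role (a crowding probe);
4. **Reading correlation** — sentence reading speed in characters/minute,
   correlated with span overall and within complexity levels.

A calibrated synthetic generator (`visualspan.synthetic`) simulates whole
cohorts — trial tables and reading records — with known ground truth, so the
pipeline is testable end to end and estimator bias is measurable. See
`docs/methods.md` for the model and calibration details.

## Worked example

```bash
visualspan simulate --seed 42 --out-dir out        # 42 participants x 459 trials
visualspan analyze --trials out/trials.csv --reading out/reading.csv --out-dir out
```

`out/report.txt` from this exact run:

```
Mean span size (characters; SE) and bits by cell:
   older / high   span   2.8 (0.3)   bits  22.6
   older / low    span   7.1 (0.6)   bits  41.3
   older / medium span   6.6 (0.5)   bits  38.8
   young / high   span   5.4 (0.4)   bits  35.5
   young / low    span   7.2 (0.3)   bits  43.3
   young / medium span   6.5 (0.3)   bits  40.0

Mixed ANOVA on span in characters (GG-corrected):
  age_group                F(1.00, 40.00) =    2.71   p = 0.1076   eta_p^2 = 0.06
  complexity               F(1.51, 60.49) =  169.80   p = 6.388e-23   eta_p^2 = 0.81
  age_group*complexity     F(1.51, 60.49) =   38.62   p = 5.593e-10   eta_p^2 = 0.49

Pairwise age contrasts (Bonferroni-corrected):
  young - older @ high     t(40) =   5.52   p_bonf = 6.636e-06   d = 1.70
  young - older @ low      t(40) =   0.11   p_bonf = 1   d = 0.03
  young - older @ medium   t(40) =  -0.11   p_bonf = 1   d = -0.03

Span vs reading speed (Pearson):
  all    r =  0.34   p = 0.02662   n = 42
  high   r =  0.60   p = 2.282e-05   n = 42
  low    r =  0.14   p = 0.3599   n = 42
  medium r =  0.16   p = 0.3239   n = 42
```

Reading the numbers: spans shrink as pattern complexity rises for both
groups, but older adults lose far more at high complexity (2.8 vs 5.4
characters; the age × complexity interaction and the high-complexity
contrast t(40) = 5.52, d = 1.70, carry the effect, while low/medium show no
age difference). The span–speed correlation is positive and strongest at
high complexity. Both patterns are properties of the calibrated generator
that the analysis recovers from raw simulated trials.

The same operations are available as a library:

```python
import visualspan as vs
parts, trials, reading = vs.simulate_experiment(vs.default_config(), seed=42)
result = vs.analyze(trials, reading)      # AnalysisResult
print(result.spans.head())                # per participant x complexity
print(vs.render_report(result))
```

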