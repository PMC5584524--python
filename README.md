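# elicit — hybrid-method expert elicitation for bounded quantities

`elicit` turns structured expert judgements into probability distributions
that can serve as priors in health-technology-assessment (HTA) and other
decision models. It implements the **hybrid method** (also known as *four
complementary intervals*): the expert states a lower plausible limit *L*, a
mode *M* and an upper plausible limit *H* for a bounded quantity, the
intervals [L, M] and [M, H] are each halved, and the expert allocates 100 %
of probability across the four resulting intervals. The answer is encoded
as a piecewise-constant density

> f(x) = pᵢ / wᵢ  for x in bin i,  with edges [L, (L+M)/2, M, (M+H)/2, H],

zero outside [L, H]. The package is aimed at analysts who run elicitation
exercises — facilitated or self-administered at a distance — and need the
whole chain from questionnaire to pooled prior in one tested toolkit:

- **Encoding** — histogram construction, exact moments, modes
  (`elicit.hybrid`).
- **Consistency checking** — the four real-time rules applied to every
  answer: total probability must be 100 % and *L < M < H* within the scale
  (hard errors), while a uniform allocation or limits spanning the whole
  scale only prompt the expert to confirm (warnings) (`elicit.validation`).
- **Beta fitting** — a smooth Beta(α, β) matched to the histogram either by
  moments or by least squares on bin masses,
  minimising Σᵢ (F(eᵢ₊₁) − F(eᵢ) − pᵢ)² (`elicit.fitting`).
- **Pooling and reporting** — linear opinion pooling (weighted arithmetic
  average of densities), panel summaries (mean/min/max of modes, mean
  range H−L, pooled mean and sd), completion rates and arm contrasts
  (`elicit.pooling`).
- **Sessions** — a complete self-administered workflow (consent, training
  with a practice question, demographics, seed and main questions with live
  validation, face-validity confirmation of a rendered histogram, a 0–100
  certainty rating), with per-section timing and JSON persistence
  (`elicit.session`; JSON Schema in `schemas/`).
- **Synthetic experts** — panels of simulated experts whose true beliefs
  are beta distributions with between-expert variation and integer-percent
  answer granularity, so every step is testable against a known truth
  (`elicit.simulate`).

## Worked example

Simulate a small panel, fit and pool it through the model/results surface:

```python
from elicit import ElicitationPanel, SimulationSpec, simulate_panel, unit_quantity

panel = simulate_panel(SimulationSpec(n_experts=8, seed=42))
res = ElicitationPanel(panel, unit_quantity("steatosis_reduction")).fit()
print(res.summary())
```

```
Elicitation panel results
============================================================
Quantity:            steatosis_reduction
Experts:             8
Fitting method:      least_squares
------------------------------------------------------------
Mean of modes:       0.256  (min 0.141, max 0.372)
Mean range (H-L):    0.752
Pooled mean:         0.333
Pooled sd:           0.200
Pooled beta fit:     alpha=1.524, beta=3.047
------------------------------------------------------------
 expert_id     L  mode     H  range  alpha  beta   gof
         1 0.069 0.372 0.826  0.757  2.723 3.896 0.000
         2 0.036 0.265 0.787  0.751  2.094 3.945 0.000
         ...
```

Each row is one expert's normalized answer: their stated limits and mode,
the plausible range H−L, and the Beta(α, β) fitted to their histogram with
its bin-mass discrepancy `gof`. The panel block above it gives the linear
pool of the eight densities: its mean and standard deviation are the
numbers an HTA modeller would carry forward as a prior (here a belief
centred at 0.33 with sd 0.20, smoothed as Beta(1.52, 3.05)).

The same pipeline is available from the shell:

```bash
elicit simulate --seed 42 --out panel.csv
elicit validate panel.csv
elicit fit panel.csv --out fits.csv
elicit pool panel.csv --out pooled.csv
elicit report panel.csv --out report.json
elicit elicit --out session.json        # interactive session
```

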