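# decisio

Preference-sensitive decision support built on value-based compensatory
multi-criteria decision analysis (MCDA), with GRADE certainty-of-evidence
adjustment and preference-sensitivity analysis. It is written for people
building or studying patient decision aids: tools that integrate the
evidence on how treatment options perform with the importance an
individual attaches to each outcome, and return a personal,
preference-sensitive opinion rather than a recommendation.

## The model

A decision model has options *o* rated against criteria *k* on a 0–1
scale (`r_ok`, 1 = best). A person supplies nonnegative importance
weights, normalized to `w_k` with `Σ_k w_k = 1`. Each option's
expected-value score is

```
S_o = Σ_k w_k · r_ok
```

Criteria whose ratings rest on evidence carry a GRADE certainty level
(very low / low / moderate / high) mapped to a multiplier `c_k`
(defaults 0.1 / 0.4 / 0.7 / 1.0). The certainty-adjusted score is, in the
default multiplicative mode,

```
S'_o = Σ_k w_k · c_k · r_ok
```

(an alternative `shrink_to_neutral` mode pulls uncertain ratings toward
0.5 instead). Both scores are always reported side by side so the effect
of the adjustment is visible. Evidence-sourced ratings are *locked*
against editing; the person's own practical criteria are not.

Sensitivity analysis answers "how preference-dependent is this result?"
three ways: one-way flip thresholds (the weight on a criterion at which
the preferred option changes, in closed form from the linearity of `S_o`
in the weights), Dirichlet simulation of heterogeneous informed
preferences with per-option preference shares, and a configurable
classification of those shares into `strong_for` / `weak_for` /
`equipoise`.

## The bundled worked example

The package ships a two-option, ten-criterion model of the choice between
transfemoral TAVI (transcatheter aortic valve implantation) and SAVR
(surgical aortic valve replacement) for symptomatic severe aortic
stenosis, constructed from pooled randomized-trial effect differences:
TAVI reduces mortality (~3 percentage points), stroke (~2), acute kidney
injury (~5), serious bleeding (~24), new-onset atrial fibrillation (~18)
and admission length (~3 days), but increases heart-failure symptoms
(~6 points), permanent pacemaker insertion (~15) and short-term valve
reintervention (~1). Seven of these are locked evidence criteria; three
user-rated practical considerations complete the ten.

## Worked example

```python
import decisio as d

model = d.build_model("65_to_75")            # bundled TAVI/SAVR model
weights = d.elicit_weights(model, {c: 100 for c in model.criterion_ids})
scores = d.certainty_adjusted_scores(model, weights)
print(scores.as_dict())                      # unadjusted S_o
print(scores.as_dict(adjusted=True))         # certainty-adjusted S'_o
```

prints

```
{'TAVI': 0.5125, 'SAVR': 0.5}
{'TAVI': 0.40374999999999994, 'SAVR': 0.3949999999999999}
```

Under equal weights TAVI edges ahead (0.5125 vs 0.5000): its large
advantages on bleeding and atrial fibrillation outweigh its disadvantages
on pacemaker insertion and heart-failure symptoms. Certainty adjustment
(all evidence criteria moderate, multiplier 0.7) shrinks both scores but
preserves the ordering. Neither option dominates — each is better on some
criteria — so the result is genuinely preference-sensitive: flip
thresholds and simulated preference shares quantify by how much, e.g.

```python
t = d.one_way_flip_threshold(model, weights, "pacemaker")
print(round(t.threshold, 3), t.direction)    # 0.229 SAVR
sample = d.sample_weight_vectors(10_000, 10, 1.0, seed=7)
print(d.preference_share(model, sample))     # {'TAVI': 0.7938, 'SAVR': 0.2062}
```

— raise the pacemaker criterion's weight to 0.229 of the total and the
opinion flips to SAVR; under uniformly random informed preferences about
79% of simulated patients score TAVI higher, which the default
thresholds classify as `weak_for_TAVI`.

The same workflow is scriptable from the shell:

```
decisio fixture --age 65-75 --out model.yaml
decisio score --model model.yaml --weights weights.csv
decisio sensitivity --model model.yaml --weights weights.csv
decisio simulate --model model.yaml --n 10000 --seed 7
```

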