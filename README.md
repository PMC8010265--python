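# cloverdry

Dry-down phenotyping of white clover (*Trifolium repens* L.) cultivars:
from daily pot weights to per-cultivar drought-response thresholds and
their trend across a century of breeding.

## The problem

White clover is the key pastoral legume of temperate grazing systems, and
drought is the main limit on its performance. Comparing cultivars' drought
behaviour fairly requires exposing them to the *same* soil water deficit —
which glasshouse dry-down trials achieve by weighing sealed pots daily while
watering is withheld. This package implements the full analysis for such
trials, for a panel of 80 cultivars released between 1920 and 2010:

* **NTR**, the normalized transpiration rate: daily water loss of a drought
  pot relative to its well-watered controls, normalized to the mean of days
  3 and 5 so NTR ≈ 1 under ample water;
* **FTSW**, the fraction of transpirable soil water:
  `(w_d − w_last)/(w_first − w_last)`, 1 at container capacity, 0 at
  exhaustion;
* **FTSWc**, the critical threshold: the breakpoint of the plateau
  regression `NTR = plateau · min(1, FTSW/c)`, read as the onset of
  stomatal closure (a logistic description
  `NTR = 1/(1 + A·e^{B·FTSW})` with coefficient CIs is fitted alongside);
* the **decade trend** of FTSWc, an OLS linear spline with a knot at 1965
  (`a + b·Time + c·max(0, Time − knot)`, Time in decades), whose slopes `b`
  and `b + c` quantify the rise to the mid-1960s and the fall after;
* a **synthetic dry-down simulator** (drought, rewatered-control, and bare
  evaporation pots, with known ground-truth thresholds) so the whole chain
  is testable end to end by parameter recovery.

It is aimed at forage breeders and plant ecophysiologists running pot
dry-downs, and at anyone who wants a tested, reusable reference
implementation of the NTR/FTSW/plateau-regression workflow.

## Worked example

Simulate a two-cultivar trial with known thresholds, run the pipeline, and
estimate each threshold with a bootstrap interval:

```python
import cloverdry as cd

profiles = [
    cd.CultivarProfile(name="early-closer", ftswc_true=0.45),
    cd.CultivarProfile(name="late-closer", ftswc_true=0.15),
]
design = cd.ExperimentDesign(n_days=19, seed=7)   # default weighing noise
dataset = cd.simulate_experiment(profiles, design)
points = cd.build_response_points(dataset)

for p in profiles:
    fit = cd.fit_plateau(points.for_cultivar(p.name), seed=7)
    print(f"{p.name}: FTSWc = {fit.ftswc:.3f} "
          f"(95% CI {fit.ci95_ftswc[0]:.3f}-{fit.ci95_ftswc[1]:.3f}, "
          f"true {p.ftswc_true:.2f}, plateau {fit.plateau:.2f}, n = {fit.n_points})")
```

prints

```
early-closer: FTSWc = 0.469 (95% CI 0.435-0.515, true 0.45, plateau 1.03, n = 34)
late-closer: FTSWc = 0.164 (95% CI 0.122-0.200, true 0.15, plateau 1.01, n = 34)
```

The early closer shuts its stomata while almost half the transpirable water
remains (a water-saver, suited to long droughts); the late closer keeps
transpiring into much drier soil (suited to short droughts). Both intervals
cover the generating truth.

The same machinery drives a small CLI. Summaries of the packaged
80-cultivar reference panel:

```
$ cloverdry summarize
FTSWc (n=59): mean 0.29, min 0.12 (AberHerald), max 0.52 (Tribute)
dry weight, drought: mean 16.27 g, range 10.65-23.33 g
dry weight, irrigated: mean 22.70 g, range 11.23-29.25 g
bottom-5 FTSWc: AberHerald (0.12), Aquiles (0.13), Chieftain (0.17), Goliath (0.17), Kent White (0.17)
top-5 FTSWc: Tribute (0.52), Sacramento (0.49), Pitau (0.48), Bounty (0.47), Kotare (0.42)

$ cloverdry trend
pre-knot slope b = +0.0292/decade (p=0.009); post-knot slope b+c = -0.0251/decade (p=0.018); r2 = 0.67
```

The threshold climbed significantly up to the mid-1960s and has declined
significantly since — the rise-then-fall signature of a shift in breeding
priorities around 1965. `cloverdry simulate` and `cloverdry analyze` write
and process weighing CSVs (`experiment_id,pot_id,cultivar,treatment,
replicate,day,weight_g`); see `docs/methods.md` for every convention and
switch.

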