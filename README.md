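# urisat

Urinary ion speciation and relative supersaturation (RSS) for calcium
oxalate and struvite, with an open, editable coefficient registry and the
four-part statistical suite used to compare two RSS programs.

## Who this is for

Veterinary and clinical researchers who quantify urinary stone risk from
24-h urine chemistry panels. Urolithiasis is common in dogs and cats, and
struvite (MgNH₄PO₄·6H₂O) and calcium oxalate (CaC₂O₄·H₂O, whewellite)
account for most stones; diets are routinely evaluated by their effect on
urine RSS. Historical RSS calculators are closed binaries with undisclosed
coefficient tables, which makes results from different programs
incomparable. `urisat` makes every coefficient visible, sourced, and
swappable, and ships the statistics needed to characterise how two
programs' outputs relate.

## The model

For a urine sample with measured pH and total concentrations
T_j (mmol/L) of the major ions (Ca, Mg, Na, K, NH₄, Cl, SO₄, PO₄, oxalate,
citrate; optionally urate, pyrophosphate, total CO₂), the solver finds the
free concentrations [j] satisfying, for each component j,

    T_j = [j] + Σ_k n_kj [C_k],      [C_k] = β_k · Π_j a_j^{n_kj} / γ_k

where a_j = γ_j[j] is the molar-scale activity, β_k the cumulative
stability constant of soluble complex C_k, and the proton activity is
clamped at a_H = 10^(−pH) (pH is measured, so no proton balance is
written; OH⁻ enters via the water ion product). Activity coefficients
follow the Davies equation,

    log₁₀ γ = −A z² ( √I/(1+√I) − 0.3 I ),   I = ½ Σ c z²,

with A = 0.5221 at 38 °C, iterated to self-consistency with the ionic
strength. For each salt the ion activity product IAP = Π a_ion^ν is
compared with the thermodynamic solubility product:

    RSS = IAP / Ksp

RSS = 1 is saturation; > 1 supersaturated (crystals can grow); < 1
undersaturated. RSS is a thermodynamic risk index, not a verdict: a
supersaturated urine may or may not form stones.

Two programs that differ only in a salt's Ksp produce RSS series related by
an exact constant factor: regression slope = Ksp ratio, r² = 1, while Lin's
concordance correlation coefficient (which penalises bias) is depressed.
The `compare` module implements the paired t-test, Lin's CCC, OLS of
Control on New with a 95 % slope CI and r², and Bland–Altman analysis with
±2 SD and ±3 SD limits to make such relationships measurable.

## Worked example

```python
from urisat import compute_rss, load_constants
from urisat.io import read_panels

constants = load_constants("default")
panels = read_panels("examples/data/demo_panels.csv")
for p in panels:
    r = compute_rss(p, constants)
    print(p.sample_id, p.ph, round(r.rss("caox"), 3), round(r.rss("struvite"), 4))
```

prints

```
dog-A 6.45 6.985 0.2366
dog-B 7.2 13.383 4.8003
cat-A 6.1 4.633 0.4208
```

Both dogs are supersaturated for calcium oxalate (RSS ≫ 1). Only dog-B, at
pH 7.20, is supersaturated for struvite: phosphate deprotonates as pH
rises, raising the Mg·NH₄·PO₄ activity product roughly tenfold per pH
unit. The `examples/` directory has one short script per capability:
computing RSS, the program-agreement suite, cohort simulation, and editing
the constants registry.

The same pipeline is available from the shell:

```sh
urisat simulate --species canine --n 100 --seed 7 --out panels.csv
urisat compute --panels panels.csv --out rss.csv
urisat compare --new rss.csv --control rss_other.csv --column rss_struvite \
       --out-json agreement.json --plot-prefix fig
urisat constants validate my_constants.yaml
```

## Scope

The solver certifies calcium oxalate and struvite; the registry format
accepts further salts (brushite, apatite, uric acid) as extension points.
Single unit system (mmol/L). No temperature corrections (constants are
taken at 38 °C), no precipitation mass transfer, no nucleation kinetics.
See `docs/methods.md` for the full model description, parameter defaults,
and limitations.
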