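# metalrisk

Deterministic dietary risk assessment of metal residues in poultry
edibles: estimated daily intake (EDI), target hazard quotient (THQ),
hazard index (HI), target cancer risk (TR), and maximum-residue-limit
screening, for food-safety and public-health analysts.

The package reproduces, at desk scale, a market-basket study of 12 metals
(Al, Cd, Pb, Ba, Bi, Co, Ni, Cr, Fe, Cu, Zn, Se) in chest muscle, thigh
muscle and liver of six retail poultry brands (20 birds per brand, 360
birds). For a group with mean residue concentration C (µg/g wet weight):

```
EDI = C · FIR / BW                    [µg/kg BW/day]
THQ = EDI · 10⁻³ / RfD                HI = Σ THQ
TR  = EDI · 10⁻⁶ · CPSo               (published-table convention)
```

with FIR the ingestion rate (39.53 g/day muscle, 0.1 g/day liver),
BW = 70 kg, RfD the oral reference dose and CPSo the oral carcinogenic
potency slope. THQ or HI ≥ 1 flags potential non-cancer risk; TR in
10⁻⁶–10⁻⁴ is the usual cancer-risk concern band. Limit screening flags a
group whose mean strictly exceeds an authority's limit for its tissue
class and reports sample-weighted exceedance percentages. See
`docs/methods.md` for conventions and the `published` vs `stated`
formula modes.

## Worked example

```python
>>> import metalrisk as mr
>>> table = mr.load_study_means()          # packaged 216-group fixture
>>> reg = mr.load_registry("defaults")     # RfD, CPSo, limits, exposure
>>> frames = mr.risk_frames(mr.assess(table, reg, mode="published"))
>>> frames["tr"].query("brand=='1' and tissue=='chest' and metal=='Ni'")
  brand tissue metal            tr
3     1  chest    Ni  2.188833e-07
>>> rep = mr.exceedance_report(table, reg, "FAO/WHO", "Pb")
>>> rep.flagged_sample_count, rep.total_sample_count, rep.percent_display
(340, 360, 94)
```

The nickel lifetime cancer risk for chest muscle of brand 1 is
2.19 × 10⁻⁷ — below the 10⁻⁶ concern threshold — and lead exceeds the
FAO/WHO limits in 340 of 360 samples (94 %), every group except the
liver of brand 1.

The same stages are scripted as a narrative analysis:

```
python analysis/01_screen_limits.py      # exceedance percentages
python analysis/02_risk_assessment.py    # EDI/THQ/HI/TR + audit vs print
python analysis/03_simulate_samples.py   # synthetic birds, moment recovery
python analysis/04_tissue_contrasts.py   # ANOVA + Tukey letters
```

each writing its tables under `results/`, or driven from the shell via
the `metalrisk` CLI (`summarize`, `screen`, `risk`, `simulate`,
`reproduce-study`).

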