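# Default toxicological reference registry for the poultry metal-residue
# risk pipeline.  Values are stored as decimal strings exactly as published.
#
# rfd:  oral reference dose, mg per kg body weight per day
# cpso: oral carcinogenic potency slope, per (mg/kg body weight/day)
# limits: maximum permissible residue, ug/g wet weight (= mg/kg)
# qc_recovery: spike-recovery percentages of the analytical run (metadata)

[[metals]]
symbol = "Al"
name = "aluminium"
iarc_group = "3"

[[metals]]
symbol = "Cd"
name = "cadmium"
iarc_group = "1"

[[metals]]
symbol = "Pb"
name = "lead"
iarc_group = "2B"

[[metals]]
symbol = "Ba"
name = "barium"
iarc_group = "3"

[[metals]]
symbol = "Bi"
name = "bismuth"
iarc_group = "3"

[[metals]]
symbol = "Co"
name = "cobalt"
iarc_group = "2A"

[[metals]]
symbol = "Ni"
name = "nickel"
iarc_group = "1"

[[metals]]
symbol = "Cr"
name = "chromium"
iarc_group = "1"

[[metals]]
symbol = "Fe"
name = "iron"
iarc_group = "3"

[[metals]]
symbol = "Cu"
name = "copper"
iarc_group = "3"

[[metals]]
symbol = "Zn"
name = "zinc"
iarc_group = "3"

[[metals]]
symbol = "Se"
name = "selenium"
iarc_group = "3"

[rfd]
Al = 0.0004
Cd = 0.001
Pb = 0.004
Ba = 0.07
Bi = 0.00029
Co = 0.0003
Ni = 0.02
Cr = 0.003
Fe = 0.7
Cu = 0.005
Zn = 0.3
Se = 0.005

[cpso]
Cd = 0.38
Pb = 0.0085
Co = 0.7
Ni = 1.7
Cr = 0.5

# FAO/WHO and EU poultry limits: Cd 0.05 (meat) / 0.5 (liver),
# Pb 0.1 (meat) / 0.5 (liver).  EOS national guidelines: Cd 0.5, Pb 2,
# Fe 15 (meat) / 20 (offal), Cu 15, Ni 10.  FNB: Ni 4.  The "international"
# proposals for Cr 1.0, Zn 20, Se 0.5 apply to muscle and offal alike.
[[limits]]
authority = "FAO/WHO"
metal = "Cd"
tissue_class = "muscle"
limit = 0.05

[[limits]]
authority = "FAO/WHO"
metal = "Cd"
tissue_class = "offal"
limit = 0.5

[[limits]]
authority = "FAO/WHO"
metal = "Pb"
tissue_class = "muscle"
limit = 0.1

[[limits]]
authority = "FAO/WHO"
metal = "Pb"
tissue_class = "offal"
limit = 0.5

[[limits]]
authority = "EU"
metal = "Cd"
tissue_class = "muscle"
limit = 0.05

[[limits]]
authority = "EU"
metal = "Cd"
tissue_class = "offal"
limit = 0.5

[[limits]]
authority = "EU"
metal = "Pb"
tissue_class = "muscle"
limit = 0.1

[[limits]]
authority = "EU"
metal = "Pb"
tissue_class = "offal"
limit = 0.5

[[limits]]
authority = "EOS"
metal = "Cd"
tissue_class = "muscle"
limit = 0.5

[[limits]]
authority = "EOS"
metal = "Cd"
tissue_class = "offal"
limit = 0.5

[[limits]]
authority = "EOS"
metal = "Pb"
tissue_class = "muscle"
limit = 2.0

[[limits]]
authority = "EOS"
metal = "Pb"
tissue_class = "offal"
limit = 2.0

[[limits]]
authority = "EOS"
metal = "Fe"
tissue_class = "muscle"
limit = 15.0

[[limits]]
authority = "EOS"
metal = "Fe"
tissue_class = "offal"
limit = 20.0

[[limits]]
authority = "EOS"
metal = "Cu"
tissue_class = "muscle"
limit = 15.0

[[limits]]
authority = "EOS"
metal = "Cu"
tissue_class = "offal"
limit = 15.0

[[limits]]
authority = "EOS"
metal = "Ni"
tissue_class = "muscle"
limit = 10.0

[[limits]]
authority = "EOS"
metal = "Ni"
tissue_class = "offal"
limit = 10.0

[[limits]]
authority = "FNB"
metal = "Ni"
tissue_class = "muscle"
limit = 4.0

[[limits]]
authority = "FNB"
metal = "Ni"
tissue_class = "offal"
limit = 4.0

[[limits]]
authority = "INTL"
metal = "Cr"
tissue_class = "muscle"
limit = 1.0

[[limits]]
authority = "INTL"
metal = "Cr"
tissue_class = "offal"
limit = 1.0

[[limits]]
authority = "INTL"
metal = "Zn"
tissue_class = "muscle"
limit = 20.0

[[limits]]
authority = "INTL"
metal = "Zn"
tissue_class = "offal"
limit = 20.0

[[limits]]
authority = "INTL"
metal = "Se"
tissue_class = "muscle"
limit = 0.5

[[limits]]
authority = "INTL"
metal = "Se"
tissue_class = "offal"
limit = 0.5

[exposure]
fir_muscle = 39.53
fir_liver = 0.1
bw = 70.0
ed_noncancer = 30.0
ed_cancer = 70.0
ef = 365.0
at_years = 70.0

[qc_recovery]
Al = 97.3
Cd = 99.6
Pb = 93.6
Ba = 105.3
Bi = 103.16
Co = 105.6
Ni = 92.1
Cr = 104.9
Fe = 104.5
Cu = 99.5
Zn = 97.6
Se = 100.46

[guidelines]
# recommended dietary allowance used in the intake report, mg/day
Al_rda_mg_day = 60.0
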