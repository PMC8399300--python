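# masm — membrane activated sludge model

`masm` is a simulator for activated-sludge COD removal in plants where the
clarifier is replaced by a membrane module. It is written for environmental
process engineers and modellers who want to see, mechanistically, why a
membrane bioreactor produces a better effluent than the same biology behind a
gravity settler — and by how much, as a function of sludge age and hydraulic
retention time.

## The model

Classical activated-sludge models (the ASM family) split COD at a single
450 nm threshold: everything "soluble" escapes with the effluent if it is not
degraded, everything particulate is retained with the sludge. A membrane,
however, separates at its *effective filtration size* — about 8 nm once the
cake layer is accounted for, far below the nominal pore size. Consequently a
large part of the "soluble" COD is physically captured in the reactor:

* soluble hydrolysable COD `S_HT1` splits into a membrane-passing pool `S_H`
  and a captured pool `S_HC` (≈78% of the pool in denim-processing textile
  wastewater, ≈76% in domestic sewage);
* soluble inert COD `S_IT1` splits likewise into `S_I` and `S_IC`.

The kinetic core is a six-process, twelve-component Petersen (Gujer) matrix:
Monod growth of heterotrophs `X_H` on readily biodegradable COD `S_S`,

```
r_growth = μ̂_H · S_S/(K_S + S_S) · X_H,
```

surface-saturation hydrolysis of each hydrolysable pool `C`,

```
r_hyd = k_h · (C/X_H)/(K_h + C/X_H) · X_H,
```

and endogenous decay `b_H·X_H` that releases soluble/particulate residual
products (`f_S`, `f_X`) and consumes oxygen for the rest. Settleable
biodegradable COD `X_SS` hydrolyses in two steps, first into the captured
soluble pool `S_HC` and then to `S_S`. Every process row conserves COD
exactly (oxygen counted as negative COD), and the package audits this
continuity as well as the whole-plant COD balance of every run.

Captured pools obey sludge-age-controlled balances
(`Q·S_HC1 − V·S_HC/θ_X − V·r_hyd = 0` in the single-tank limit), while the
passing pool `S_H` is governed by the hydraulic retention time — which is the
mechanistic reason membrane plants can be run at a fraction of the footprint.

The gravity-settled reference (`asm1_mod`, ASM1 modified for endogenous
decay) uses the same component vector with the captured pools lumped away and
one-step hydrolysis of particulates.

The plant is the flowsheet used for the published evaluations: three CSTRs in
series, an ideal point separator (8 nm membrane or 450 nm settler), sludge
return to tank 1, and mixed-liquor wastage from the last tank enforcing the
sludge age (`Q_w = V/θ_X`). Steady states are found by stiff (BDF) time
integration followed by Newton polishing.

## Worked example

Conventional-range membrane plant (sludge age 6 d, HRT 6.5 h) on the bundled
textile characterisation:

```python
from masm import TEXTILE, KineticParams, steady_state_solve, to_influent_state
from masm.scenarios import plant_config, removal_percent, effluent_breakdown

cfg = plant_config("masm", theta_X_d=6.0, theta_H_h=6.5)
res = steady_state_solve(cfg, to_influent_state(TEXTILE, "masm"), KineticParams())
print(f"S_HE  = {res.S_HE:.1f} mg/L")
print(f"S_TE  = {res.S_TE:.1f} mg/L")
print(f"MLSS  = {res.mlss:.0f} mg/L")
print(f"removal = {removal_percent(res.S_HE, TEXTILE, 'masm')} %")
parts, s_te = effluent_breakdown(res)
print({k: round(v, 1) for k, v in parts.items()})
```

prints

```
S_HE  = 8.1 mg/L
S_TE  = 159.5 mg/L
MLSS  = 9206 mg/L
removal = 92 %
{'S_I': 135.0, 'S_S': 0.8, 'S_H': 8.1, 'S_P': 15.5}
```

Of the 1340 mg/L influent COD, only ~160 mg/L of soluble COD leaves: the
influent passing inert (135), residual microbial products (15.5), and a small
hydrolysable remainder (8.1, i.e. 92% of the membrane-bypassing pool
removed). The 90 mg/L of captured inert COD that a 450 nm model would send to
the effluent is retained and wasted with the sludge — run the same
configuration with `plant_config("asm1_mod", theta_X_d=6.0, theta_H_h=14.4)`
and the effluent plateau rises to ≈247 mg/L.

The same sweeps are available from the shell:

```sh
masm table-footprint --profile textile -o footprint.csv
masm table-matched   --profile textile -o matched.csv
masm simulate -c run.yaml
masm psd effective-size --curve psd.csv --permeate 54
```

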