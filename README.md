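# adrgame

Evolutionary game analysis of product-quality regulation for COVID-19
antigen detection reagents (ADRs). The package is for policy modellers and
students of regulatory compliance games: it implements a tripartite
evolutionary game between ADR **manufacturers** (produce low- or
high-quality reagents), third-party **inspection agencies** (accept or
refuse bribes) and **regulatory authorities** (strict or lax supervision),
and analyses where the population dynamics settle.

## The model

Fifteen nonnegative parameters (abstract monetary units) describe the
incentives: sales revenue `Ee`, production costs `Ch > Cl`, the bribe `K`,
speculative (concealment) costs `Ve`, `Vt`, fines `Pe`, `Pt`, subsidies
`Se`, `St`, agency income `Et`, the regulator's social benefit `Eg`,
regulation cost `Cr`, remediation cost `Gg` and credibility loss `Pg`.
Two standing constraints define the modelled region: `Ee > Ch > Cl` and
`Ch > Cl + K + Ve + Pe + Se`.

With `x`, `y`, `z` the population shares choosing low quality, bribe
acceptance and strict supervision, replicator dynamics give

```
dx/dt = x(1-x)(U11 - U12)   U11-U12 = yEe - zPe - Cl - Ve - zSe - Ee + Ch - yzK
dy/dt = y(1-y)(U21 - U22)   U21-U22 = K - Vt - z(K + St + Pt) + xzK
dz/dt = z(1-z)(U31 - U32)   U31-U32 = xPe + yPt - Cr + ySt + xSe + xyPg
```

where `Uij` are conditional expected payoffs against the opponents'
mixtures. The eight pure-strategy corners `E1=(0,0,0) ... E8=(1,1,1)` are
equilibria; a corner is evolutionarily stable when all three eigenvalues
of the (diagonal-at-corners) Jacobian are negative. Under the standing
constraints only three corners can ever be stable:

| Corner | Interpretation | Stability conditions |
|---|---|---|
| E1 (0,0,0) | high quality, honest agencies, lax supervision | `K - Vt < 0` |
| E5 (1,1,0) | low quality, bribery, still-lax supervision | `Vt - K < 0`, `Pe - Cr + Pg + Pt + Se + St < 0` |
| E8 (1,1,1) | low quality, bribery, strict supervision | `Vt - K + St + Pt < 0`, `Cr - Pe - Pg - Pt - Se - St < 0` |

## Worked example

```python
>>> import adrgame as ag
>>> A = ag.printed_sets()["A"].params          # Ee=500, Ch=180, ..., K=30
>>> ag.replicator_field((0.5, 0.5, 0.5), A)
FieldVector(Fx=-35.0, Fy=-10.625, Fz=-19.375)
>>> ag.stable_corners(A)
['E1']
>>> traj = ag.integrate((0.5, 0.5, 0.5), A)
>>> traj.limit
(0.0, 1.0000000000100003e-11, 0.0)
```

At the cube centre all three frequencies are falling (`Fx`, `Fy`, `Fz`
negative): with the bribe `K=30` below the agency's concealment cost
`Vt=40`, bribery does not pay, quality production takes over, and the
regulator can afford to relax — the dynamics converge to the welfare-
maximising corner `(0,0,0)`. Raising the bribe to `K=100` flips the
system to `(1,1,0)` (bribery under lax supervision), and additionally
raising the credibility loss to `Pg=100` forces strict supervision,
`(1,1,1)`.

The same analyses run from the shell:

```sh
adrgame scenario show A > a.json
adrgame stability --config a.json      # {"stable": ["E1"]}
adrgame simulate  --config a.json --out traj.csv
adrgame sweep     --config a.json --param K --values 30,50,100 --out sweeps/
```

and the numbered drivers under `analysis/` reproduce the headline
stability reports, equilibrium simulations and sensitivity sweeps into
`results/`.

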