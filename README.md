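# dyrknet

Logic-based ODE modeling of DYRK1A-mediated cardiomyocyte cell-cycle
regulation.

Adult cardiomyocytes are quiescent: the kinase DYRK1A phosphorylates
LIN52 (S28) to nucleate the repressive DREAM complex and destabilizes
cyclin D, keeping RB-1 active, the activator E2Fs (E2F1/2/3) silenced and
the DNA-replication program off. Inhibiting DYRK1A releases this brake
and re-opens cell-cycle entry — a candidate route to heart regeneration
after myocardial infarction. `dyrknet` packages a curated
DYRK1A/DREAM/RB/E2F network as a normalized-Hill logic-ODE model together
with the in-silico protocols used to interrogate it: literature-direction
validation, graded-knockdown concentration response with EC50/IC50
extraction, single-node knockout screens, and low/medium/high
inhibitor-dose simulations. It is aimed at systems-biology and
cardiac-regeneration researchers who want a reproducible, diffable,
scriptable version of this class of model.

## The model

Each species *i* (molecule, complex, or process) carries an activity
*Y_i ∈ [0, Y_max,i]* evolving as

    dY_i/dt = (Y_max,i · g_i(Y) − Y_i) / τ_i

where the gate input `g_i` OR-combines (a + b − ab) the fluxes of all
reaction rules producing species *i*. A rule's flux is its weight *w*
times the product (AND) of one normalized-Hill term per regulator,

    f(x) = B·xⁿ / (Kⁿ + xⁿ),   B = (EC50ⁿ − 1)/(2·EC50ⁿ − 1),   K = (B − 1)^(1/n)

the unique Hill sigmoid with f(0) = 0, f(EC50) = ½, f(1) = 1; inhibitors
contribute 1 − f(x). Defaults are w = 1, n = 1.4, EC50 = 0.5, Y_init = 0,
Y_max = 1, τ = 1. Knockdown of fraction k scales a node's Y_max by
(1 − k); overexpression sets Y_max = 10 (inputs) or clamps Y_init = 10
with τ = 10⁹ (other nodes). Steady state is declared when every node
changes by less than 0.05% over one time unit.

Models live in a plain two-section TSV (see
`src/dyrknet/data/dyrk1a_cellcycle.tsv`) with rules written as
`!DYRK1A => CycD` — swap that file to swap the network.

## Worked example

```python
import dyrknet as dn

model = dn.build_dyrk1a_model()
baseline = dn.run_to_steady_state(model)
print(baseline.state.round(4).to_dict())
```

```
{'DYRK1A': 0.9, 'BMyb': 0.1, 'CDK2': 0.8, 'pLIN52': 0.9116,
 'DREAM': 0.8171, 'CycD': 0.0884, 'CycE': 0.1977, 'CycE_CDK2': 0.1299,
 'RB1': 0.8604, 'E2F1': 0.0208, 'E2F2': 0.0208, 'E2F3': 0.0208,
 'DNA_replication': 0.0908}
```

With DYRK1A active, the repressors dominate (DREAM 0.82, RB-1 0.86) and
the cycle genes idle low (DNA replication 0.09). Knocking DYRK1A out and
re-running from this operating point flips the switch:

```python
ko = dn.run_to_steady_state(dn.apply_knockdown(model, "DYRK1A", 1.0),
                            y0=baseline.state.to_numpy())
print(round(ko.state["DNA_replication"], 3))   # 1.0  (was 0.091)
print(round(ko.state["CycD"], 3))              # 1.0  (was 0.088)
```

The concentration response (1% knockdown increments) shows downstream
nodes switching well before the upstream signal fades — partial DYRK1A
inhibition suffices for cycle entry:

```python
curve = dn.concentration_response(model, target="DYRK1A", step=0.01)
print({k: round(v, 3) for k, v in curve.half_max.items()
       if k in ("DNA_replication", "CycD", "pLIN52")})
# {'pLIN52': 0.488, 'CycD': 0.488, 'DNA_replication': 0.179}
```

The same analyses are available from a shell:

```
dyrknet steady                      # baseline steady state (JSON)
dyrknet perturb --ko DYRK1A:1.0     # knockout steady state
dyrknet dose-response --out curve.csv
dyrknet screen --context DYRK1A:1.0 --out screen.csv
dyrknet dose --doses 0.15,0.30,0.45 --out doses.csv
dyrknet validate --out report.json  # packaged cardiomyocyte suite
dyrknet synth --kind cascade --depth 3 --seed 7
```

The packaged five-experiment cardiomyocyte validation suite scores 100%
(`report.json` → `"context_accuracy": {"cardiomyocyte": 100}`).

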