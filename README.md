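# plasmidkinetics

Kinetics of radiation-induced plasmid DNA damage: fit topology-conversion
rates to gel band-percentage data and convert between external-beam dose
and radionuclide incubation time producing equal modeled damage.

## The problem

Cell-free plasmid assays measure DNA damage by topology.  Intact plasmid is
supercoiled (S); a single-strand break relaxes it to the open-circular form
(R); a double-strand break linearises it (L).  The three forms separate on
an agarose gel, so densitometry of one lane yields the percentage of DNA in
each state.  Exposing plasmid to an external gamma source (dose axis, Gy)
or co-incubating it with an Auger-electron-emitting radionuclide such as
⁶⁷Ga or ¹¹¹In (time axis, h at a given activity) and modelling the
band percentages with the two-step irreversible scheme

```
S --k_sr--> R --k_rl--> L
S(x) = S0 e^(-k_sr x),   R(x) = S0 k_sr/(k_rl - k_sr) (e^(-k_sr x) - e^(-k_rl x)),   L = S0 - S - R
```

turns the gels into conversion-rate estimates `k_sr`, `k_rl` (Gy⁻¹ or h⁻¹,
± standard error).  Equating the modeled supercoiled fraction across the
two exposure axes then gives a dose–time equivalence with delta-method
uncertainties:

```
D = (k_sr,t / k_sr,D) · t,     se(D) = D √((se_t/k_t)² + (se_D/k_D)²)
```

The package is aimed at radiation-biology groups running plasmid nicking
assays: it provides the closed-form kinetics (with ODE cross-check), a
statsmodels-style model/results pair for global weighted fitting, the
equivalence calculator, gel-lane densitometry, and a synthetic-data
generator with known ground truth for validating the whole pipeline.

## Worked example

```python
from plasmidkinetics import (PlasmidKineticsModel, equivalent_time,
                             generate_proportion_dataset, preset_config)

# synthetic EBRT dataset: 0-40 Gy, 6 replicates, truth ksr=1.21, krl=0.017
data = generate_proportion_dataset(preset_config("ebrt-1.25", seed=11))
res = PlasmidKineticsModel(data).fit()
print(res.summary())
```

```
Plasmid topology-conversion kinetics — weighted least squares
==============================================================
condition:        EBRT 1.25 ng/uL
exposure axis:    dose (Gy)
variant:          basic   mode: means
observations:     24   dof: 21
WRSS: 7.64634   reduced chi^2: 0.3641
converged: True   nfev: 11
--------------------------------------------------------------
param         estimate     std err  units
ksr             1.2082      0.0321  Gy^-1
krl          0.0172419    0.000476  Gy^-1
s0            0.939918     0.00892  
==============================================================
```

The supercoiled→relaxed rate (1.21 ± 0.03 Gy⁻¹) is recovered within one
standard error of the generating value, and `k_sr ≫ k_rl`: double-strand
breaks form much more slowly than single-strand breaks, so the second step
is rate-limiting.  Fitting a time-axis dataset the same way and asking for
the incubation time equivalent to 1 Gy:

```python
data_t = generate_proportion_dataset(preset_config("ga-0.5", seed=11))
res_t = PlasmidKineticsModel(data_t).fit()
eq = equivalent_time(res.ksr, res_t.ksr, 1.0)
print(f"1 Gy EBRT ~ {eq.value:.2f} ± {eq.se:.2f} h incubation")
# 1 Gy EBRT ~ 1.93 ± 0.12 h incubation
```

i.e. for these synthetic rates, roughly two hours of 0.5 MBq ⁶⁷Ga
incubation damages as much plasmid as 1 Gy of external beam.  With the
published rate estimates (k_sr,D = 1.21 ± 0.04 Gy⁻¹,
k_sr,t = 0.590 ± 0.100 h⁻¹) the same call gives 2.05 ± 0.35 h.

The same pipeline runs from the shell:

```sh
plasmidkinetics simulate --preset ebrt-1.25 --seed 11 --out ebrt.csv
plasmidkinetics fit --input ebrt.csv --out ebrt_fit.json
plasmidkinetics equiv --fit-dose ebrt_fit.json --ksr-time 0.59 --se-time 0.1 --dose 1
```

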