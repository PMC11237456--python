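# phageweapons

Temperate bacteriophages integrated in a bacterial genome (prophages) can
act as self-amplifying weapons: the lysogen carrying the phage is immune,
while spontaneously induced virions lyse susceptible competitors.  Whether
a given phage actually helps its host, though, depends on a tangle of
life-history traits — induction rate, probability of lysis, adsorption
rate, burst size, lysis rate, virion decay — and on the ecological
context, above all the lysogen's starting frequency in the population.

`phageweapons` is a simulation and analysis package for exactly this
question, aimed at microbial ecologists and phage biologists.  It provides
the compartmental ODE competition model, the effectivity metrics, the
trait-sweep and phage-ranking analyses, estimators that turn plate-assay
counts into model parameters, and synthetic-data generators so the whole
pipeline is testable end to end.

## The model

A focal strain F (optionally a lysogen), a susceptible background strain
B, novel lysogens N (background cells that acquired the phage), free
virions P, and induced / lytically infected pools F̃ and B̃ that are
committed to lysis:

    dF/dt  = F(r + μS − κ)
    dB/dt  = B(r + μS − αP)
    dN/dt  = B α(1−π) P + N(r + μS − κ_N)
    dP/dt  = βλ(B̃ + F̃) − αPB − δP
    dB̃/dt = κ_N N + απBP − λB̃
    dF̃/dt = κF − λF̃

with S the summed living bacterial abundance, so each strain grows
logistically against a shared carrying capacity K = −r/μ (generalized
Lotka–Volterra form).  A second, resource-explicit variant replaces
r + μS with r·g, g = R/(R + k), and depletes the nutrient R in proportion
to growth — the appropriate description of batch culture, where cells
killed *after* consuming nutrients drain the common pool.

The **phage effectivity index (PEI)** contrasts each lysogen run with a
phage-free control started from identical abundances: the focal strain's
final frequency with the phage minus its final frequency without it.
Relative-fitness and log-fold-change variants are also provided.

## Worked example

```python
>>> import phageweapons as pw
>>> phi2 = pw.load_preset("phi2")          # P. aeruginosa LESB58 Phi2 traits
>>> pair = pw.run_competition_pair(
...     pw.CompetitionSetup(focal_fraction=0.1),
...     phi2["traits"], phi2["community"])
>>> round(pw.pei_frequency(pair), 4)
0.4523
>>> pw.pei_relative_fitness(pair).v
1.342921180094623
```

Starting from 10% lysogens, carrying Phi2 lifts the focal strain's final
share of the community by 0.45 over the phage-free control, and its
Malthusian growth runs 1.34× the background strain's.  Predicting the
head-to-head difference between the high-lysis phage Phi2 (π = 0.91) and
Phi4 (π = 0.72) across starting frequencies:

```python
>>> pw.predict_experimental_pei(phi2["traits"],
...     pw.load_preset("phi4")["traits"], phi2["community"]) \
...     .pivot(index="f0", columns="phage", values="pei").round(3)
phage   phi2   phi4
f0
0.01   0.091  0.025
0.10   0.452  0.184
0.50   0.417  0.281
0.90   0.090  0.070
0.99   0.009  0.007
```

Phi2 beats Phi4 at every ratio, and both phages matter most at
intermediate frequencies — a rare lysogen makes too few virions, a
dominant one has nobody left to kill.

The same machinery is available from a thin CLI:

```
$ phageweapons simulate --preset fixed --ratio 0.1 --out traj.csv
wrote traj.csv (PEI = +0.0817)
$ phageweapons sweep --trait kappa --axis frequency --out grid.csv
$ phageweapons rank --n-sets 100 --n-phages 100 --seed 7 --regress --out vol.csv
```

Every output ships with a JSON manifest (parameters, seed, checksum) so it
can be regenerated exactly.

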