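"""Do cells in a population migrate farther than solitary cells?

Compares the farthest cell of an n-cell population against the best of n
independent solitary runs, for switching and non-switching cells, under
structured ECM.  Mesenchymal cells leave degraded trails that faster
amoeboid (or switched) cells can reuse, so the population's champion
outruns the solitary champion.  Small n and few repeats for speed; the
study design uses n=500 with 100 repeats.
"""

from ammica.experiments import EcmSpec, ScenarioSpec, cooperativity_experiment

spec = ScenarioSpec(ecm=EcmSpec("heterogeneous", theta=0.5), c_ratio=0.25,
                    base_seed=0)
res = cooperativity_experiment(spec, n=50, repeats=10)

print(f"mean d_max over {res.repeats} repeats (n = {res.n}):")
print(f"  (i)   switching population      {res.population_switching.mean():6.2f}")
print(f"  (ii)  best solitary switching   {res.single_switching.mean():6.2f}")
print(f"  (iii) non-switching population  {res.population_nonswitching.mean():6.2f}")
print(f"  (iv)  best solitary non-switch  {res.single_nonswitching.mean():6.2f}")
print()
print("the switching population leads: its cells both create and exploit")
print("paths, and shared degradation is a weak cooperative bonus.")
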