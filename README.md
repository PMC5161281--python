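# demeflow

Agent-based simulation and approximate Bayesian inference of sex-biased
Asian–Papuan admixture across island deme networks.

## The problem

During the mid-Holocene farming expansion, people of Asian ancestry
moved from mainland Asia through Island Southeast Asia, meeting resident
populations of Papuan ancestry. The admixture they left behind is
strikingly sex-biased: Asian ancestry is highest on mtDNA, then the X
chromosome, then the autosomes, and lowest on the Y — the signature of
gene flow channelled preferentially through women. `demeflow` is for
population geneticists and demographic modellers who want to ask *which
demographic and social parameters can produce such patterns*: it
forward-simulates individuals (birth, one-time migration, marriage,
reproduction, death) on a georeferenced network of island communities
while transmitting binary ancestry markers on four genomic systems, and
then inverts the model with approximate Bayesian computation (ABC).

## The model in brief

* **Demes.** Communities sit at lon/lat coordinates; two demes are
  connected if their great-circle distance is ≤ 650 km. Mainland
  "source" demes are perpetual reservoirs of unadmixed Asian ancestry.
  Carrying capacity grows as K(t) = min(K_max, K₀·e^{rt}); births and
  in-moves are blocked at capacity.
* **Agents.** Individuals age in 1-year steps under a compressed,
  doubled Siler mortality (e₀ ≈ 28 y). At maturity (18 y) an unmarried
  agent each year either moves (probability m_A or m_P by its ancestry
  class, once per lifetime, destination drawn by a Beta(1,5) kernel over
  distance-ranked neighbours), attempts a marriage, or stays.
* **Marriage.** Partners must live in the same deme, be of opposite sex
  and within ±6 years. A weighting M ∈ [0, 0.25] shifts union rates
  between ancestry classes: Papuan-man × Asian-woman unions carry weight
  0.25 + M, Asian-man × Papuan-woman 0.25 − M, within-group unions 0.25.
  Each family draws a maximum family size from Poisson(f_A or f_P by the
  mother's class) and bears at most one child per year under an
  age-specific natural-fertility schedule.
* **Genomes.** 25 unlinked diploid autosomal markers, 25 partially
  linked X markers (Poisson crossovers on a 1.8-Morgan female map),
  one mtDNA and one Y marker; alleles are 0 (Papuan) or 1 (Asian) and
  are transmitted without mutation. An individual is classified Asian
  when ≥ 50% of all its alleles are Asian.
* **Inference.** A run is reduced to regional mean Asian ancestry on the
  autosomes and X. Parameters (m_A, m_P, f_A, f_P, M) are drawn from
  uniform priors and the founding Asian layout D from a discrete
  library; rejection ABC keeps the tolerance-quantile of runs closest
  (Euclidean distance) to the observed vector, with optional local
  linear regression adjustment, leave-one-out prediction errors
  (E_pred), and posterior frequency of each founding layout.

## Worked example

```python
import demeflow
from demeflow import ParameterSet, run_simulation, scaled_config
from demeflow.summarize import regional_summary_vector, spread_rates

fix = demeflow.default_fixture(n_islands=8, demes_per_island=4, seed=0)
params = ParameterSet(m_a=0.51, m_p=0.31, f_a=3.9, f_p=5.7,
                      marriage_weight=0.23, start_distribution="D000")
cfg = scaled_config(pop_scale=1.0, steps=1000)
res = run_simulation(params, fix.network, cfg, seed=1, start=fix.library[0])

by = regional_summary_vector(res.world, regions=fix.regions,
                             systems=("autosome", "x", "mt", "y"))
print(by.groupby(level="system").mean().round(3))
print(spread_rates(res.arrival_log, fix.network, fix.library[0]))
```

prints (seed 1):

```
system
autosome    0.148
mt          0.155
x           0.159
y           0.124
Name: ancestry, dtype: float64
SpreadRates(marker_rate=4.808251198600489, agent_rate=2.9710534468229097,
            n_marker=23, n_agent=12, n_unreached=9)
```

Read: after 1000 years of expansion from a mainland-only founding layout
under the most probable parameter regime, mean Asian ancestry across
regions runs higher on the female-inherited systems (mtDNA, X) than on
the autosomes and lowest on the Y — the signature of unions biased
toward Asian women and Papuan men. (In any single replicate the mt–X
ranks can swap from haploid drift; pooled over admixed demes and ≥20
replicates the full step-like ordering mtDNA ≥ X ≥ autosomes ≥ Y holds —
see `tests/test_acceptance.py`.) The allele wavefront (4.8 km/yr) runs
ahead of the front of individuals classified Asian (3.0 km/yr), which
alleles always precede.

The same pipeline is scriptable from the shell:

```bash
demeflow fixtures --n-islands 8 --seed 0 --out fx/
demeflow simulate --demes fx/demes.csv --distributions fx/start_distributions.csv \
    --seed 1 --steps 1000 --out run/
demeflow sample --demes fx/demes.csv --distributions fx/start_distributions.csv \
    --n-sims 2000 --steps 220 --pop-scale 0.17 --out ref/
demeflow fit --table ref/reference_table.csv --observed fx/observed_ancestry.csv \
    --tolerance 0.01 --out posterior/
```

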