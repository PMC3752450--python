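"""Pure-CFTR-loss experiment over the filtered non-CF population.

For every accepted non-CF parameter set, apical Cl- permeability is set to
zero and the new steady state solved; dVt0 is the resulting change in basal
V_t. The distribution of dVt0 shows that losing the Cl- conductance alone
can depolarise or hyperpolarise V_t, and that even the most hyperpolarising
response (~ -4 mV) falls far short of the ~ -20 mV basal hyperpolarisation
seen in CF — the quantitative core of the argument that CF epithelia need
an increased ENaC permeability as well.

Usage: python analysis/05_cftr_knockout.py [N] [seed]
Writes results/cftr_knockout.csv and results/cftr_knockout_summary.json.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from nasotrans import default_baths, load_params
from nasotrans.config import write_results
from nasotrans.population import run_filter
from nasotrans.simulate import knockout_batch

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N = int(sys.argv[1]) if len(sys.argv) > 1 else 100_000
seed = int(sys.argv[2]) if len(sys.argv) > 2 else 1

baseline = load_params("table1_baseline")
baths = default_baths()
pop = run_filter(N, baseline, seed=seed)
mask = pop.accepted_nonCF
dvt0, ok = knockout_batch(pop.parameters[mask], baseline, baths)
dvt0 = dvt0[ok]

df = pd.DataFrame({"dVt0_mV": dvt0, "dVt_lowCl_mV": pop.observables[mask, 8][ok]})
df.to_csv(OUT / "cftr_knockout.csv", index=False)
summary = {
    "n": int(ok.sum()),
    "min_dVt0_mV": round(float(np.min(dvt0)), 3),
    "max_dVt0_mV": round(float(np.max(dvt0)), 3),
    "fraction_hyperpolarising": round(float((dvt0 < 0).mean()), 3),
    "fraction_depolarising": round(float((dvt0 > 0).mean()), 3),
}
write_results(summary, OUT / "cftr_knockout_summary.json")
print(f"CFTR knockout over {summary['n']} accepted non-CF sets:")
print(f"  dVt0 range [{summary['min_dVt0_mV']}, {summary['max_dVt0_mV']}] mV; "
      f"{summary['fraction_hyperpolarising']:.0%} hyperpolarise, "
      f"{summary['fraction_depolarising']:.0%} depolarise")
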