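"""Monte Carlo filtering of transport-parameter space.

Draws N parameter sets from U(0, 5 x baseline) per free parameter, computes
the nine observables for each, and splits them into sets compatible with the
healthy (non-CF) ranges and sets compatible with the CF ranges. The filtered
distributions show which transport parameters must shift in disease —
notably apical Cl- permeability down and apical Na+ permeability up.

Usage: python analysis/03_mc_filter.py [N] [seed] [variant]
Writes results/population_<variant>.csv (accepted sets only),
results/population_<variant>_counts.json and ..._percentiles.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from nasotrans import load_params
from nasotrans.config import write_results
from nasotrans.population import run_filter

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N = int(sys.argv[1]) if len(sys.argv) > 1 else 100_000
seed = int(sys.argv[2]) if len(sys.argv) > 2 else 1
variant = sys.argv[3] if len(sys.argv) > 3 else "default"

baseline = load_params("table1_baseline")
pop = run_filter(N, baseline, seed=seed, variant=variant)
counts = pop.counts
per_million = {k: round(v * 1e6 / N) for k, v in counts.items() if k != "N"}
print(f"variant={variant} N={N}: accepted {counts['nonCF']} non-CF, {counts['CF']} CF "
      f"({per_million['nonCF']} and {per_million['CF']} per 10^6 draws)")

frame = pop.to_frame()
accepted = frame[frame.label.isin(["nonCF", "CF"])]
accepted.to_csv(OUT / f"population_{variant}.csv", index=False, float_format="%.6g")
write_results({**counts, "per_million": per_million, "seed": seed},
              OUT / f"population_{variant}_counts.json")
table = pop.percentile_table()
table.to_csv(OUT / f"population_{variant}_percentiles.csv", index=False)

med = table[table.parameter.isin(["P_Na_ap", "P_Cl_ap"])][["condition", "parameter", "p50"]]
print("median apical permeabilities by condition (um/s):")
print(med.pivot(index="parameter", columns="condition", values="p50"))
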