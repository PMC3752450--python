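"""Regression sensitivity analysis over the filtered non-CF population.

Fits V_t (and the two clinical responses) as a linear function of the six
baseline-normalised transport parameters across the accepted non-CF sets.
The coefficients quantify the influence of each pathway: basolateral K+
permeability dominates basal V_t (hyperpolarising), apical Cl- permeability
is negligible there, while the amiloride response is driven up by ENaC and
damped by CFTR.

Usage: python analysis/04_sensitivity.py [N] [seed]
Writes results/sensitivity.json.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from nasotrans import load_params
from nasotrans.config import write_results
from nasotrans.params import FREE_PARAM_NAMES
from nasotrans.population import run_filter
from nasotrans.sensitivity import sensitivity_report

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N = int(sys.argv[1]) if len(sys.argv) > 1 else 100_000
seed = int(sys.argv[2]) if len(sys.argv) > 2 else 1

baseline = load_params("table1_baseline")
pop = run_filter(N, baseline, seed=seed)
report = sensitivity_report(pop, baseline, condition="nonCF")
write_results({k: v.as_dict() for k, v in report.items()}, OUT / "sensitivity.json")

vt = report["V_t"]
b = dict(zip(FREE_PARAM_NAMES, vt.coefficients))
print(f"accepted non-CF sets: {vt.n}")
print(f"basal V_t: b(P_K_bl) = {b['P_K_bl']:.3f} mV, "
      f"b(P_Cl_ap) = {b['P_Cl_ap']:.3f} mV "
      f"(|ratio| = {100 * abs(b['P_Cl_ap']) / abs(b['P_K_bl']):.1f}%), R^2 = {vt.r_squared:.2f}")
for out_name, res in report.items():
    print(f"{out_name}: influence ranking {[f'{n} ({c:+.2f})' for n, c in res.ranked()[:3]]}")
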