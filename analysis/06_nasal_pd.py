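"""Simulated clinical nasal potential-difference recordings.

Runs the three-phase protocol (basal, +amiloride at 5 min, +low luminal Cl-
at 10 min) for four parameterisations: fitted non-CF, non-CF with CFTR
reduced to 5%, fitted CF, and CF with CFTR restored to the non-CF level.
The traces show that reducing CFTR alone in a healthy cell does not
reproduce a CF recording, and that restoring CFTR alone in a CF cell does
not normalise basal V_t.

Writes results/nasal_pd_traces.csv and results/nasal_pd_summary.json.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from nasotrans import default_baths, load_params
from nasotrans.config import write_results
from nasotrans.simulate import run_nasal_pd_protocol

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

baths = default_baths()
frames, summaries = [], {}
for fixture, variant in (("table1_nonCF", "nonCF"), ("table1_nonCF", "nonCF_lowCFTR"),
                         ("table1_CF", "CF"), ("table1_CF", "CF_restoredCFTR")):
    trace = run_nasal_pd_protocol(load_params(fixture), baths, variant=variant,
                                  t_end_min=16.0, samples_per_min=6)
    df = trace.to_frame()
    df["variant"] = variant
    frames.append(df)
    summaries[variant] = trace.summary()
    s = summaries[variant]
    print(f"{variant:16s}: basal V_t {s['V_t_basal']:7.2f} mV, "
          f"dVt+amiloride {s['dVt_amiloride']:+6.2f} mV, "
          f"dVt+0Cl {s['dVt_low_chloride']:+6.2f} mV")

pd.concat(frames).to_csv(OUT / "nasal_pd_traces.csv", index=False, float_format="%.4g")
write_results(summaries, OUT / "nasal_pd_summary.json")
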