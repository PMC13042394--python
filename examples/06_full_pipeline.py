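"""Run the full orchestrated pipeline on the bundled two-condition demo.

Equivalent to `villustat run` on the command line. Writes per-condition spot
tables, counts, SAP coordinates, crypt regions, polarization scores, positive
rates, proximity networks, plus Ro/e, diversity tables and a run report.
"""

import json
from pathlib import Path

import villustat as vs

out = Path("scratch/pipeline_demo")
cfg = vs.demo_config(out, seed=1)
vs.run_pipeline(cfg)

report = json.loads((out / "report.json").read_text())
for cond in ("WT", "cKO"):
    s = report["stages"]
    print(f"{cond}: {s['simulate'][cond]['n_spots']} spots, "
          f"{s['sap'][cond]['n_regions']} crypt regions, "
          f"mean crypt macrophage M2-M1 delta = "
          f"{s['score'][cond]['mean_crypt_macrophage_delta']:+.3f}")
print(f"artifacts under {out}/")
# The WT-like delta should be positive (M2-dominant crypts) and the cKO-like
# delta negative, mirroring the polarization shift the pipeline quantifies.
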