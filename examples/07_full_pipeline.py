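"""Run every pipeline stage over a synthetic input bundle.

Generates the full bundle (airway phantom, parenchyma + lobe masks, vessel
map, displacement field, demographics, cohort), executes
airway -> normalize -> parenchyma -> vessels -> deform -> progress ->
correlate, and lists the outputs plus the run manifest, which records the
conventions used (log base, WT convention, SRI polarity, FDR method).
Equivalent shell usage: `lungqct simulate` then `lungqct run-all`.
"""

import tempfile
from pathlib import Path

from lungqct.pipeline import PipelineConfig, run_pipeline, simulate_bundle, validate_inputs

workdir = Path(tempfile.mkdtemp(prefix="lungqct_"))
bundle = workdir / "bundle"
simulate_bundle(bundle, seed=0)

report = validate_inputs({
    "parenchyma_hu": bundle / "parenchyma_hu.mha",
    "lobe_mask": bundle / "lobe_mask.mha",
    "vessel_csa": bundle / "vessel_csa.mha",
    "displacement": bundle / "displacement.mha",
    "airway_skeleton": bundle / "airway_skeleton.json",
    "cohort": bundle / "cohort.csv",
})
print(f"validation violations: {report or 'none'}")

config = PipelineConfig(out_dir=str(workdir / "out"))
manifest = run_pipeline(config, bundle)
print(f"stages run: {list(manifest.stages)}")
for f in sorted(Path(config.out_dir).iterdir()):
    print(f"  wrote {f.name}")
print()
print("Each CSV mirrors one analysis table: airway branch metrics, tracheal")
print("references, parenchymal class percentages, BV profiles, regional")
print("deformation summaries, progression values, paired tests with q-values,")
print("and the progression correlation matrix.")
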