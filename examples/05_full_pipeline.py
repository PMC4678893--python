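"""The full simulate-to-comparison pipeline from one config object.

Runs every stage — simulation, activation mapping, conjunction, ROI
definition, lateralization, signal change, deconvolved conditional GC,
bootstrap networks, degree/count analysis, group comparisons — and
writes TSV/NIfTI/JSON artifacts plus a deterministic run manifest.
"""
import json
from pathlib import Path

import pandas as pd

from hemiflow import PipelineConfig, run_pipeline
from hemiflow.config import GroupConfig

out = Path("pipeline_demo_out")
cfg = PipelineConfig(seed=11, out_dir=str(out))
cfg.simulation.groups = [
    GroupConfig(label="LH", n_subjects=6, asymmetry_ratio=1.0,
                edge_deltas=[["MOG_R", "INS_L", 0.35],
                             ["MOG_R", "INS_R", 0.35]]),
    GroupConfig(label="RH", n_subjects=6, asymmetry_ratio=3.0),
]

manifest = run_pipeline(cfg)
print(f"config hash {manifest.config_hash}; "
      f"{len(manifest.checksums)} artifacts written to {out}/")

li = pd.read_csv(out / "laterality.tsv", sep="\t")
print("\nmean LI by group (territory 'cerebral'):")
print(li.groupby("group").li.agg(["mean", "std"]).round(3))
print("\nLI categories:")
print(li.groupby("group").category.value_counts())
# the asymmetric (RH-like) cohort should come out left-lateralized,
# the symmetric (LH-like) cohort non-lateralized

counts = pd.read_csv(out / "count_comparison.tsv", sep="\t")
print("\nhemispheric count tests (group A = LH):")
print(counts[["count", "alternative", "mean_a", "mean_b", "p",
              "significant"]].to_string(index=False))
print("\nmanifest checksums are reproducible:",
      json.loads((out / "manifest.json").read_text())["config_hash"])
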