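"""Simulate the synthetic cohort: 73 subjects with DSC, FLAIR, and truth maps.

Volumes land under scratch/pipeline/subjects/ (NIfTI is binary and stays out
of the repo); the cohort roster is copied to results/.
"""

from pathlib import Path
import shutil

from rcbvpipe.pipeline import run_pipeline, validate_config

HERE = Path(__file__).resolve().parent
cfg = validate_config(HERE / "config.yaml")
run_pipeline(cfg, stages=("simulate",))

results = HERE.parent / "results"
results.mkdir(exist_ok=True)
shutil.copy(cfg.out_dir / "subjects" / "cohort.csv", results / "cohort.csv")
n = sum(1 for _ in (cfg.out_dir / "subjects").glob("sub-*"))
print(f"simulated {n} subjects -> {cfg.out_dir / 'subjects'}")
print(f"cohort roster -> {results / 'cohort.csv'}")
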