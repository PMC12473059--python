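"""Run every stage end to end on a synthetic corpus and inspect the manifest.

The same run is available from the shell as:
    psorimetrics run-all --out pipeline_out --seed 11
"""

import tempfile
from pathlib import Path

import psorimetrics as pm

with tempfile.TemporaryDirectory() as tmp:
    config = pm.PipelineConfig(output_dir=str(Path(tmp) / "run"), seed=11)
    manifest = pm.run_pipeline(config)

    print("stages executed:", " -> ".join(manifest["stages"]))
    print("record counts:  ", {k: v for k, v in manifest["counts"].items()
                               if isinstance(v, int)})
    print(f"variant recovery: {manifest['counts']['variant_recovery_pct']:.1f}% "
          "(injected formatting variants resolved to their canonical terms)")
    print(f"outputs written: {len(manifest['outputs'])} files, each with a "
          "SHA-256 checksum")
    # Re-running with the same seed and configuration reproduces every checksum.
    again = pm.run_pipeline(pm.PipelineConfig(output_dir=str(Path(tmp) / "run2"), seed=11))
    same = all(again["outputs"][k]["sha256"] == v["sha256"]
               for k, v in manifest["outputs"].items())
    print("checksums reproducible across runs:", same)
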