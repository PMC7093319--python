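"""Run the whole pipeline from a config and inspect the artifacts.

A PipelineConfig drives generate -> correlate -> estimate -> path
analytics -> bootstraps and writes every stage's output (CSV/JSON/
GraphML) plus a manifest whose seeds make the run reproducible.
A small cohort and bootstrap keep this example quick; scale n and B
up for a real analysis.
"""

import json
import tempfile
from pathlib import Path

import prsnet
from prsnet.pipeline import BootstrapConfig, PipelineConfig

outdir = Path(tempfile.mkdtemp()) / "run"
config = PipelineConfig(
    preset="cape_like", n=400, seed=7, estimator="threshold",
    bootstrap=BootstrapConfig(B=50, casedrop_B=10,
                              proportions=(0.0, 0.25, 0.5)),
    output_dir=str(outdir))

results = prsnet.run_pipeline(config)
model = results["model"]
print(f"estimated {model.n_edges} edges with '{model.estimator}' "
      f"(BIC {model.bic:.0f}) on n={results['dataset'].n}")
print(f"risk node reaches {results['betweenness'].targets_reached} symptoms "
      f"within {results['diagram'].n_levels} levels")
print(f"CS-coefficient: {results['stability'].cs_coefficient}")

print("\nartifacts:")
for f in sorted(outdir.iterdir()):
    print(f"  {f.name}")
manifest = json.loads((outdir / "manifest.json").read_text())
print(f"\nmanifest config hash {manifest['config_hash']}; rerunning with the "
      f"same seeds reproduces the deterministic outputs byte for byte.")
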