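#!/usr/bin/env python
"""Decompose the cohorts into redundancy/synergy maps, contrast the groups
region by region, and associate the changes with the communication models.

Reports the significant regions (permutation t-tests, stimulated minus
control), whether the stimulated target is among them, and the Spearman
association of the change map with each communication model's seed row.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tusnet.io import read_json
from tusnet.pipeline import RunConfig, run

CONFIG = Path(__file__).resolve().parents[1] / "configs" / "study.yaml"


def main():
    config = RunConfig.from_yaml(CONFIG)
    config.stages = {s: s in ("phiid", "contrast", "associate") for s in config.stages}
    run(config)

    contrast = read_json(config.out_dir / "contrast" / "contrast.json")
    sig = np.asarray(contrast["significant"], bool)
    t = np.asarray(contrast["t_values"])
    target = read_json(config.out_dir / "cohorts" / "tus" / "manifest.json")[
        "target_region"
    ]
    print(f"regions significant after stimulation: {int(sig.sum())} of {len(sig)}")
    print(f"stimulated target {target}: t = {t[target]:+.2f}, "
          f"significant = {bool(sig[target])}")

    assoc = read_json(config.out_dir / "associations" / "associations.json")
    print("model-change associations (Spearman rho, Bonferroni-corrected p):")
    for key, res in sorted(assoc.items()):
        star = " *" if res["p_corrected"] < 0.05 else ""
        print(f"  {key:22s} rho = {res['rho']:+.3f}  p = {res['p_corrected']:.4f}{star}")


if __name__ == "__main__":
    main()
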