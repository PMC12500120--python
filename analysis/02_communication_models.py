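#!/usr/bin/env python
"""Compute the four communication models (distance, SPE, SI, CMY) on the
representative connectome and report how they inter-correlate.

Distance and communicability are the two models later used as heterogeneity
vectors in the whole-brain model; SPE and SI are the efficiency-based
alternatives.
"""

import sys
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tusnet.pipeline import RunConfig, run

CONFIG = Path(__file__).resolve().parents[1] / "configs" / "study.yaml"


def main():
    config = RunConfig.from_yaml(CONFIG)
    config.stages = {s: s in ("commodels",) for s in config.stages}
    run(config)

    from tusnet.io import read_matrix

    comm = config.out_dir / "comm"
    mats = {name: read_matrix(comm / f"{name}.tsv") for name in
            ("distance", "spe", "si", "cmy")}
    n = mats["distance"].shape[0]
    iu = np.triu_indices(n, k=1)
    names = list(mats)
    print("pairwise Spearman correlations of the model matrices (upper triangles):")
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x, y = mats[a][iu], mats[b][iu]
            keep = np.isfinite(x) & np.isfinite(y)
            rho = spearmanr(x[keep], y[keep]).statistic
            print(f"  {a:9s} vs {b:9s}: rho = {rho:+.3f}")
    beta = read_matrix(comm / "beta.tsv").ravel()
    print(f"heterogeneity vector beta (distance node-summary): "
          f"range [{beta.min():.2f}, {beta.max():.2f}], mean {beta.mean():.2f}")


if __name__ == "__main__":
    main()
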