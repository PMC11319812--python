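#!/usr/bin/env python
"""Province similarity network and the centrality-augmentation robustness check.

Builds the |Spearman| province similarity matrix for 2015, picks the hard
threshold maximizing the entropy of the betweenness distribution, exports
the network, and measures how much appending the four centrality features
(degree, betweenness, closeness, eigenvector) shifts the forest's
cross-validated MAE.  A shift smaller than the across-repeat MAE standard
deviation indicates the model is robust to these potential confounders.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from smrnet import network, preprocess, studies, synth

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = preprocess.impute_mean(
        synth.IndicatorPanel.from_csv(ROOT / "data" / "panel.csv",
                                      ROOT / "data" / "panel_categories.csv")
    )
    M = panel.year_matrix(2015)
    D = network.spearman_abs_matrix(M.to_numpy())
    net = network.threshold_scan(D, np.linspace(0, 1, 101), node_ids=panel.province_ids)
    network.export_network(net, ROOT / "network_2015_edges.tsv",
                           ROOT / "network_2015_entropy.csv")
    network.centrality_features(net).to_csv(ROOT / "network_2015_centrality.csv")
    print(f"threshold {net.threshold:.2f} maximizes betweenness entropy "
          f"({max(h for _, h in net.entropy_curve):.2f} bits); "
          f"{len(net.edge_list())} edges among {net.n_nodes} provinces")

    rob = studies.network_robustness(seed=0, repeats=10)
    (ROOT / "network_robustness.json").write_text(json.dumps(rob, indent=2))
    print(f"RF MAE {rob['mae_original']:.4f} -> {rob['mae_augmented']:.4f} "
          f"with centrality features (|shift| {rob['mae_shift']:.4f}, "
          f"across-repeat sd {rob['mae_sd']:.4f})")
    print(f"robust to the 4 added features: {rob['mae_shift'] < rob['mae_sd']}")


if __name__ == "__main__":
    main()
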