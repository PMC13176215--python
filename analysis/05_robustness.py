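"""Permutation test (label shuffles rerun the whole CV) and bootstrap
confidence intervals for the ensemble's cross-validated performance."""

import json

import pandas as pd
from _common import DATA, RESULTS, SEED

from cdikit import robustness, synthetic

expression = synthetic.read_expression_tsv(DATA / "expression_corrected.tsv")
metadata = synthetic.read_metadata_tsv(DATA / "metadata.tsv")
features = (RESULTS / "features.txt").read_text().split()
train = metadata.index[metadata["role"] == "train"]

perm = robustness.permutation_test(
    expression.loc[features, train].T,
    metadata.loc[train, "class"].to_numpy(),
    n_iter=200, seed=SEED, search=False,
)
print(f"true AUC {perm.true_auc:.3f}, mean permuted {perm.mean_permuted_auc:.3f}, "
      f"p = {perm.p_value:.4g} ({perm.n_iter} permutations)")

oof = pd.read_csv(DATA / "oof_probabilities.tsv", sep="\t", index_col=0)
boot = robustness.bootstrap_ci(oof["y"].to_numpy(),
                               oof["ensemble"].to_numpy(),
                               n_iter=1000, seed=SEED)
for r in boot:
    print(f"{r.metric}: {r.mean:.3f} [{r.ci_low:.3f}, {r.ci_high:.3f}] "
          f"({r.level:.0%} percentile bootstrap)")

(RESULTS / "robustness.json").write_text(json.dumps(
    {"permutation": perm.as_dict(),
     "bootstrap": [r.as_dict() for r in boot]}, indent=1))
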