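"""Over-representation analysis of the selected genes against a synthetic
gene-set collection with planted enrichment, run overall and per direction,
plus the attribution-weighted pathway score."""

import pandas as pd
from _common import DATA, RESULTS, SEED

from cdikit import pathways, synthetic
from cdikit.synthetic import GroundTruth, generate_pathway_collection

expression = synthetic.read_expression_tsv(DATA / "expression_corrected.tsv")
truth = GroundTruth.from_json(DATA / "ground_truth.json")
deg_table = pd.read_csv(DATA / "deg_table.tsv", sep="\t", index_col="gene")
importance = pd.read_csv(RESULTS / "importance_ranking.tsv", sep="\t",
                         index_col="gene")

universe = expression.index.tolist()
features = deg_table.index[deg_table["selected"]].tolist()
collection = generate_pathway_collection(universe, truth, n_sets=40,
                                         enriched_fraction=0.15, seed=SEED)
pathways.write_gmt(collection, RESULTS / "genesets.gmt")

ora = pathways.enrich_collection(features, collection, universe)
scores = pathways.score_collection(collection, importance, features)
merged = ora.merge(scores, on="term")
merged.to_csv(RESULTS / "pathway_enrichment.tsv", sep="\t", index=False)
print(f"{int(ora['significant'].sum())} of {len(ora)} terms significant at "
      f"FDR < 0.05")
print(merged.head(8)[["term", "k", "K", "fdr", "shap_score"]]
      .round(4).to_string(index=False))

up = deg_table.index[deg_table["direction"] == "up"]
down = deg_table.index[deg_table["direction"] == "down"]
up_res, down_res = pathways.directional_enrichment(up, down, collection,
                                                   universe)
up_res.to_csv(RESULTS / "pathway_up.tsv", sep="\t", index=False)
down_res.to_csv(RESULTS / "pathway_down.tsv", sep="\t", index=False)
print(f"directional runs: {int(up_res['significant'].sum())} up-significant, "
      f"{int(down_res['significant'].sum())} down-significant terms")
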