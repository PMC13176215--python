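"""Welch's t-test with BH correction on the training cohort; genes pass with
FDR < 0.05 and |log2FC| > 0.5. Reports recovery of the planted signal."""

from _common import DATA, RESULTS

from cdikit import deg, synthetic
from cdikit.synthetic import GroundTruth

expression = synthetic.read_expression_tsv(DATA / "expression_corrected.tsv")
metadata = synthetic.read_metadata_tsv(DATA / "metadata.tsv")
truth = GroundTruth.from_json(DATA / "ground_truth.json")

train = metadata.index[metadata["role"] == "train"]
table = deg.deg_table(expression.loc[:, train], metadata.loc[train, "class"])
table.to_csv(DATA / "deg_table.tsv", sep="\t")

selected = table.index[table["selected"]]
n_up = (table["direction"] == "up").sum()
n_down = (table["direction"] == "down").sum()
planted = set(truth.deg_symbols)
print(f"selected {len(selected)} genes ({n_up} up, {n_down} down) "
      f"of {len(table)} tested")
print(f"sensitivity vs planted truth: "
      f"{len(set(selected) & planted) / len(planted):.2f}; "
      f"false discoveries: {len(set(selected) - planted)}")
(RESULTS / "features.txt").write_text("\n".join(selected) + "\n")
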