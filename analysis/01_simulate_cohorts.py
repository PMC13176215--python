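"""Generate the synthetic multi-batch study: six tissue datasets with batch
effects and a graded degradation spectrum, plus a strain-vs-control
mini-cohort. Writes the raw expression matrix, sample metadata and the
planted ground truth."""

from _common import COHORT, DATA, RESULTS

from cdikit import synthetic

expression, metadata, truth = synthetic.generate_multibatch_expression(COHORT)
synthetic.write_expression_tsv(expression, DATA / "expression_raw.tsv")
synthetic.write_metadata_tsv(metadata, DATA / "metadata.tsv")
truth.to_json(DATA / "ground_truth.json")

print(f"cohort: {expression.shape[0]} genes x {expression.shape[1]} samples "
      f"in {metadata['batch'].nunique()} batches")
print(metadata.groupby(['role', 'condition']).size().to_string())
print(f"planted: {len(truth.deg_genes)} DEGs "
      f"({sum(1 for _, d in truth.deg_genes if d > 0)} up), "
      f"{len(truth.mechano_genes)} strain-responsive")
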