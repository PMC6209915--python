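pathway_db: examples/pathways.tsv
expression: examples/expression.tsv
metadata: examples/metadata.tsv
drug_map: examples/drug_targets.tsv
alias_table: examples/aliases.tsv
fraction: 0.5
floor: 1.0
top_n: 3
out_dir: results/demo
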