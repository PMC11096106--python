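# Demo configuration for the end-to-end pipeline:
#   pansynkit run --config examples/pipeline_config.yaml
# Stages: simulate -> classify -> syndiv -> svmerge -> censize -> report.
# Outputs land in pipeline_demo/ with a manifest of sha256 digests;
# re-running with the same config reproduces identical digests.
outdir: pipeline_demo
seed: 42
rarefaction_replicates: 500
repeat_accessions: 4
sim:
  n_accessions: 20
  n_families: 500
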