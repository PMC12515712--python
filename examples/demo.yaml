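# Small end-to-end demonstration: simulate a 150 kb reference with four
# reference L1HS copies, plant four germline insertions plus one somatic
# insertion (30 % of cells, follow-up sample only), then run the full
# cascade.  Completes in a few seconds on one CPU:
#
#   l1trace run-all --config examples/demo.yaml
#
seed: 7
outdir: demo_out
simulate:
  genome_length: 150000
  n_ref_l1: 4
  genome_equivalents: 50
  mean_reads_per_molecule: 2.0
  subst_error_rate: 0.001
  chimera_rate: 0.002
  germline: 4
  somatic:
    - cell_fraction: 0.3
      samples: [s_fu]
      n: 1
samples:
  - sample_id: s_base
    subject: subjA
    timepoint: baseline
    condition: untreated
  - sample_id: s_fu
    subject: subjA
    timepoint: day28
    condition: untreated
baseline_label: baseline
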