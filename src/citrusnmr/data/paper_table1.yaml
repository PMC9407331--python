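# Table-driven run: skip simulation, fit both instruments' models on
# the bundled reference varieties and emit the comparison report.
output_dir: citrusnmr_table_out
use_reference_table: true
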