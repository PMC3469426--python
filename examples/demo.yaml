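# Demo configuration: simulate every data layer on a 2 x 200 kb genome and
# run the full analysis. `suvrkit run --config examples/demo.yaml`
outdir: suvrkit_demo
seed: 11
simulate: true
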