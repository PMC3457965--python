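49267538378ad99fe0c2e09db075d2a40e268e5e3c735b2e259c566a9bfe5774  table1_probes.tsv
76dcee8bca59d0f04a45e4d9174bb150acc342220003979d66564024582862bb  table2_summary.tsv
0b86823d7fa8a5a6f3fc5c9ca9a0823984bfbc4340c218ebb7c598a0d89d05a0  table3_series.tsv
6b3948652691ea905db7c17ca67ff9a1be95604dad4a998d86f0c7295c9998aa  nn_params_santalucia.csv
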