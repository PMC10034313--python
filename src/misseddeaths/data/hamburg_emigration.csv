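diagnosis_group,emigrations,persons
"Colorectum (C18-C21)",964,31057
"Pancreas (C25)",36,8002
"Lung (C33-C34)",319,30074
"Female breast (C50)",1934,35550
"Prostate (C61)",842,25241
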