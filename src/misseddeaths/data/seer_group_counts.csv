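diagnosis_group,n_patients,n_deaths,n_missed
"Oral cavity, pharynx, larynx (C00-C14, C30-C32)",214194,132105,33
"Esophagus, stomach (C15-C16)",172502,146866,20
"Intestine (C17-C21, C26)",723196,478874,16
"Liver, gallbladder, bile ducts (C22-C24)",127233,108527,32
"Pancreas (C25)",176048,162893,27
"Thorax (C33-C34, C37-C39, C45)",933743,829143,6
"Malignant melanoma (C43)",295823,88920,231
"Bones, soft tissues (C40, C41, C46-C49)",82679,51305,33
"Breast (C50)",957499,373349,19
"Vulva, vagina, uterine cervix (C51-C53)",86859,41168,5
"Corpus uteri (C54-C55)",199411,85238,2
"Ovaries, other female genital organs (C56-C58)",117272,80887,63
"Male genital organs (C60, C62, C63)",52423,9114,0
"Prostate (C61)",875432,366773,0
"Urinary organs (C64-C68, C74)",481187,269131,33
"Central nervous system (C69-C72)",108846,83001,13
"Thyroid and other endocrine glands (C73, C75)",146517,18413,134
"Hodgkin lymphoma (C81)",40800,13236,0
"Non-Hodgkin lymphoma (C82-C88)",273704,158368,0
"Multiple myeloma (C90)",81574,59894,3
"Leukemia (C91-C96)",191275,128114,3
"Unspecified, ill-defined (C76, C80)",141353,131124,23
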