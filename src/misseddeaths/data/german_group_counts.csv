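diagnosis_group,n_patients,n_deaths,n_missed
"Oral cavity, pharynx, larynx (C00-C14, C30-C32)",184991,103012,738
"Esophagus, stomach (C15-C16)",251170,192952,1693
"Intestine (C17-C21, C26)",713309,391996,4141
"Liver, gallbladder, bile ducts (C22-C24)",124047,104123,859
"Pancreas (C25)",141445,124152,519
"Thorax (C33-C34, C37-C39, C45)",574300,476417,2154
"Malignant melanoma (C43)",204486,43122,1083
"Bones, soft tissues (C40, C41, C46-C49)",44174,22591,235
"Breast (C50)",791557,227326,2220
"Vulva, vagina, uterine cervix (C51-C53)",97465,41651,595
"Corpus uteri (C54-C55)",127332,48315,778
"Ovaries, other female genital organs (C56-C58)",93349,59790,489
"Male genital organs (C60, C62, C63)",57723,7047,77
"Prostate (C61)",625176,198413,2836
"Urinary organs (C64-C68, C74)",351936,186809,1995
"Central nervous system (C69-C72)",81558,59138,364
"Thyroid and other endocrine glands (C73, C75)",67122,10790,202
"Hodgkin lymphoma (C81)",24179,5274,45
"Non-Hodgkin lymphoma (C82-C88)",161772,74906,579
"Multiple myeloma (C90)",61052,38533,242
"Leukemia (C91-C96)",118005,66387,317
"Unspecified, ill-defined (C76, C80)",101488,87380,1119
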