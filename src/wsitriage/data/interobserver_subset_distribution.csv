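category,subcategory,count
malignant,squamous_carcinoma,25
malignant,adenocarcinoma,13
malignant,cgin,7
malignant,other,5
high_grade,cin2,27
high_grade,cin3,23
low_grade,hpv,32
low_grade,cin1,18
normal,normal_inflammation,50
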