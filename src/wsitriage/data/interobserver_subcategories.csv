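observer,assigned_subcategory,original_subcategory,count
A,squamous_carcinoma,squamous_carcinoma,25
A,adenocarcinoma,adenocarcinoma,12
A,adenocarcinoma,cgin,1
A,cgin,cgin,7
A,other,other,5
A,cin2,cin2,25
A,cin2,cin3,1
A,cin2,cin1,1
A,cin3,cin3,23
A,cin1,cin2,2
A,cin1,cin3,1
A,cin1,cin1,14
A,cin1,hpv,1
A,hpv,hpv,28
A,hpv,normal_inflammation,4
A,normal_inflammation,cin1,1
A,normal_inflammation,normal_inflammation,49
B,squamous_carcinoma,squamous_carcinoma,25
B,adenocarcinoma,adenocarcinoma,13
B,cgin,cgin,7
B,other,other,5
B,cin2,cin2,25
B,cin2,cin1,1
B,cin2,normal_inflammation,1
B,cin3,cin3,23
B,cin1,cin2,1
B,cin1,cin1,16
B,cin1,hpv,1
B,hpv,hpv,32
B,normal_inflammation,hpv,6
B,normal_inflammation,normal_inflammation,44
C,squamous_carcinoma,squamous_carcinoma,25
C,adenocarcinoma,adenocarcinoma,12
C,adenocarcinoma,cgin,1
C,cgin,cgin,7
C,other,squamous_carcinoma,1
C,other,adenocarcinoma,1
C,other,cgin,3
C,cin2,cin2,24
C,cin2,cin1,2
C,cin2,hpv,1
C,cin3,cin3,23
C,cin1,cin2,3
C,cin1,cin1,11
C,cin1,hpv,3
C,cin1,normal_inflammation,1
C,hpv,hpv,28
C,hpv,normal_inflammation,4
C,normal_inflammation,cin3,1
C,normal_inflammation,hpv,3
C,normal_inflammation,normal_inflammation,46
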