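observer,original_category,observed_category,count
A,malignant,malignant,50
A,malignant,high_grade,0
A,malignant,low_grade,0
A,malignant,normal,0
A,high_grade,malignant,0
A,high_grade,high_grade,49
A,high_grade,low_grade,1
A,high_grade,normal,0
A,low_grade,malignant,0
A,low_grade,high_grade,3
A,low_grade,low_grade,43
A,low_grade,normal,4
A,normal,malignant,0
A,normal,high_grade,0
A,normal,low_grade,1
A,normal,normal,49
B,malignant,malignant,50
B,malignant,high_grade,0
B,malignant,low_grade,0
B,malignant,normal,0
B,high_grade,malignant,0
B,high_grade,high_grade,48
B,high_grade,low_grade,1
B,high_grade,normal,1
B,low_grade,malignant,0
B,low_grade,high_grade,1
B,low_grade,low_grade,49
B,low_grade,normal,0
B,normal,malignant,0
B,normal,high_grade,0
B,normal,low_grade,6
B,normal,normal,44
C,malignant,malignant,50
C,malignant,high_grade,0
C,malignant,low_grade,0
C,malignant,normal,0
C,high_grade,malignant,0
C,high_grade,high_grade,47
C,high_grade,low_grade,3
C,high_grade,normal,0
C,low_grade,malignant,0
C,low_grade,high_grade,2
C,low_grade,low_grade,43
C,low_grade,normal,5
C,normal,malignant,0
C,normal,high_grade,1
C,normal,low_grade,3
C,normal,normal,46
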