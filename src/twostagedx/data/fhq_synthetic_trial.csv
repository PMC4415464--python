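# SYNTHETIC questionnaire validation fixture (the published per-question
# stage-1 tables are not available in machine-readable form).  Counts were
# constructed so that the analysis exhibits the documented behaviours: for
# the breast-cancer-like condition the selected question's restricted
# support truncates and the conditionally unbiased estimate falls below the
# pooled MLE (its selected-question counts, 19/26 and 14/22, are the
# published ones); for the other conditions the support is unrestricted and
# the two estimates coincide.  Rows flagged excluded=1 mimic questions
# dropped for sparse responses before threshold derivation.
condition,question,excluded,tp1,fn1,fp1,tn1,tp2,fn2
diabetes,Q1,0,40,20,50,150,,
diabetes,Q3,0,54,1,30,170,32,1
diabetes,Q4a,1,2,58,1,199,,
ihd,Q2,0,37,3,36,144,27,2
ihd,Q8,0,30,15,45,155,,
breast_cancer,Q6,0,12,16,60,140,,
breast_cancer,Q7,0,16,14,30,170,,
breast_cancer,Q8,0,19,7,40,160,14,8
breast_cancer,Q9a,1,1,25,2,198,,
colorectal_cancer,Q10,0,11,2,20,180,12,3
colorectal_cancer,Q11,0,10,6,30,175,,
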