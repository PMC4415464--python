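# Pairwise-complete correlation matrix of the stage-1 responses to the
# family-history questionnaire items (published study data).
question,Q1,Q2,Q3,Q5,Q6,Q7,Q8,Q10,Q11,Q12a,Q12b
Q1,1,0.142,0.121,0.051,0.072,0.028,0.096,0.047,0.086,0.049,0.062
Q2,0.142,1,0.101,0.090,0.056,0.033,0.062,0.006,0.050,0.002,0.063
Q3,0.121,0.101,1,-0.003,0.067,0.027,0.013,0.005,0.069,0.022,0.029
Q5,0.051,0.090,-0.003,1,0.006,0.016,0.014,-0.049,-0.014,0.121,0.012
Q6,0.072,0.056,0.067,0.006,1,0.005,0.018,0.045,-0.002,0.085,0.096
Q7,0.028,0.033,0.027,0.016,0.005,1,0.282,0.004,-0.007,0.116,0.124
Q8,0.096,0.062,0.013,0.014,0.018,0.282,1,-0.023,0.056,0.240,0.112
Q10,0.047,0.006,0.005,-0.049,0.045,0.004,-0.023,1,0.193,0.084,0.112
Q11,0.086,0.050,0.069,-0.014,-0.002,-0.007,0.056,0.193,1,0.187,0.121
Q12a,0.049,0.002,0.022,0.121,0.085,0.116,0.240,0.084,0.187,1,0.395
Q12b,0.062,0.063,0.029,0.012,0.096,0.124,0.112,0.112,0.121,0.395,1
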