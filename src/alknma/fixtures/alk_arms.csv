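trial,treatment,n,percent,outcome
JALEX,alectinib,103,92.23,orr
JALEX,crizotinib,104,78.85,orr
ALTA1L,brigatinib,137,74.45,orr
ALTA1L,crizotinib,138,62.32,orr
CROWN,lorlatinib,149,77.18,orr
CROWN,crizotinib,147,58.50,orr
EXALT3,ensartinib,143,74.13,orr
EXALT3,crizotinib,147,66.67,orr
ALEX,alectinib,152,82.89,orr
ALEX,crizotinib,151,75.50,orr
ALESIA,alectinib,125,91.20,orr
ALESIA,crizotinib,62,77.42,orr
PROFILE1029,crizotinib,104,87.50,orr
PROFILE1029,chemotherapy,103,45.63,orr
PROFILE1014,crizotinib,172,74.42,orr
PROFILE1014,chemotherapy,171,45.03,orr
PROFILE1007,crizotinib,173,65.32,orr
PROFILE1007,chemotherapy,174,19.54,orr
ALUR,alectinib,72,37.50,orr
ALUR,chemotherapy,35,2.86,orr
ASCEND4,ceritinib,189,72.49,orr
ASCEND4,chemotherapy,187,26.74,orr
ASCEND5,ceritinib,115,39.13,orr
ASCEND5,chemotherapy,116,6.90,orr
JALEX,alectinib,103,36.89,sae
JALEX,crizotinib,104,60.58,sae
ALTA1L,brigatinib,137,69.85,sae
ALTA1L,crizotinib,138,56.20,sae
CROWN,lorlatinib,149,64.43,sae
CROWN,crizotinib,147,38.03,sae
EXALT3,ensartinib,143,50.35,sae
EXALT3,crizotinib,147,42.47,sae
ALEX,alectinib,152,51.97,sae
ALEX,crizotinib,151,56.29,sae
ALESIA,alectinib,125,28.80,sae
ALESIA,crizotinib,62,48.39,sae
PROFILE1029,crizotinib,104,41.35,sae
PROFILE1029,chemotherapy,103,67.33,sae
PROFILE1014,crizotinib,172,50.29,sae
PROFILE1014,chemotherapy,171,53.25,sae
PROFILE1007,crizotinib,173,25.58,sae
PROFILE1007,chemotherapy,174,24.56,sae
ALUR,alectinib,72,27.14,sae
ALUR,chemotherapy,35,41.18,sae
ASCEND4,ceritinib,189,78.31,sae
ASCEND4,chemotherapy,187,61.71,sae
ASCEND5,ceritinib,115,90.43,sae
ASCEND5,chemotherapy,116,80.53,sae
JALEX,alectinib,103,11.65,discontinuation
JALEX,crizotinib,104,23.08,discontinuation
ALTA1L,brigatinib,137,13.24,discontinuation
ALTA1L,crizotinib,138,8.76,discontinuation
CROWN,lorlatinib,149,63.76,discontinuation
CROWN,crizotinib,147,58.45,discontinuation
EXALT3,ensartinib,143,9.09,discontinuation
EXALT3,crizotinib,147,6.85,discontinuation
ALEX,alectinib,152,14.47,discontinuation
ALEX,crizotinib,151,14.57,discontinuation
ALESIA,alectinib,125,7.20,discontinuation
ALESIA,crizotinib,62,9.68,discontinuation
PROFILE1029,crizotinib,104,8.65,discontinuation
PROFILE1029,chemotherapy,103,1.98,discontinuation
PROFILE1014,crizotinib,172,15.79,discontinuation
PROFILE1014,chemotherapy,171,9.47,discontinuation
ALUR,alectinib,72,5.71,discontinuation
ALUR,chemotherapy,35,8.82,discontinuation
ASCEND4,ceritinib,189,5.29,discontinuation
ASCEND4,chemotherapy,187,11.43,discontinuation
ASCEND5,ceritinib,115,3.48,discontinuation
ASCEND5,chemotherapy,116,5.31,discontinuation
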