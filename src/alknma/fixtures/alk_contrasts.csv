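trial,treat_ref,treat_alt,hr,ci_low,ci_high,outcome
JALEX,crizotinib,alectinib,0.37,0.26,0.52,pfs
ALTA1L,crizotinib,brigatinib,0.48,0.35,0.66,pfs
CROWN,crizotinib,lorlatinib,0.27,0.184,0.388,pfs
EXALT3,crizotinib,ensartinib,0.51,0.35,0.72,pfs
ALEX,crizotinib,alectinib,0.43,0.32,0.58,pfs
ALESIA,crizotinib,alectinib,0.37,0.22,0.61,pfs
PROFILE1029,chemotherapy,crizotinib,0.402,0.286,0.565,pfs
PROFILE1014,chemotherapy,crizotinib,0.45,0.35,0.60,pfs
PROFILE1007,chemotherapy,crizotinib,0.487,0.371,0.638,pfs
ALUR,chemotherapy,alectinib,0.32,0.17,0.59,pfs
ASCEND4,chemotherapy,ceritinib,0.55,0.42,0.73,pfs
ASCEND5,chemotherapy,ceritinib,0.49,0.36,0.67,pfs
JALEX,crizotinib,alectinib,0.80,0.35,1.82,os
ALTA1L,crizotinib,brigatinib,0.54,0.31,0.92,os
CROWN,crizotinib,lorlatinib,0.72,0.57,1.47,os
EXALT3,crizotinib,ensartinib,0.91,0.54,1.54,os
ALEX,crizotinib,alectinib,0.67,0.46,0.98,os
ALESIA,crizotinib,alectinib,0.28,0.12,0.68,os
PROFILE1029,chemotherapy,crizotinib,1.056,0.734,1.521,os
PROFILE1014,chemotherapy,crizotinib,0.760,0.548,1.053,os
PROFILE1007,chemotherapy,crizotinib,0.854,0.661,1.104,os
ALUR,chemotherapy,alectinib,0.89,0.35,2.24,os
ASCEND4,chemotherapy,ceritinib,0.73,0.50,1.08,os
ASCEND5,chemotherapy,ceritinib,1.0,0.67,1.49,os
JALEX,crizotinib,alectinib,0.08,0.01,0.61,pfs_bm
ALTA1L,crizotinib,brigatinib,0.293,0.17,0.51,pfs_bm
CROWN,crizotinib,lorlatinib,0.21,0.099,0.436,pfs_bm
EXALT3,crizotinib,ensartinib,0.55,0.3,1.01,pfs_bm
ALEX,crizotinib,alectinib,0.37,0.23,0.58,pfs_bm
ALESIA,crizotinib,alectinib,0.11,0.05,0.28,pfs_bm
PROFILE1029,chemotherapy,crizotinib,0.507,0.258,0.994,pfs_bm
PROFILE1014,chemotherapy,crizotinib,0.4,0.23,0.69,pfs_bm
PROFILE1007,chemotherapy,crizotinib,0.67,0.44,1.03,pfs_bm
ALUR,chemotherapy,alectinib,0.12,0.05,0.27,pfs_bm
ASCEND4,chemotherapy,ceritinib,0.7,0.44,1.12,pfs_bm
ASCEND5,chemotherapy,ceritinib,0.54,0.36,0.8,pfs_bm
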