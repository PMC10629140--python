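original_firstorder_Mean
original_firstorder_Entropy
original_firstorder_Uniformity
original_firstorder_Skewness
original_firstorder_Kurtosis
original_glcm_Contrast
original_glcm_Correlation
original_glcm_JointEntropy
original_glcm_Idm
original_glrlm_GrayLevelNonUniformity
original_glrlm_RunLengthNonUniformity
original_glrlm_ShortRunEmphasis
original_glszm_GrayLevelNonUniformity
original_glszm_ZoneEntropy
original_gldm_DependenceNonUniformity
original_gldm_GrayLevelNonUniformity
original_ngtdm_Coarseness
original_ngtdm_Busyness
wavelet-LLL_firstorder_Mean
wavelet-LLH_glcm_JointEntropy
wavelet-HLL_glrlm_RunLengthNonUniformity
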