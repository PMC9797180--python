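cohort,category,feature,regions_failed,n_patients
GE,GradientOrientHistogram,InterQuartileRange,4,14
GE,GradientOrientHistogram,Kurtosis,4,14
GE,GradientOrientHistogram,MeanAbsoluteDeviation,4,14
GE,GradientOrientHistogram,MedianAbsoluteDeviation,4,14
GE,GradientOrientHistogram,Percentile,4,14
GE,GradientOrientHistogram,PercentileArea,4,14
GE,GradientOrientHistogram,Quantile,4,14
GE,GradientOrientHistogram,Range,4,14
GE,GradientOrientHistogram,Skewness,4,14
GE,GLCM3D,Autocorrelation,1,14
GE,GLCM3D,InverseDiffMomentNorm,4,14
GE,GLCM3D,InverseDiffNorm,4,14
GE,GLCM3D,SumAverage,3,14
GE,IntensityHistGaussFit,GaussAmplitude,3,14
GE,IntensityHistGaussFit,GaussArea,3,14
GE,IntensityHistGaussFit,GaussMean,3,14
GE,IntensityHistGaussFit,GaussStd,3,14
GE,IntensityHistGaussFit,HistArea,3,14
GE,IntensityHistGaussFit,NumberOfGauss,3,14
Siemens,GradientOrientHistogram,InterQuartileRange,4,18
Siemens,GradientOrientHistogram,Kurtosis,4,18
Siemens,GradientOrientHistogram,MeanAbsoluteDeviation,4,18
Siemens,GradientOrientHistogram,MedianAbsoluteDeviation,4,18
Siemens,GradientOrientHistogram,Percentile,4,18
Siemens,GradientOrientHistogram,PercentileArea,4,18
Siemens,GradientOrientHistogram,Quantile,4,18
Siemens,GradientOrientHistogram,Range,4,18
Siemens,GradientOrientHistogram,Skewness,4,18
Siemens,GLCM2D,Energy,4,18
Siemens,GLCM2D,Entropy,3,18
Siemens,GLCM3D,Energy,4,18
Siemens,GLCM3D,Entropy,3,18
Siemens,GLCM3D,InverseDiffMomentNorm,4,18
Siemens,GLCM3D,InverseDiffNorm,4,18
Siemens,GLCM3D,MaxProbability,4,18
Siemens,GrayRunLength2D,GrayLevelNonuniformity,1,18
Siemens,GrayRunLength2D,HighGrayLevelRunEmpha,1,18
Siemens,GrayRunLength2D,LongRunEmphasis,1,18
Siemens,GrayRunLength2D,LongRunHighGrayLevelEmpha,1,18
Siemens,GrayRunLength2D,LongRunLowGrayLevelEmpha,1,18
Siemens,GrayRunLength2D,LowGrayLevelRunEmpha,1,18
Siemens,GrayRunLength2D,RunLengthNonuniformity,1,18
Siemens,GrayRunLength2D,RunPercentage,1,18
Siemens,GrayRunLength2D,ShortRunEmphasis,1,18
Siemens,GrayRunLength2D,ShortRunHighGrayLevelEmpha,1,18
Siemens,GrayRunLength2D,ShortRunLowGrayLevelEmpha,1,18
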