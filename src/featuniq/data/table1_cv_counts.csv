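cohort,category,feature,patients_failed,n_patients
GE,GradientOrientHistogram,InterQuartileRange,10,14
GE,GradientOrientHistogram,Kurtosis,11,14
GE,GradientOrientHistogram,MeanAbsoluteDeviation,13,14
GE,GradientOrientHistogram,MedianAbsoluteDeviation,10,14
GE,GradientOrientHistogram,Percentile,8,14
GE,GradientOrientHistogram,PercentileArea,9,14
GE,GradientOrientHistogram,Quantile,1,14
GE,GradientOrientHistogram,Range,14,14
GE,GLCM2D,InverseDiffMomentNorm,14,14
GE,GLCM2D,InverseDiffNorm,14,14
GE,GLCM3D,InverseDiffMomentNorm,14,14
GE,GLCM3D,InverseDiffNorm,14,14
GE,IntensityDirect,GlobalMax,2,14
GE,IntensityDirect,GlobalStd,1,14
GE,IntensityDirect,GlobalUniformity,1,14
GE,IntensityDirect,Kurtosis,1,14
GE,IntensityDirect,LocalEntropyMax,1,14
GE,IntensityDirect,LocalEntropyMean,1,14
GE,IntensityDirect,LocalEntropyMedian,1,14
GE,IntensityDirect,LocalEntropyMin,1,14
GE,IntensityDirect,LocalEntropyStd,1,14
GE,IntensityDirect,LocalRangeMax,1,14
GE,IntensityDirect,LocalRangeMean,1,14
GE,IntensityDirect,LocalRangeMedian,1,14
GE,IntensityDirect,LocalRangeMin,1,14
GE,IntensityHistGaussFit,HistArea,14,14
GE,NeighborIntensityDiff3D,Coarseness,1,14
Siemens,GradientOrientHistogram,InterQuartileRange,16,18
Siemens,GradientOrientHistogram,Kurtosis,17,18
Siemens,GradientOrientHistogram,MeanAbsoluteDeviation,17,18
Siemens,GradientOrientHistogram,MedianAbsoluteDeviation,15,18
Siemens,GradientOrientHistogram,Percentile,13,18
Siemens,GradientOrientHistogram,PercentileArea,13,18
Siemens,GradientOrientHistogram,Quantile,7,18
Siemens,GradientOrientHistogram,Range,18,18
Siemens,GLCM2D,DifferenceEntropy,9,18
Siemens,GLCM2D,Energy,2,18
Siemens,GLCM2D,Entropy,12,18
Siemens,GLCM2D,InformationMeasureCorr1,2,18
Siemens,GLCM2D,InformationMeasureCorr2,10,18
Siemens,GLCM2D,InverseDiffMomentNorm,18,18
Siemens,GLCM2D,InverseDiffNorm,18,18
Siemens,GLCM2D,SumEntropy,10,18
Siemens,GLCM3D,DifferenceEntropy,9,18
Siemens,GLCM3D,Energy,2,18
Siemens,GLCM3D,Entropy,13,18
Siemens,GLCM3D,InformationMeasureCorr1,2,18
Siemens,GLCM3D,InformationMeasureCorr2,12,18
Siemens,GLCM3D,InverseDiffMomentNorm,14,18
Siemens,GLCM3D,InverseDiffNorm,14,18
Siemens,GLCM3D,SumEntropy,12,18
Siemens,GrayRunLength2D,LongRunEmphasis,13,18
Siemens,GrayRunLength2D,RunLengthNonuniformity,13,18
Siemens,GrayRunLength2D,RunPercentage,13,18
Siemens,GrayRunLength2D,ShortRunEmphasis,13,18
Siemens,IntensityDirect,GlobalEntropy,9,18
Siemens,IntensityDirect,GlobalMax,2,18
Siemens,IntensityDirect,GlobalStd,0,18
Siemens,IntensityDirect,GlobalUniformity,1,18
Siemens,IntensityDirect,LocalEntropyMean,13,18
Siemens,IntensityDirect,LocalEntropyMedian,13,18
Siemens,IntensityDirect,LocalEntropyMin,13,18
Siemens,IntensityDirect,LocalEntropyStd,11,18
Siemens,IntensityDirect,LocalRangeMax,6,18
Siemens,IntensityDirect,LocalRangeMean,1,18
Siemens,IntensityDirect,LocalRangeMedian,1,18
Siemens,IntensityDirect,LocalRangeStd,2,18
Siemens,IntensityDirect,LocalStdMax,1,18
Siemens,IntensityDirect,LocalStdMean,1,18
Siemens,IntensityDirect,LocalStdMin,1,18
Siemens,IntensityDirect,LocalStdStd,1,18
Siemens,IntensityDirect,Range,1,18
Siemens,IntensityHistogram,Range,1,18
Siemens,IntensityHistGaussFit,HistArea,18,18
Siemens,NeighborIntensityDiff2D,Contrast,1,18
Siemens,NeighborIntensityDiff3D,Coarseness,1,18
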