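dataset,model,accuracy,precision,auc
Elderly,RF,0.699,0.671,0.645
LLOS,RF,0.858,0.927,0.855
Stroke,RF,0.805,0.730,0.703
ARF,RF,0.630,0.646,0.619
CIR,RF,0.767,0.800,0.737
Elderly,SVM,0.712,0.661,0.650
LLOS,SVM,0.869,0.908,0.855
Stroke,SVM,0.829,0.735,0.716
ARF,SVM,0.559,0.622,0.547
CIR,SVM,0.837,0.688,0.737
Elderly,LR,0.698,0.647,0.634
LLOS,LR,0.884,0.935,0.866
Stroke,LR,0.800,0.625,0.666
ARF,LR,0.606,0.694,0.596
CIR,LR,0.767,0.733,0.670
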