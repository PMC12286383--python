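table,method,AT,CA,EF,CO,ED,PN,avg_printed
scenario1,Single Best,63.37,90.50,88.71,63.54,82.44,77.30,77.64
scenario1,JAN,65.88,97.21,95.42,75.27,86.55,75.11,82.57
scenario1,DCTN,70.53,96.23,92.81,77.61,86.77,86.88,85.14
scenario1,M3SDA,69.76,98.58,95.23,78.56,87.56,83.60,85.55
scenario1,ABMSDA,70.76,98.98,94.23,75.56,87.76,89.25,86.09
scenario1,CASR,89.99,98.70,98.30,85.95,95.80,82.86,91.93
scenario1,TSCDA,89.38,98.32,96.25,86.72,94.30,90.37,92.56
scenario1,CAMSDA-RMM,90.50,98.02,97.82,88.80,95.40,90.44,93.50
scenario2,Single Best,81.15,88.86,90.12,90.32,84.33,86.79,86.93
scenario2,JAN,82.38,91.97,93.89,94.30,89.81,89.44,90.30
scenario2,DCTN,81.48,91.22,94.19,95.10,88.96,89.58,90.09
scenario2,M3SDA,83.09,87.20,96.11,95.10,86.87,87.40,89.29
scenario2,CASR,82.26,87.64,94.71,96.61,90.22,85.12,89.43
scenario2,TSCDA,82.98,92.13,95.88,95.76,92.09,88.68,91.25
scenario2,CAMSDA-RMM,83.64,91.50,95.30,96.84,91.88,91.25,91.74
class_aware_ablation,Without strategy,90.00,96.89,96.72,87.55,94.38,89.75,92.55
class_aware_ablation,With strategy,90.50,98.02,97.82,88.80,95.40,90.44,93.50
reweighting_ablation,Without strategy,82.88,90.90,95.70,96.51,91.36,90.22,91.26
reweighting_ablation,With strategy,83.64,91.50,95.30,96.84,91.88,91.25,91.74
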