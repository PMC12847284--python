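dataset,Naive Bayes,1-NN,3-NN,MLP,SMO,C4.5,Random Forest,3-SBC,5-SBC
Appendicitis,0.786,0.745,0.738,0.75,0.744,0.732,0.744,0.703,0.746
Exasens COPD,0.9,0.937,0.875,0.95,0.887,0.887,0.912,0.898,0.9
Acute Inflammations D1,0.992,1,1,1,1,1,0.933,1,1
Acute Inflammations D2,1,1,1,1,1,1,0.958,1,1
ACPs Lung Cancer,0.695,0.683,0.648,0.707,0.707,0.559,0.645,0.984,0.984
Vertical Column 2C,0.801,0.809,0.751,0.807,0.704,0.77,0.82,0.712,0.735
Contraceptive,0.514,0.417,0.42,0.54,0.488,0.488,0.507,0.637,0.636
Cryotherapy,0.841,0.9,0.911,0.879,0.879,0.936,0.936,0.934,0.941
Dermatology,0.976,0.952,0.969,0.968,0.971,0.955,0.958,0.967,0.971
Hepatitis,0.83,0.736,0.763,0.755,0.807,0.85,0.835,0.818,0.835
Mammographic Masses,0.828,0.754,0.763,0.822,0.796,0.822,0.797,0.84,0.834
Wisconsin,0.964,0.94,0.964,0.939,0.965,0.937,0.963,0.939,0.941
HCC Survival,0.677,0.6,0.584,0.6,0.711,0.546,0.668,0.828,0.822
Autism Adolescent,0.959,0.882,0.841,0.887,0.891,1,1,0.923,0.902
Autism Child,0.827,0.748,0.784,0.798,0.829,0.819,0.812,0.969,0.976
Survey Lung Cancer,0.688,0.758,0.745,0.802,0.782,0.747,0.754,0.792,0.765
Breast Cancer Coimbra,0.63,0.67,0.674,0.651,0.663,0.688,0.735,1,1
Saheart,0.655,0.58,0.619,0.63,0.658,0.657,0.622,0.577,0.57
Cirrhosis,0.515,0.429,0.444,0.525,0.52,0.549,0.524,0.642,0.617
Multiple Sclerosis,0.902,0.788,0.802,0.907,0.812,0.783,0.786,0.984,0.983
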