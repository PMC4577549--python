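population,sex,quantile,2010,2020,2030,2040,2050
Spain,F,0.025,84.63,85.32,85.97,86.58,87.18
Spain,M,0.025,78.55,79.25,79.93,80.60,81.27
Spain,F,0.5,84.8,87.13,89.39,91.62,93.84
Spain,M,0.5,78.73,81.21,83.64,86.07,88.51
Spain,F,0.975,84.87,87.98,91.08,94.18,97.18
Spain,M,0.975,78.86,82.66,86.44,90.20,93.86
Hungary,F,0.025,78.31,79.16,79.98,80.78,81.56
Hungary,M,0.025,70.29,71.15,72.01,72.86,73.71
Hungary,F,0.5,78.51,81.39,84.16,86.82,89.34
Hungary,M,0.5,70.54,73.97,77.43,80.81,84.09
Hungary,F,0.975,78.60,82.39,86.16,89.89,93.53
Hungary,M,0.975,70.65,75.18,79.74,84.24,88.57
Russia,F,0.025,74.79,75.71,76.56,77.36,78.12
Russia,M,0.025,62.82,63.77,64.67,65.55,66.40
Russia,F,0.5,74.98,77.75,80.45,83.13,85.83
Russia,M,0.5,63.04,66.21,69.38,72.62,75.97
Russia,F,0.975,75.11,79.26,83.33,87.37,91.34
Russia,M,0.975,63.25,68.55,73.88,79.21,84.47
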