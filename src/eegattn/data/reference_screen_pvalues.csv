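component,apen,mean,iqr,mad,range,variance,skewness,kurtosis,l1,l2,linf
EEG-SSA1,5.97e-15,9.06e-5,3.50e-2,2.93e-5,1.28e-17,3.65e-2,9.66e-23,1.06e-49,3.65e-2,9.17e-2,3.65e-23
EEG-SSA2,6.49e-3,4.51e-8,2.75e-1,1.43e-2,2.73e-9,4.98e-7,1.41e-50,9.94e-15,4.99e-7,4.53e-4,6.54e-9
EEG-SSA3,4.75e-3,4.11e-6,2.64e-4,1.12e-1,3.71e-2,5.41e-7,2.04e-73,1.47e-2,5.41e-7,2.47e-2,3.46e-2
EEG-SSA4,4.49e-19,7.14e-9,5.73e-29,1.35e-1,2.69e-10,7.02e-3,3.21e-5,1.28e-50,7.03e-3,2.24e-2,4.27e-11
delta-SSA1,1.67e-17,1.84e-1,8.43e-28,1.96e-24,3.24e-24,1.41e-26,4.86e-2,9.59e-2,1.41e-26,1.97e-27,2.83e-24
delta-SSA2,1.45e-8,1.84e-1,5.90e-17,8.29e-21,4.98e-13,2.84e-16,1.06e-1,6.84e-2,2.84e-16,1.55e-18,1.01e-13
theta-SSA1,6.45e-3,8.77e-7,9.28e-3,3.81e-9,6.34e-3,4.77e-3,3.46e-3,1.44e-1,4.77e-3,5.23e-3,5.36e-3
theta-SSA2,5.64e-3,8.77e-7,1.35e-1,3.79e-4,1.82e-4,1.09e-3,2.46e-11,9.33e-5,1.09e-3,7.74e-2,3.27e-5
alpha-SSA1,1.77e-16,3.23e-1,2.94e-2,1.60e-9,1.67e-5,2.89e-4,2.03e-6,2.66e-4,2.89e-4,1.31e-3,1.87e-5
alpha-SSA2,3.54e-6,3.23e-1,1.49e-2,3.41e-11,2.04e-14,9.81e-16,4.32e-3,1.67e-8,9.81e-16,4.59e-6,6.23e-14
SMR-SSA1,4.43e-10,5.30e-5,1.73e-1,1.21e-4,6.37e-5,1.97e-3,3.93e-11,1.11e-5,1.97e-3,9.44e-3,5.83e-5
SMR-SSA2,2.57e-4,5.30e-5,2.29e-1,5.13e-5,8.28e-13,2.01e-12,9.11e-9,6.09e-11,2.01e-12,2.27e-3,9.75e-13
mid_beta-SSA1,5.28e-9,1.15e-24,2.95e-1,1.10e-2,5.30e-9,1.63e-3,1.61e-1,1.15e-19,1.63e-3,7.85e-2,4.93e-9
mid_beta-SSA2,3.61e-4,1.15e-24,3.99e-1,1.46e-2,2.87e-6,1.54e-5,4.13e-31,9.97e-8,1.54e-5,4.44e-2,8.17e-10
high_beta-SSA1,3.71e-2,4.60e-20,7.91e-4,5.73e-2,2.54e-18,5.92e-2,1.93e-8,6.60e-43,5.92e-2,9.22e-2,2.13e-18
high_beta-SSA2,1.65e-1,4.60e-20,7.02e-4,1.31e-1,1.27e-19,3.49e-7,2.52e-38,3.38e-25,3.48e-7,9.57e-2,2.47e-25
low_beta-SSA1,1.38e-4,7.50e-21,1.86e-2,6.01e-3,5.24e-15,1.73e-3,1.44e-15,1.95e-32,1.73e-3,1.67e-1,3.56e-15
low_beta-SSA2,1.77e-8,7.50e-21,3.93e-2,2.81e-3,4.14e-16,1.96e-14,1.37e-33,4.58e-15,1.96e-14,6.08e-2,6.82e-20
beta-SSA1,3.62e-6,2.48e-28,9.81e-5,1.73e-1,5.44e-40,9.92e-3,3.08e-29,3.98e-57,9.92e-3,1.04e-1,2.34e-44
beta-SSA2,3.16e-1,2.48e-28,1.97e-4,1.24e-1,1.79e-5,1.36e-2,3.61e-24,1.21e-8,1.36e-2,1.55e-1,4.34e-9
gamma-SSA1,1.97e-4,3.21e-1,3.84e-3,1.36e-1,1.05e-1,1.24e-1,7.83e-2,7.68e-12,1.24e-1,3.25e-2,2.24e-1
gamma-SSA2,1.22e-1,3.21e-1,2.46e-3,1.44e-1,2.07e-3,8.36e-2,2.12e-4,1.60e-8,8.36e-2,4.04e-2,3.64e-4
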