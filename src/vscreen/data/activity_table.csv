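compound,training,pic50_experimental,pic50_estimated,error,fit_value,scale_experimental,scale_estimated
N1,1,7.14,6.22,-1.1,74.21,+++,+++
N2,1,6.89,7.24,2.3,73.29,+++,++
N3,0,5.76,5.45,3.2,72.34,++,++
N4,1,6.21,6.33,0.9,71.91,++,++
N5,0,6.23,6.1,2.9,70.14,++,+
N6,1,6.58,6.44,-1.3,72.14,+++,+++
N7,0,6.55,6.44,-1.8,71.36,+++,+++
N8,1,3.91,4.23,2.4,69.15,+,+
N9,0,5.59,6.27,-1.9,71.85,+,+
N10,1,8.03,8.11,1.2,75.12,+++,+++
N11,0,9.1,9.22,2.5,69.71,+++,++
N12,0,7.99,8.14,1.5,72.49,+++,+++
N13,1,8.28,8.22,-0.6,75.16,+++,+++
N14,1,8.47,8.84,2.2,76.12,+++,+++
N15,1,6.57,8.53,3.2,73.11,+++,+++
N16,0,6.49,6.78,-1.5,72.44,++,++
N17,1,6.26,8.23,3.1,71.94,++,+++
N18,0,6.24,6.21,1.3,72.45,++,++
N19,0,6.36,6.26,2.2,71.88,++,++
N20,0,8.47,7.98,3.7,72.67,+++,++
N21,1,5.77,5.72,-0.5,71.26,++,++
N22,0,7.34,7.31,2.8,72.12,+++,+++
S1,1,8.65,8.62,-0.3,77.68,+++,+++
S2,1,8.55,8.53,-0.4,76.23,+++,+++
S3,0,8.4,8.34,-0.5,70.11,+++,+++
S4,1,8.03,8.01,-0.3,75.1,+++,+++
S5,0,4.47,3.29,3.1,72.4,+,+
S6,0,4.94,5.13,-1.6,71.85,+,+
S7,1,5.7,4.91,-1.8,71.22,++,+
S8,0,4.91,4.9,0.4,69.36,+,+
S9,1,7.15,7.78,1.6,74.29,+++,+++
S10,0,5.9,5.56,3.4,71.36,++,+
S11,0,5.2,5.16,-0.3,70.88,+,+
S12,0,5.76,5.73,2.4,71.73,++,++
S13,0,7.14,6.78,1.2,71.49,+++,++
S14,0,4.35,4.36,-0.1,70.34,+,+
S15,0,6.03,6.05,1.9,71.13,++,++
S16,0,5.67,5.41,3.7,72.55,++,+
S17,1,5.02,6.01,1.4,70.63,+,+
S18,1,5.17,5.23,1.1,70.89,+,+
S19,1,4.71,4.67,-1.6,70.25,+,+
S20,0,5.05,5.03,0.4,71.61,+,+
S21,0,4.39,4.38,0.6,70.78,+,+
S22,1,4.41,4.41,-0.8,70.16,+,+
S23,0,5.68,5.7,1.5,71.64,++,++
S24,0,4.85,4.83,2.1,69.52,+,+
S25,1,5.38,5.96,1.7,71.13,+,+
S26,0,4.43,4.42,1.4,71.47,+,+
S27,1,4.34,4.39,0.6,69.67,+,+
S28,0,5.15,5.17,-0.5,71.45,+,+
S29,0,5.49,5.48,1.6,70.43,+,+
S30,0,5.93,5.91,1.1,69.71,++,++
S31,0,6.16,6.15,1.1,72.43,++,++
S32,1,6.36,7.63,1.9,71.98,++,+
S33,0,6.07,6.08,1.3,69.11,++,++
S34,1,6.61,5.56,-1.8,73.45,+++,+++
S35,0,5.07,5.06,-1.1,74.23,+,+
S36,0,4.74,4.75,1.2,71.26,+,+
S37,0,5.65,5.41,1.3,72.84,++,+
S38,0,6.92,6.94,1.1,71.04,+++,+++
S39,0,6.09,6.07,-0.3,70.09,++,++
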