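class,abbr,species_in_class,strain,chow_mean,chow_sem,hfd_mean,hfd_sem,n_down,n_up
Ceramide,CER,9,C57BL/6,0.07,0.01,0.07,0.01,0,0
Ceramide,CER,9,129X1,0.05,0.01,0.06,0.01,0,0
Ceramide,CER,9,BALB/c,0.07,0.01,0.07,0.01,0,0
Ceramide,CER,9,DBA/2,0.07,0.01,0.07,0.01,0,0
Ceramide,CER,9,FVB/N,0.05,0.01,0.06,0.01,0,0
Sphingomyelin,SM,27,C57BL/6,0.28,0.03,0.28,0.03,1,3
Sphingomyelin,SM,27,129X1,0.27,0.01,0.30,0.02,1,5
Sphingomyelin,SM,27,BALB/c,0.31,0.02,0.31,0.01,1,1
Sphingomyelin,SM,27,DBA/2,0.34,0.03,0.29,0.01,3,2
Sphingomyelin,SM,27,FVB/N,0.32,0.01,0.30,0.01,2,0
Diacylglycerol,DAG,14,C57BL/6,1.55,0.27,1.80,0.42,0,0
Diacylglycerol,DAG,14,129X1,1.91,0.24,1.72,0.13,0,0
Diacylglycerol,DAG,14,BALB/c,2.12,0.31,1.92,0.22,0,0
Diacylglycerol,DAG,14,DBA/2,2.07,0.35,1.88,0.15,0,0
Diacylglycerol,DAG,14,FVB/N,1.43,0.04,1.79,0.11,0,0
Triacylglycerol,TAG,32,C57BL/6,7.81,1.70,12.10,2.82,0,4
Triacylglycerol,TAG,32,129X1,12.64,1.72,31.61,1.78,0,13
Triacylglycerol,TAG,32,BALB/c,13.31,1.27,23.48,2.28,0,6
Triacylglycerol,TAG,32,DBA/2,17.57,2.04,45.16,6.08,0,12
Triacylglycerol,TAG,32,FVB/N,12.90,0.67,21.07,1.58,0,4
Cholesterolester,CE,9,C57BL/6,0.08,0.03,0.04,0.01,0,0
Cholesterolester,CE,9,129X1,0.04,0.01,0.14,0.02,0,3
Cholesterolester,CE,9,BALB/c,0.02,0.01,0.06,0.01,0,1
Cholesterolester,CE,9,DBA/2,0.07,0.03,0.05,0.01,0,0
Cholesterolester,CE,9,FVB/N,0.06,0.02,0.10,0.001,0,0
Phospholipids,PL,96,C57BL/6,14.75,1.49,14.12,0.35,15,15
Phospholipids,PL,96,129X1,12.64,0.59,13.96,0.41,6,18
Phospholipids,PL,96,BALB/c,14.94,1.23,14.75,0.28,15,12
Phospholipids,PL,96,DBA/2,15.97,0.63,15.46,0.49,15,11
Phospholipids,PL,96,FVB/N,13.02,0.35,13.73,0.35,7,15
Phosphatidyl choline,PC,35,C57BL/6,11.27,1.13,10.84,0.26,8,7
Phosphatidyl choline,PC,35,129X1,9.97,0.58,10.38,0.32,5,7
Phosphatidyl choline,PC,35,BALB/c,12.08,0.97,11.38,0.24,11,6
Phosphatidyl choline,PC,35,DBA/2,12.11,0.45,11.61,0.37,7,4
Phosphatidyl choline,PC,35,FVB/N,9.96,0.18,10.20,0.29,6,5
Alkyl Phosphatidyl choline,PC-O,13,C57BL/6,0.28,0.03,0.31,0.01,2,2
Alkyl Phosphatidyl choline,PC-O,13,129X1,0.26,0.01,0.31,0.02,0,2
Alkyl Phosphatidyl choline,PC-O,13,BALB/c,0.33,0.01,0.34,0.01,2,2
Alkyl Phosphatidyl choline,PC-O,13,DBA/2,0.40,0.02,0.37,0.01,2,2
Alkyl Phosphatidyl choline,PC-O,13,FVB/N,0.22,0.01,0.27,0.01,1,1
Phosphatidyl ethanolamine,PE,26,C57BL/6,3.15,0.34,2.93,0.13,4,6
Phosphatidyl ethanolamine,PE,26,129X1,2.39,0.08,3.26,0.12,1,5
Phosphatidyl ethanolamine,PE,26,BALB/c,2.55,0.27,3.02,0.07,2,3
Phosphatidyl ethanolamine,PE,26,DBA/2,3.51,0.30,3.46,0.09,4,3
Phosphatidyl ethanolamine,PE,26,FVB/N,2.74,0.16,3.16,0.17,0,6
Alkyl Phosphatidyl ethanolamine,PE-O,16,C57BL/6,0.53,0.09,0.48,0.03,1,0
Alkyl Phosphatidyl ethanolamine,PE-O,16,129X1,0.39,0.04,0.70,0.05,0,3
Alkyl Phosphatidyl ethanolamine,PE-O,16,BALB/c,0.34,0.08,0.51,0.03,0,0
Alkyl Phosphatidyl ethanolamine,PE-O,16,DBA/2,0.66,0.08,0.57,0.02,2,1
Alkyl Phosphatidyl ethanolamine,PE-O,16,FVB/N,0.47,0.05,0.57,0.01,0,2
Phosphatidyl serine,PS,6,C57BL/6,0.33,0.07,0.35,0.01,0,0
Phosphatidyl serine,PS,6,129X1,0.29,0.01,0.32,0.02,0,1
Phosphatidyl serine,PS,6,BALB/c,0.30,0.01,0.35,0.01,0,1
Phosphatidyl serine,PS,6,DBA/2,0.35,0.04,0.40,0.03,0,1
Phosphatidyl serine,PS,6,FVB/N,0.32,0.02,0.37,0.01,0,1
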