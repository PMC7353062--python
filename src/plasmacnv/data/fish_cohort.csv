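case_id,ratio,avg_gene_signals,avg_cen_signals,q5,q15
446894,2.3,6.3,2.8,0.8,0
525973,1.9,7.7,4.1,0.9,0.1
529014,3.4,7.2,2.1,0.9,0
531084,2.5,6.3,2.5,0.8,0
537264,1.1,7.5,7.1,0.9,0.1
542827,4.5,11.6,2.6,1.0,0.3
548602,6.7,16.2,2.4,1.0,0.6
550066,1.9,5.9,3.1,0.8,0
557513,5.5,10.8,2.0,1.0,0.3
562315,8.4,25.1,3.0,1.0,0.9
587002,3.4,15.6,4.6,1.0,0.7
594270,2.8,11.6,4.2,1.0,0.3
595763,2.5,10.5,4.2,1.0,0.1
599471,5.4,9.8,1.8,1.0,0.1
600575,6.2,12.8,2.0,1.0,0.4
615064,1.9,4.8,2.6,0.6,0
621823,5.6,12.7,2.2,1.0,0.4
623854,4.6,7.8,1.7,0.7,0.1
630510,4.2,5.3,1.3,0.6,0
631774,1.9,5.1,2.7,0.6,0
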