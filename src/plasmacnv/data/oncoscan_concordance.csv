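case_id,oncoscan_status,oncoscan_copy_number,fish_status,fish_avg_gene_signals
529014,gain,3,amplified,7.2
531084,gain,4,amplified,6.3
542827,no_gain,2,amplified,11.6
548602,gain,5,amplified,16.2
557513,gain,8,amplified,10.8
562315,gain,24,amplified,25.1
587002,gain,5,amplified,15.6
594270,gain,16,amplified,11.6
600575,gain,7,amplified,12.8
623854,gain,15,amplified,7.8
630510,gain,5,amplified,5.3
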