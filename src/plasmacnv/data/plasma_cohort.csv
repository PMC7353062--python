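case_id,fish_status,oncoscan_status,gw_z,itf_percent,plasma_call
529014,amplified,gain,1.6,0.35,-
529773,balanced,,10.6,38,-
530077,balanced,,1.7,1.15,-
531084,amplified,gain,4.5,4.6,+
542827,amplified,no_gain,1.6,1.2,-
544065,balanced,,31.5,47,-
548696,balanced,,2.9,19,-
557513,amplified,gain,1.7,3.9,-
562315,amplified,gain,1.9,0.86,+
568895,balanced,,1.1,0.6,-
578098,balanced,,2,0.73,-
587002,amplified,gain,3.8,9.5,+
590243,balanced,,1.9,5.9,-
594270,amplified,gain,2.4,5.5,+
600575,amplified,gain,3.6,4.6,+
612988,balanced,,1.8,0.7,-
615064,low_amplified,,19.7,35,+
615972,balanced,,3.1,7.77,-
623854,amplified,gain,11.1,16,+
628696,balanced,,1.6,2.2,-
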