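species,sex,n_ommatidia,interommatidial_angle_deg,ommatidial_diameter_um,eye_radius_um,ct_dv_diameter_um,ct_ap_diameter_um,stereo_dv_diameter_um,stereo_dv_sem_um,stereo_ap_diameter_um,stereo_ap_sem_um,clear_zone_um
CP,male,2150,3.50,20,290,660,610,632,5,614,5,85
CP,female,1900,3.80,20,290,600,570,648,8,604,10,85
LB,male,1300,4.30,20,230,480,430,492,3,467,4,60
LB,female,1190,4.40,20,220,470,440,482,4,461,4,60
GM,male,870,4.70,15,190,420,380,423,7,389,3,36
GM,female,930,5.00,15,180,430,380,446,6,396,4,36
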