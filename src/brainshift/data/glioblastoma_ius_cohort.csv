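case_id,vol_pre_mri_cm3,vol_pre_us_cm3,vol_res_ius_cm3,vol_post_us_cm3,vol_post_mri_cm3,cog_offset_mm,hausdorff_mm,dice,us_quality,exclude_pre,exclude_pre_reason,exclude_post,exclude_post_reason
1,2.4,1.8,,0,0,1.11,5.39,0.72,excellent,false,,false,
2,57.8,57.7,0.2,0,0,4.08,10.20,0.80,excellent,false,,false,
3,47.9,50.4,,17.0,18.1,3.75,15.39,0.80,excellent,false,,false,
4,5.5,4.84,,2.0,1.7,3.35,30.41,0.75,excellent,false,,false,
5,16.1,15.9,,0.8,0.5,1.26,13.34,0.79,excellent,false,,false,
6,47.8,48.5,,0,0,2.06,6.48,0.86,good,false,,false,
7,18.8,18.4,,,,3.48,8.06,0.80,sufficient,false,,true,corrupted post-resectional ultrasound dataset
8,2.2,2.1,,,,7.31,9.54,0.36,good,false,,true,corrupted post-resectional ultrasound dataset
9,16.4,19.3,,0,3.0,3.19,8.60,0.54,excellent,false,,true,same patient as case 10 operated twice within 5 days
10,3.0,3.1,,0,0,7.87,13.89,0.51,excellent,false,,false,
11,2.4,2.5,,0,0,1.23,3.00,0.87,excellent,false,,false,
12,95.1,90.5,,0,0,3.29,8.66,0.86,good,false,,false,
13,15.7,16.7,,0,0,6.07,15.81,0.66,excellent,false,,false,
14,26.0,24.8,,0,0,1.37,9.43,0.77,sufficient,false,,false,
15,43.9,,,2.1,3.2,,,,poor,true,poor pre-resectional ultrasound image quality,false,
16,22.1,23.1,,0.6,0.9,2.40,12.57,0.84,good,false,,false,
17,6.0,5.6,1.0,0,0,1.21,4.12,0.89,excellent,false,,false,
18,16.2,16.5,,0,0,0.25,19.82,0.92,excellent,false,,false,
19,30.8,28.7,,0,0,3.36,8.06,0.80,excellent,false,,false,
20,19.7,21.8,3.0,0,0,5.96,31.16,0.64,sufficient,false,,false,
21,9.2,10.5,,0.7,0.1,13.14,14.04,0.29,sufficient,false,,false,
22,11.0,11.2,,2.2,1.7,0.61,4.47,0.91,good,false,,false,
23,50.8,62.1,2.8,0,0,3.78,11.18,0.79,good,false,,false,
24,9.6,13.2,,2.7,3.3,5.37,14.73,0.69,sufficient,false,,false,
25,0.5,0.3,,0,0,7.64,9.00,0.01,excellent,false,,false,
26,4.1,4.3,,0,0,4.11,13.38,0.50,excellent,false,,false,
27,51.8,47.1,,3.5,2.7,10.63,24.54,0.65,excellent,false,,false,
28,40.8,35.8,,0,0,1.75,13.04,0.86,good,false,,false,
29,13.0,10.1,,0,0,1.96,8.06,0.82,excellent,false,,false,
30,49.7,38.4,,3.7,2.7,3.04,16.79,0.65,good,false,,false,
31,33.6,34.5,,0,0,1.19,7.07,0.93,excellent,false,,false,
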