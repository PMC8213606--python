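ta_c,rh_pct,clothing,pwc_mean,pwc_sd,singleton
25,20,low,91,4,0
25,50,low,96,1,0
25,80,low,89,11,0
30,20,low,88,11,0
30,50,low,84,10,0
30,80,low,77,11,0
35,20,low,84,9,0
35,35,low,70,11,0
35,50,low,73,10,0
35,80,low,44,12,0
40,20,low,73,10,0
40,40,low,70,5,0
40,50,low,52,14,0
40,60,low,36,4,0
40,70,low,34,13,0
40,80,low,23,10,0
45,20,low,62,9,0
45,40,low,37,15,0
45,50,low,28,9,0
45,60,low,22,8,0
50,30,low,33,5,0
50,40,low,24,3,0
25,20,high,88,3,0
25,80,high,81,12,0
30,20,high,87,7,0
30,50,high,81,11,0
30,80,high,75,13,0
35,20,high,82,15,0
35,50,high,68,14,0
35,80,high,42,11,0
40,20,high,71,14,0
40,40,high,68,13,0
40,50,high,50,14,0
40,60,high,48,16,0
40,70,high,35,11,0
40,80,high,30,11,0
45,20,high,68,15,0
45,40,high,45,13,0
45,50,high,31,10,0
45,60,high,25,3,0
50,30,high,29,,1
50,40,high,28,,1
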