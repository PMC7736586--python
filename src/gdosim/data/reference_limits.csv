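# Published reference MDA/MDD values for indirect Gd-148 whole-body
# assessment after a tungsten spallation-target release (1-y and 5-y
# operated target scenarios), used by the deviation report.
time_d,op_years,tracer,line_keV,mda_ing_bq,mdd_ing_usv,mda_inh_bq,mdd_inh_usv
1,1,Gd-146,115.4,0.0634,0.0035,0.362,4.57
1,1,Gd-146,154.6,0.121,0.0067,0.689,8.68
1,5,Gd-146,115.4,0.306,0.0168,1.74,22.0
1,5,Gd-146,154.6,0.582,0.032,3.31,41.8
7,1,Gd-146,115.4,0.069,0.0178,1.68,21.7
7,1,Gd-146,154.6,0.132,0.0339,3.19,40.2
7,5,Gd-146,115.4,0.334,0.0857,8.08,102
7,5,Gd-146,154.6,0.635,0.163,15.4,194
30,1,Gd-146,115.4,0.096,0.107,2.73,34.4
30,1,Gd-146,154.6,0.183,0.203,5.19,65.4
30,5,Gd-146,115.4,0.464,0.513,13.18,165
30,5,Gd-146,154.6,0.882,0.975,25.0,315
365,1,Gd-146,115.4,11.6,168,481,6060
365,1,Gd-146,154.6,22.2,320,915,11500
365,5,Gd-146,115.4,56.0,808,2310,29100
365,5,Gd-146,154.6,107,1540,4400,55400
1,1,Gd-153,97.4,0.443,0.0243,2.52,31.8
1,1,Gd-153,103.2,0.585,0.0328,3.33,42.0
1,5,Gd-153,97.4,1.40,0.0767,7.93,100
1,5,Gd-153,103.2,1.85,0.102,10.5,132
7,1,Gd-153,97.4,0.450,0.116,10.9,137
7,1,Gd-153,103.2,0.596,0.153,14.4,182
7,5,Gd-153,97.4,1.42,0.365,34.3,432
7,5,Gd-153,103.2,1.88,0.482,45.4,572
30,1,Gd-153,97.4,0.481,0.532,13.6,171
30,1,Gd-153,103.2,0.639,0.704,18.0,226
30,5,Gd-153,97.4,1.52,1.68,42.7,539
30,5,Gd-153,103.2,2.01,2.22,56.6,713
365,1,Gd-153,97.4,1.27,18.4,50.9,642
365,1,Gd-153,103.2,1.68,24.3,67.4,849
365,5,Gd-153,97.4,4.01,57.9,160,2020
365,5,Gd-153,103.2,5.31,76.6,212,2670
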