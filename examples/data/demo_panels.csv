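sample_id,ph,ca,mg,na,k,nh4,cl,so4,po4,oxalate,citrate,urate,pyrophosphate,co2_total
dog-A,6.45,2.1,1.8,85,62,28,110,14,24,0.32,1.6,1.0,0.03,4.0
dog-B,7.20,3.4,2.6,70,55,35,95,18,30,0.41,0.9,0.8,0.02,6.5
cat-A,6.10,1.5,3.8,130,95,55,160,26,42,0.36,1.1,1.3,0.04,3.2
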