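complex,dg_exp,dg_pred,abs_diff,kd_exp_nM,kd_pred_nM,exp_range,pred_range,set
mWnt3a–mFzd2,-10.64,-10.87,0.23,15.7,10.7,+++,+++,training
mWnt3a–mFzd4,-11.27,-11.49,0.22,5.4,3.7,++++,++++,training
mWnt3a–mFzd5,-11.60,-11.66,0.06,3.1,2.8,++++,++++,training
mWnt3a–mFzd7,-11.28,-11.03,0.25,5.3,8.1,++++,++++,training
mWnt3a–mFzd8,-12.03,-11.66,0.37,1.5,2.8,++++,++++,training
mWnt5–mFzd2,-10.38,-10.00,0.38,24.4,46.3,+++,++,training
mWnt5–mFzd4,-10.38,-10.75,0.37,24.4,13.0,+++,+++,training
mWnt5–mFzd5,-11.31,-11.20,0.11,5.1,6.1,++++,++++,training
mWnt5–mFzd7,-10.05,-10.61,0.56,42.6,16.5,++,+++,training
mWnt5–mFzd8,-11.45,-11.17,0.28,4.0,6.4,++++,++++,training
mWnt5b–mFzd2,-9.60,-9.62,0.02,91.0,87.9,++,++,training
mWnt5b–mFzd4,-9.95,-10.61,0.66,50.4,16.5,++,+++,training
mWnt5b–mFzd5,-10.44,-10.32,0.12,22.0,27.0,+++,+++,training
mWnt5b–mFzd7,-9.65,-9.55,0.10,83.7,99.0,++,++,training
mWnt5b–mFzd8,-11.04,-10.59,0.45,8.0,17.1,++++,+++,training
mWnt3a–mFzd1,-10.66,-10.30,0.36,15.2,27.9,+++,+++,test
mWnt4–mFzd2,-9.53,-9.47,0.06,102.5,113.3,+,+,test
mWnt4–mFzd4,-10.04,-10.00,0.04,43.3,46.3,++,++,test
mWnt4–mFzd5,-10.68,-10.20,0.38,14.7,33.0,+++,+++,test
mWnt4–mFzd7,-9.58,-9.72,0.14,94.2,74.3,++,++,test
mWnt4–mFzd8,-10.95,-11.44,0.49,9.3,4.1,++++,++++,test
mWnt5–mFzd1,-10.33,-10.87,0.44,26.5,10.7,+++,+++,test
mWnt5b–mFzd1,-9.60,-9.92,0.32,91.0,53.0,++,++,test
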