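id,score,med_obs,units,source
YF23,-8.520,0.625,umol/cm2,table4
YF24,-8.491,0.039,umol/cm2,table4
C40,-8.367,25.0,umol/cm2,table4
YF19,-8.363,0.065,umol/cm2,table4
5i',-8.334,20.5,umol/cm2,table4
5w,-8.273,5.16,umol/cm2,table4
YF25,-8.210,0.078,umol/cm2,table4
C41,-7.640,25.0,umol/cm2,table4
5h,-7.508,0.102,umol/cm2,table4
5l',-7.394,0.14,umol/cm2,table4
YF21,-7.226,0.208,umol/cm2,table4
5d',-7.222,20.25,umol/cm2,table4
5m,-7.203,0.172,umol/cm2,table4
5b',-7.019,10.75,umol/cm2,table4
5f,-6.944,0.625,umol/cm2,table4
X1,-9.109,,ug/cm2,table5
X2,-8.166,,ug/cm2,table5
X4,-8.715,0.078,ug/cm2,table5
X5,-8.643,0.156,ug/cm2,table5
X7,-7.797,0.417,ug/cm2,table5
X9,-8.106,,ug/cm2,table5
X11,-7.910,,ug/cm2,table5
X12,-7.757,,ug/cm2,table5
X14,-6.684,,ug/cm2,table5
X16,-8.405,0.261,ug/cm2,table5
X20,-7.666,,ug/cm2,table5
X21,-7.529,,ug/cm2,table5
X23,-6.832,0.039,ug/cm2,table5
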