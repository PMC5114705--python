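species,variables,log_likelihood,aicc,delta_aicc,weight,auc_mean
Kinosternon baurii,BIO1+BIO8+BIO16+BIO18,-2137.721,4342.748,0,1,0.986
Kinosternon flavescens,BIO8+BIO9+BIO10+BIO15,-7157.165,14428.017,0,1,0.941
Kinosternon hirtipes,BIO6+BIO15+BIO17+ELEV,-1320.249,2719.672,0,0.423,0.983
Kinosternon hirtipes,BIO4+BIO15+BIO17+ELEV,-1320.749,2720.673,1.001,0.256,0.983
Kinosternon hirtipes,BIO6+BIO15+BIO17,-1335.399,2721.515,1.842,0.168,0.981
Kinosternon hirtipes,BIO4+BIO15+ELEV,-1334.259,2722.157,2.484,0.122,0.982
Kinosternon sonoriense,BIO2+BIO4+BIO8+BIO14,-1668.1444,3420.533,0,0.590,0.976
Kinosternon sonoriense,BIO1+BIO2+BIO4+BIO8+BIO14,-1660.954,3423.026,2.493,0.170,0.975
Kinosternon sonoriense,BIO1+BIO2+BIO4+BIO8+BIO17,-1642.117,3423.790,3.257,0.116,0.976
Kinosternon sonoriense,BIO3+BIO5+BIO8+BIO17,-1673.281,3424.434,3.901,0.084,0.973
Kinosternon subrubrum,BIO6+BIO10+BIO12+ELEV,-15855.610,31797.221,0,1,0.915
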