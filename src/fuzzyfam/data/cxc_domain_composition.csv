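sequence_id,group,acidic,basic,hydrophobic
AT3G04850,I,3.24,23.92,19.57
AT3G22760,I,4.35,23.92,28.26
AT3G22780,I,6.53,22.83,23.92
AT4G14770,I,6.34,22.77,25.07
LOC_Os03g43730,I,7.61,23.92,19.57
LOC_Os04g09560,I,3.26,9.79,13.05
LOC_Os05g43380,I,5.44,20.66,22.83
LOC_Os05g51040,I,4.35,18.48,26.09
LOC_Os07g07974,I,5.44,23.92,19.57
LOC_Os12g41230,I,4.35,20.66,20.66
GRMZM2G015097,I,6.52,21.74,19.57
GRMZM2G023936,I,2.18,8.70,9.79
GRMZM2G044182,I,4.35,21.74,19.57
GRMZM2G066986,I,2.17,25.00,20.65
GRMZM2G096600,I,7.11,20.04,23.30
GRMZM2G124285,I,6.52,21.74,18.48
GRMZM2G157405,I,5.44,23.92,21.74
GRMZM2G173198,I,4.35,9.79,7.61
GRMZM2G060170,I,7.61,19.57,19.57
GRMZM2G153754,I,5.44,23.92,21.74
AT2G20110,II,9.88,18.65,20.90
AT3G16160,II,11.02,22.01,23.02
AT4G29000,II,9.88,18.65,22.22
AT5G25790,II,8.77,20.87,18.48
LOC_Os01g55580,II,7.66,20.87,20.90
LOC_Os02g17460,II,9.88,25.29,19.81
LOC_Os06g22670,II,7.53,19.10,24.57
LOC_Os08g28214,II,5.48,24.13,18.70
LOC_Os12g41210,II,6.52,22.83,18.48
GRMZM2G045880,II,9.91,20.85,19.79
GRMZM2G059678,II,9.88,17.54,17.57
GRMZM2G086570,II,6.60,23.02,18.72
GRMZM2G092259,II,9.88,18.65,16.45
GRMZM2G098684,II,6.60,23.02,18.72
GRMZM2G104246,II,9.88,18.65,16.45
GRMZM2G109514,II,9.89,17.54,17.57
GRMZM2G156574,II,9.88,17.54,17.57
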