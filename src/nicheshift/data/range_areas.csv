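species,scenario,area_km2,pct_change,common_km2,pct_retained
Kinosternon baurii,current,97886.39,,,
Kinosternon baurii,2050-rcp2.6,18747.20,-80.85,18040.93,18.43
Kinosternon baurii,2050-rcp4.5,15146.41,-84.53,14895.92,15.22
Kinosternon baurii,2050-rcp6.0,6832.12,-93.02,6284.87,6.42
Kinosternon baurii,2050-rcp8.5,5330.04,-94.55,5125.59,5.24
Kinosternon baurii,2070-rcp2.6,40147.31,-58.99,36337.27,37.12
Kinosternon baurii,2070-rcp4.5,6190.85,-93.68,5999.67,6.13
Kinosternon baurii,2070-rcp6.0,0.00,-100.00,0,0.00
Kinosternon baurii,2070-rcp8.5,0.00,-100.00,0,0.00
Kinosternon flavescens,current,761894.36,,,
Kinosternon flavescens,2050-rcp2.6,1263789.95,65.87,654059.81,85.85
Kinosternon flavescens,2050-rcp4.5,1483646.97,94.73,648173.86,85.07
Kinosternon flavescens,2050-rcp6.0,1106486.87,45.23,613075.46,80.47
Kinosternon flavescens,2050-rcp8.5,1639647.95,115.21,630273.02,82.72
Kinosternon flavescens,2070-rcp2.6,1255586.38,64.80,651539.39,85.52
Kinosternon flavescens,2070-rcp4.5,1655794.48,117.33,644113.09,84.54
Kinosternon flavescens,2070-rcp6.0,1592850.61,109.06,635724.28,83.44
Kinosternon flavescens,2070-rcp8.5,2125826.78,179.02,621984.94,81.64
Kinosternon hirtipes,current,274569.84,,,
Kinosternon hirtipes,2050-rcp2.6,249224.98,-9.23,191989.18,69.92
Kinosternon hirtipes,2050-rcp4.5,249655.50,-9.07,183512.06,66.84
Kinosternon hirtipes,2050-rcp6.0,240300.25,-12.48,183320.15,66.77
Kinosternon hirtipes,2050-rcp8.5,217223.11,-20.89,150824.54,54.93
Kinosternon hirtipes,2070-rcp2.6,230384.60,-16.09,180126.63,65.60
Kinosternon hirtipes,2070-rcp4.5,219504.46,-20.06,158869.99,57.86
Kinosternon hirtipes,2070-rcp6.0,216845.02,-21.02,150506.39,54.82
Kinosternon hirtipes,2070-rcp8.5,171578.42,-37.51,106540.69,38.80
Kinosternon sonoriense,current,360220.43,,,
Kinosternon sonoriense,2050-rcp2.6,342039.32,-5.05,278373.89,77.28
Kinosternon sonoriense,2050-rcp4.5,332967.41,-7.57,241259.57,66.98
Kinosternon sonoriense,2050-rcp6.0,334081.94,-7.26,255422.43,70.91
Kinosternon sonoriense,2050-rcp8.5,378945.04,5.20,274922.19,76.32
Kinosternon sonoriense,2070-rcp2.6,349501.44,-2.98,278584.05,77.34
Kinosternon sonoriense,2070-rcp4.5,347657.03,-3.49,253839.98,70.47
Kinosternon sonoriense,2070-rcp6.0,383026.73,6.33,264269.59,73.36
Kinosternon sonoriense,2070-rcp8.5,397782.78,10.43,249467.33,69.25
Kinosternon subrubrum,current,685299.22,,,
Kinosternon subrubrum,2050-rcp2.6,753846.01,10.00,624276.89,91.10
Kinosternon subrubrum,2050-rcp4.5,809897.41,18.18,628949.00,91.78
Kinosternon subrubrum,2050-rcp6.0,761742.99,11.15,628084.40,91.65
Kinosternon subrubrum,2050-rcp8.5,785394.02,14.61,600940.37,87.69
Kinosternon subrubrum,2070-rcp2.6,733998.32,7.11,604523.99,88.21
Kinosternon subrubrum,2070-rcp4.5,815701.39,19.03,623163.00,90.93
Kinosternon subrubrum,2070-rcp6.0,803669.48,17.27,613225.66,89.48
Kinosternon subrubrum,2070-rcp8.5,761113.95,11.06,564144.67,82.32
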