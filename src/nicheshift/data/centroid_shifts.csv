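species,scenario,distance_km,direction,rate_km_per_decade
Kinosternon baurii,2050-rcp2.6,237,ENE,59
Kinosternon baurii,2050-rcp4.5,247,ENE,62
Kinosternon baurii,2050-rcp6.0,224,ENE,56
Kinosternon baurii,2050-rcp8.5,216,NE,54
Kinosternon baurii,2070-rcp2.6,231,NE,39
Kinosternon baurii,2070-rcp4.5,267,NE,44
Kinosternon baurii,2070-rcp6.0,239,NE,40
Kinosternon baurii,2070-rcp8.5,311,NE,52
Kinosternon flavescens,2050-rcp2.6,154,NE,39
Kinosternon flavescens,2050-rcp4.5,185,NE,46
Kinosternon flavescens,2050-rcp6.0,149,NE,37
Kinosternon flavescens,2050-rcp8.5,217,NNE,54
Kinosternon flavescens,2070-rcp2.6,154,NE,26
Kinosternon flavescens,2070-rcp4.5,231,NNE,38
Kinosternon flavescens,2070-rcp6.0,211,NNE,35
Kinosternon flavescens,2070-rcp8.5,341,NNE,57
Kinosternon hirtipes,2050-rcp2.6,63,NNW,16
Kinosternon hirtipes,2050-rcp4.5,81,NNW,20
Kinosternon hirtipes,2050-rcp6.0,74,NNW,18
Kinosternon hirtipes,2050-rcp8.5,108,NNW,27
Kinosternon hirtipes,2070-rcp2.6,55,NNW,9
Kinosternon hirtipes,2070-rcp4.5,105,NNW,17
Kinosternon hirtipes,2070-rcp6.0,83,NNW,14
Kinosternon hirtipes,2070-rcp8.5,136,NNW,23
Kinosternon sonoriense,2050-rcp2.6,8,W,2
Kinosternon sonoriense,2050-rcp4.5,23,S,6
Kinosternon sonoriense,2050-rcp6.0,34,SSE,8
Kinosternon sonoriense,2050-rcp8.5,17,SSE,4
Kinosternon sonoriense,2070-rcp2.6,11,S,2
Kinosternon sonoriense,2070-rcp4.5,19,S,3
Kinosternon sonoriense,2070-rcp6.0,21,S,4
Kinosternon sonoriense,2070-rcp8.5,23,SE,5
Kinosternon subrubrum,2050-rcp2.6,179,NNE,45
Kinosternon subrubrum,2050-rcp4.5,240,NNE,60
Kinosternon subrubrum,2050-rcp6.0,201,NNE,50
Kinosternon subrubrum,2050-rcp8.5,302,NNE,75
Kinosternon subrubrum,2070-rcp2.6,203,NNE,34
Kinosternon subrubrum,2070-rcp4.5,294,NNE,49
Kinosternon subrubrum,2070-rcp6.0,274,NNE,46
Kinosternon subrubrum,2070-rcp8.5,421,NNE,70
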