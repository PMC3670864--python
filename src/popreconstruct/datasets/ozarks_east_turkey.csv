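year,spring_harvest_juvenile,spring_harvest_adult,effort,effort_se,poult_hen_ratio,archer_index,spring_npr_juvenile,spring_npr_adult,fall_harvest_juvenile,fall_harvest_adult,rt_at_risk_juvenile,rt_harvested_juvenile,rt_at_risk_adult,rt_harvested_adult
1995,,,,,1.4,,,,,,,,,
1996,626,2703,6.9298,0.519,2.1,364,53,279,253,208,23,0,32,7
1997,596,1764,6.5852,0.442,1.8,188,60,174,114,94,12,2,46,13
1998,847,2855,6.5854,0.384,3.1,541,102,255,414,115,4,2,16,8
1999,1833,1716,7.1273,0.401,2.1,263,185,197,149,154,30,3,9,5
2000,767,4237,6.2601,0.34,2.8,365,101,406,340,133,8,2,33,17
2001,1580,2781,7.6457,0.448,2.6,565,289,458,352,288,,,,
2002,1388,3399,7.4921,0.462,1.3,359,286,591,201,236,,,,
2003,884,4287,6.935,0.409,1.7,384,201,807,204,201,,,,
2004,1046,3289,8.1414,0.984,2.0,521,195,600,292,295,,,,
2005,887,2877,8.2299,0.527,1.5,224,345,799,215,198,,,,
2006,829,3033,6.7334,0.431,2.2,294,311,823,349,232,,,,
2007,904,2077,8.0017,0.483,1.2,342,349,691,381,504,,,,
2008,501,3011,6.0511,0.381,1.3,207,244,899,162,146,,,,
2009,791,2429,6.7649,0.394,1.6,326,268,692,309,276,,,,
2010,840,2233,6.2808,0.344,1.1,161,337,762,176,164,,,,
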