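region,name,actual_2016,rsvi_2016,rsvi_2017,ratio,predicted_2017,actual_2017,pct_error
AK,Alaska,3008,67,70,1.045,3143,3067,2.5
AL,Alabama,27550,89,86,0.966,26621,27409,-2.9
AR,Arkansas,17410,80,85,1.063,18498,17722,4.4
AZ,Arizona,32810,85,84,0.988,32424,33909,-4.4
CA,California,172652,78,82,1.051,181506,175579,3.4
CO,Colorado,23852,80,77,0.963,22958,24638,-6.8
CT,Connecticut,21572,95,94,0.989,21345,21731,-1.8
DC,District of Columbia,2745,78,83,1.064,2921,2966,-1.5
DE,Delaware,6101,88,85,0.966,5893,5804,1.5
FL,Florida,135354,82,81,0.988,133703,134514,-0.6
GA,Georgia,52992,87,84,0.966,51165,53729,-4.8
HI,Hawaii,7502,68,78,1.147,8605,7677,12.1
IA,Iowa,18850,81,83,1.025,19315,19188,0.7
ID,Idaho,8670,75,82,1.093,9479,8996,5.4
IL,Illinois,70577,81,84,1.037,73191,71140,2.9
IN,Indiana,36765,90,86,0.956,35131,37614,-6.6
KY,Kentucky,27720,95,92,0.968,26845,28219,-4.9
LA,Louisiana,25878,82,79,0.963,24931,26477,-5.8
MA,Massachusetts,39427,90,90,1.000,39427,39623,-0.5
MD,Maryland,31916,92,90,0.978,31222,32949,-5.2
ME,Maine,9061,87,94,1.080,9790,9228,6.1
MI,Michigan,56973,86,85,0.988,56311,56181,0.2
MN,Minnesota,30505,84,84,1.000,30505,32369,-5.8
MO,Missouri,33869,86,93,1.081,36626,35359,3.6
MS,Mississippi,16833,86,86,1.000,16833,17067,-1.4
MT,Montana,6430,73,78,1.068,6870,6647,3.4
NC,North Carolina,57398,83,83,1.000,57398,59104,-2.9
ND,North Dakota,3871,77,78,1.013,3921,3987,-1.6
NE,Nebraska,10337,86,87,1.012,10457,10578,-1.1
NH,New Hampshire,8692,88,86,0.977,8494,8774,-3.2
NJ,New Jersey,52962,91,87,0.956,50634,54033,-6.3
NM,New Mexico,9700,81,78,0.963,9341,9745,-4.1
NV,Nevada,13616,77,79,1.026,13970,14621,-4.5
NY,New York,115030,90,98,1.089,125255,117153,6.9
OH,Ohio,67791,91,86,0.945,64066,69367,-7.6
OK,Oklahoma,20499,81,84,1.037,21258,20431,4.0
OR,Oregon,22118,77,76,0.987,21831,23004,-5.1
PA,Pennsylvania,81244,94,99,1.053,85565,81018,5.6
RI,Rhode Island,6343,87,85,0.977,6197,6442,-3.8
SC,South Carolina,28230,85,88,1.035,29226,28439,2.8
SD,South Dakota,4811,90,88,0.978,4704,4865,-3.3
TN,Tennessee,37864,86,90,1.047,39625,39350,0.7
TX,Texas,114969,76,75,0.987,113456,119174,-4.8
UT,Utah,10724,73,75,1.027,11018,11168,-1.3
VA,Virginia,41108,85,81,0.953,39174,41366,-5.3
VT,Vermont,3829,83,81,0.976,3737,4034,-7.4
WA,Washington,38132,72,75,1.042,39721,38448,3.3
WI,Wisconsin,33979,85,84,0.988,33579,34305,-2.1
WV,West Virginia,12032,100,100,1.000,12032,12492,-3.7
WY,Wyoming,2802,68,72,1.059,2967,2891,2.6
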