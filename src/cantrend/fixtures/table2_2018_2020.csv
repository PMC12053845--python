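region,name,year,predicted,actual,pct_error
AK,Alaska,2018,3067,3128,-2.0
AK,Alaska,2019,3128,3307,-5.4
AK,Alaska,2020,3165,3110,1.8
AL,Alabama,2018,30915,27463,12.6
AL,Alabama,2019,26331,27971,-5.9
AL,Alabama,2020,26166,25348,3.2
AR,Arkansas,2018,18139,18505,-2.0
AR,Arkansas,2019,16378,18701,-12.4
AR,Arkansas,2020,19187,15482,23.9
AZ,Arizona,2018,34313,34797,-1.4
AZ,Arizona,2019,35206,35159,0.1
AZ,Arizona,2020,33524,32171,4.2
CA,California,2018,162732,176082,-7.6
CA,California,2019,176082,182033,-3.3
CA,California,2020,179638,163739,9.7
CO,Colorado,2018,23038,25135,-8.3
CO,Colorado,2019,25484,26180,-2.7
CO,Colorado,2020,26897,24212,11.1
CT,Connecticut,2018,21269,21471,-0.9
CT,Connecticut,2019,21004,21712,-3.3
CT,Connecticut,2020,20747,19861,4.5
DC,District of Columbia,2018,2823,2907,-2.9
DC,District of Columbia,2019,2907,2905,0.1
DC,District of Columbia,2020,2648,2585,2.4
DE,Delaware,2018,5941,6067,-2.1
DE,Delaware,2019,6206,6306,-1.6
DE,Delaware,2020,5810,5535,5.0
FL,Florida,2018,144478,140026,3.2
FL,Florida,2019,138417,139607,-0.9
FL,Florida,2020,133114,130258,2.2
GA,Georgia,2018,53729,55038,-2.4
GA,Georgia,2019,57659,56527,2.0
GA,Georgia,2020,51388,53486,-3.9
HI,Hawaii,2018,7283,7651,-4.8
HI,Hawaii,2019,7754,7819,-0.8
HI,Hawaii,2020,7923,7285,8.8
IA,Iowa,2018,18494,19443,-4.9
IA,Iowa,2019,20172,20125,0.2
IA,Iowa,2020,18913,18381,2.9
ID,Idaho,2018,8557,9088,-5.8
ID,Idaho,2019,8855,9648,-8.2
ID,Idaho,2020,9394,9208,2.0
IL,Illinois,2018,73681,71351,3.3
IL,Illinois,2019,68891,72336,-4.8
IL,Illinois,2020,68030,65398,4.0
IN,Indiana,2018,39363,37021,6.3
IN,Indiana,2019,37021,35833,3.3
IN,Indiana,2020,33046,28075,17.7
KY,Kentucky,2018,26685,28475,-6.3
KY,Kentucky,2019,29784,28899,3.1
KY,Kentucky,2020,27629,26240,5.3
LA,Louisiana,2018,27818,27404,1.5
LA,Louisiana,2019,26413,28003,-5.7
LA,Louisiana,2020,26253,24693,6.3
MA,Massachusetts,2018,38742,38408,0.9
MA,Massachusetts,2019,40154,40842,-1.7
MA,Massachusetts,2020,37291,34966,6.6
MD,Maryland,2018,31119,33335,-6.6
MD,Maryland,2019,33727,34998,-3.6
MD,Maryland,2020,34591,30603,13.0
ME,Maine,2018,9228,9282,-0.6
ME,Maine,2019,9381,9741,-3.7
ME,Maine,2020,8511,9151,-7.0
MI,Michigan,2018,58825,57003,3.2
MI,Michigan,2019,54441,57490,-5.3
MI,Michigan,2020,53432,51987,2.8
MN,Minnesota,2018,30057,32812,-8.4
MN,Minnesota,2019,35336,33600,5.2
MN,Minnesota,2020,34400,30507,12.8
MO,Missouri,2018,33078,34772,-4.9
MO,Missouri,2019,37170,35235,5.5
MO,Missouri,2020,32583,33694,-3.3
MS,Mississippi,2018,18456,17407,6.0
MS,Mississippi,2019,17033,17456,-2.4
MS,Mississippi,2020,14387,15145,-5.0
MT,Montana,2018,6817,6624,2.9
MT,Montana,2019,6541,6560,-0.3
MT,Montana,2020,5896,6045,-2.5
NC,North Carolina,2018,58392,60057,-2.8
NC,North Carolina,2019,62987,62277,1.1
NC,North Carolina,2020,60829,57243,6.3
ND,North Dakota,2018,4038,3934,2.6
ND,North Dakota,2019,3934,4024,-2.2
ND,North Dakota,2020,3973,3843,3.4
NE,Nebraska,2018,10456,10902,-4.1
NE,Nebraska,2019,10775,10773,0.0
NE,Nebraska,2020,10773,9281,16.1
NH,New Hampshire,2018,8876,8928,-0.6
NH,New Hampshire,2019,9133,9266,-1.4
NH,New Hampshire,2020,8537,8177,4.4
NJ,New Jersey,2018,52791,54430,-3.0
NJ,New Jersey,2019,53149,55269,-3.8
NJ,New Jersey,2020,54603,50347,8.5
NM,New Mexico,2018,9245,9740,-5.1
NM,New Mexico,2019,10793,10143,6.4
NM,New Mexico,2020,9525,9031,5.5
NV,Nevada,2018,14621,13630,7.3
NV,Nevada,2019,13630,13077,4.2
NV,Nevada,2020,13077,14149,-7.6
NY,New York,2018,117153,116333,0.7
NY,New York,2019,118707,120228,-1.3
NY,New York,2020,120228,105600,13.9
OH,Ohio,2018,70174,70851,-1.0
OH,Ohio,2019,74109,71897,3.1
OH,Ohio,2020,62416,65151,-4.2
OK,Oklahoma,2018,20188,21037,-4.0
OK,Oklahoma,2019,21797,21527,1.3
OK,Oklahoma,2020,20776,19782,5.0
OR,Oregon,2018,24517,22632,8.3
OR,Oregon,2019,21794,23745,-8.2
OR,Oregon,2020,21614,20141,7.3
PA,Pennsylvania,2018,73653,80903,-9.0
PA,Pennsylvania,2019,83600,82588,1.2
PA,Pennsylvania,2020,77260,72403,6.7
RI,Rhode Island,2018,6669,6561,1.7
RI,Rhode Island,2019,6561,6747,-2.8
RI,Rhode Island,2020,6210,5552,11.9
SC,South Carolina,2018,27469,28610,-4.0
SC,South Carolina,2019,30630,28875,6.1
SC,South Carolina,2020,25385,27362,-7.2
SD,South Dakota,2018,4533,4958,-8.6
SD,South Dakota,2019,4898,5150,-4.9
SD,South Dakota,2020,4451,4738,-6.1
TN,Tennessee,2018,38476,38993,-1.3
TN,Tennessee,2019,43424,39287,10.5
TN,Tennessee,2020,33675,36396,-7.5
TX,Texas,2018,122352,124867,-2.0
TX,Texas,2019,128110,127456,0.5
TX,Texas,2020,125843,116875,7.7
UT,Utah,2018,10572,11748,-10.0
UT,Utah,2019,11913,12002,-0.7
UT,Utah,2020,11502,11602,-0.9
VA,Virginia,2018,42387,41537,2.0
VA,Virginia,2019,42037,43797,-4.0
VA,Virginia,2020,42754,39599,8.0
VT,Vermont,2018,3934,4039,-2.6
VT,Vermont,2019,3937,4073,-3.3
VT,Vermont,2020,3967,3710,6.9
WA,Washington,2018,37423,39120,-4.3
WA,Washington,2019,42871,39859,7.6
WA,Washington,2020,35873,36018,-0.4
WI,Wisconsin,2018,33488,34615,-3.3
WI,Wisconsin,2019,39258,36078,8.8
WI,Wisconsin,2020,30647,32962,-7.0
WV,West Virginia,2018,12492,12539,-0.4
WV,West Virginia,2019,12539,12362,1.4
WV,West Virginia,2020,11249,11445,-1.7
WY,Wyoming,2018,2690,2858,-5.9
WY,Wyoming,2019,2986,3051,-2.1
WY,Wyoming,2020,2789,2857,-2.4
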