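region,name,year,predicted
AK,Alaska,2021,3017
AK,Alaska,2022,3435
AK,Alaska,2023,2971
AL,Alabama,2021,28553
AL,Alabama,2022,28553
AL,Alabama,2023,26222
AR,Arkansas,2021,16658
AR,Arkansas,2022,17246
AR,Arkansas,2023,16462
AZ,Arizona,2021,30994
AZ,Arizona,2022,34133
AZ,Arizona,2023,34133
CA,California,2021,170289
CA,California,2022,172472
CA,California,2023,172472
CO,Colorado,2021,23244
CO,Colorado,2022,22921
CO,Colorado,2023,23889
CT,Connecticut,2021,20092
CT,Connecticut,2022,21016
CT,Connecticut,2023,18706
DC,District of Columbia,2021,2585
DC,District of Columbia,2022,2765
DC,District of Columbia,2023,2729
DE,Delaware,2021,5805
DE,Delaware,2022,6143
DE,Delaware,2023,5873
FL,Florida,2021,135024
FL,Florida,2022,139789
FL,Florida,2023,147732
GA,Georgia,2021,52817
GA,Georgia,2022,54155
GA,Georgia,2023,60172
HI,Hawaii,2021,6902
HI,Hawaii,2022,7285
HI,Hawaii,2023,7285
IA,Iowa,2021,18617
IA,Iowa,2022,20266
IA,Iowa,2023,22387
ID,Idaho,2021,9457
ID,Idaho,2022,9955
ID,Idaho,2023,10577
IL,Illinois,2021,68709
IL,Illinois,2022,67881
IL,Illinois,2023,73676
IN,Indiana,2021,29766
IN,Indiana,2022,29428
IN,Indiana,2023,30781
KY,Kentucky,2021,26240
KY,Kentucky,2022,26843
KY,Kentucky,2023,27145
LA,Louisiana,2021,25351
LA,Louisiana,2022,29302
LA,Louisiana,2023,27656
MA,Massachusetts,2021,38712
MA,Massachusetts,2022,37464
MA,Massachusetts,2023,39545
MD,Maryland,2021,30603
MD,Maryland,2022,30963
MD,Maryland,2023,31323
ME,Maine,2021,10143
ME,Maine,2022,9813
ME,Maine,2023,10364
MI,Michigan,2021,53961
MI,Michigan,2022,56593
MI,Michigan,2023,60542
MN,Minnesota,2021,30152
MN,Minnesota,2022,29088
MN,Minnesota,2023,30507
MO,Missouri,2021,33694
MO,Missouri,2022,35261
MO,Missouri,2023,36437
MS,Mississippi,2021,16760
MS,Mississippi,2022,17972
MS,Mississippi,2023,16962
MT,Montana,2021,5790
MT,Montana,2022,6215
MT,Montana,2023,6896
NC,North Carolina,2021,54517
NC,North Carolina,2022,57924
NC,North Carolina,2023,55199
ND,North Dakota,2021,3498
ND,North Dakota,2022,3843
ND,North Dakota,2023,3942
NE,Nebraska,2021,9390
NE,Nebraska,2022,9718
NE,Nebraska,2023,9718
NH,New Hampshire,2021,7978
NH,New Hampshire,2022,8676
NH,New Hampshire,2023,8177
NJ,New Jersey,2021,51575
NJ,New Jersey,2022,50961
NJ,New Jersey,2023,56487
NM,New Mexico,2021,9031
NM,New Mexico,2022,9266
NM,New Mexico,2023,9852
NV,Nevada,2021,13791
NV,Nevada,2022,15045
NV,Nevada,2023,14686
NY,New York,2021,105600
NY,New York,2022,91872
NY,New York,2023,90816
OH,Ohio,2021,71749
OH,Ohio,2022,74223
OH,Ohio,2023,76697
OK,Oklahoma,2021,18590
OK,Oklahoma,2022,20020
OK,Oklahoma,2023,19544
OR,Oregon,2021,21559
OR,Oregon,2022,21559
OR,Oregon,2023,21843
PA,Pennsylvania,2021,77396
PA,Pennsylvania,2022,77396
PA,Pennsylvania,2023,83222
RI,Rhode Island,2021,5483
RI,Rhode Island,2022,6169
RI,Rhode Island,2023,6237
SC,South Carolina,2021,26678
SC,South Carolina,2022,30440
SC,South Carolina,2023,31466
SD,South Dakota,2021,5550
SD,South Dakota,2022,5686
SD,South Dakota,2023,5483
TN,Tennessee,2021,35529
TN,Tennessee,2022,38562
TN,Tennessee,2023,38562
TX,Texas,2021,112380
TX,Texas,2022,124367
TX,Texas,2023,121370
UT,Utah,2021,11938
UT,Utah,2022,11938
UT,Utah,2023,13115
VA,Virginia,2021,37184
VA,Virginia,2022,40082
VA,Virginia,2023,39599
VT,Vermont,2021,4155
VT,Vermont,2022,4106
VT,Vermont,2023,4155
WA,Washington,2021,38019
WA,Washington,2022,37019
WA,Washington,2023,38519
WI,Wisconsin,2021,36300
WI,Wisconsin,2022,35465
WI,Wisconsin,2023,37969
WV,West Virginia,2021,12577
WV,West Virginia,2022,12577
WV,West Virginia,2023,12577
WY,Wyoming,2021,2991
WY,Wyoming,2022,3080
WY,Wyoming,2023,2946
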