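region,name,year,predicted
AE,United Arab Emirates,2021,59286
AE,United Arab Emirates,2022,62491
AE,United Arab Emirates,2023,59286
AR,Argentina,2021,109065
AR,Argentina,2022,99370
AR,Argentina,2023,92099
AU,Australia,2021,184635
AU,Australia,2022,197823
AU,Australia,2023,184635
BD,Bangladesh,2021,137962
BD,Bangladesh,2022,137962
BD,Bangladesh,2023,112878
BE,Belgium,2021,80293
BE,Belgium,2022,86241
BE,Belgium,2023,80293
BO,Bolivia,2021,13404
BO,Bolivia,2022,15549
BO,Bolivia,2023,14745
BR,Brazil,2021,485614
BR,Brazil,2022,509302
BR,Brazil,2023,521147
CA,Canada,2021,255657
CA,Canada,2022,252540
CA,Canada,2023,240069
CH,Switzerland,2021,30242
CH,Switzerland,2022,33266
CH,Switzerland,2023,30242
CL,Chile,2021,49470
CL,Chile,2022,53276
CL,Chile,2023,53276
CO,Colombia,2021,101176
CO,Colombia,2022,105994
CO,Colombia,2023,115630
CR,Costa Rica,2021,11467
CR,Costa Rica,2022,12661
CR,Costa Rica,2023,12422
DE,Germany,2021,502815
DE,Germany,2022,502815
DE,Germany,2023,628519
DK,Denmark,2021,36457
DK,Denmark,2022,40746
DK,Denmark,2023,34313
DO,Dominican Republic,2021,16865
DO,Dominican Republic,2022,18130
DO,Dominican Republic,2023,16021
DZ,Algeria,2021,56081
DZ,Algeria,2022,58418
DZ,Algeria,2023,51408
EC,Ecuador,2021,28622
EC,Ecuador,2022,32526
EC,Ecuador,2023,29273
EG,Egypt,2021,113919
EG,Egypt,2022,134632
EG,Egypt,2023,124276
ES,Spain,2021,815883
ES,Spain,2022,784503
ES,Spain,2023,753123
FR,France,2021,426915
FR,France,2022,459755
FR,France,2023,443335
GB,United Kingdom,2021,1040818
GB,United Kingdom,2022,1040818
GB,United Kingdom,2023,1040818
GH,Ghana,2021,17340
GH,Ghana,2022,21675
GH,Ghana,2023,19674
GT,Guatemala,2021,14930
GT,Guatemala,2022,16247
GT,Guatemala,2023,15808
ID,Indonesia,2021,272878
ID,Indonesia,2022,272878
ID,Indonesia,2023,272878
IE,Ireland,2021,32187
IE,Ireland,2022,29200
IE,Ireland,2023,28869
IN,India,2021,1023410
IN,India,2022,1173912
IN,India,2023,1023410
IT,Italy,2021,332215
IT,Italy,2022,332215
IT,Italy,2023,332215
JP,Japan,2021,1028658
JP,Japan,2022,2057316
JP,Japan,2023,1028658
KE,Kenya,2021,34573
KE,Kenya,2022,43373
KE,Kenya,2023,42745
MA,Morocco,2021,54207
MA,Morocco,2022,56789
MA,Morocco,2023,49045
MX,Mexico,2021,177726
MX,Mexico,2022,188390
MX,Mexico,2023,177726
MY,Malaysia,2021,34559
MY,Malaysia,2022,37119
MY,Malaysia,2023,38399
NG,Nigeria,2021,102121
NG,Nigeria,2022,131623
NG,Nigeria,2023,118007
NO,Norway,2021,32721
NO,Norway,2022,37083
NO,Norway,2023,34902
NZ,New Zealand,2021,33769
NZ,New Zealand,2022,30739
NZ,New Zealand,2023,30306
PA,Panama,2021,7007
PA,Panama,2022,7816
PA,Panama,2023,6872
PE,Peru,2021,62088
PE,Peru,2022,69849
PE,Peru,2023,71143
PH,Philippines,2021,129727
PH,Philippines,2022,148946
PH,Philippines,2023,163360
PK,Pakistan,2021,158567
PK,Pakistan,2022,162531
PK,Pakistan,2023,146675
PL,Poland,2021,136383
PL,Poland,2022,204575
PL,Poland,2023,272767
PR,Puerto Rico,2021,12434
PR,Puerto Rico,2022,12757
PR,Puerto Rico,2023,12757
PT,Portugal,2021,57108
PT,Portugal,2022,60467
PT,Portugal,2023,60467
PY,Paraguay,2021,10571
PY,Paraguay,2022,11745
PY,Paraguay,2023,10571
RO,Romania,2021,96061
RO,Romania,2022,98886
RO,Romania,2023,104537
RU,Russian Federation,2021,394247
RU,Russian Federation,2022,394247
RU,Russian Federation,2023,394247
SA,Saudi Arabia,2021,23595
SA,Saudi Arabia,2022,25740
SA,Saudi Arabia,2023,23595
SE,Sweden,2021,40566
SE,Sweden,2022,38374
SE,Sweden,2023,39470
SG,Singapore,2021,21302
SG,Singapore,2022,20304
SG,Singapore,2023,21968
TH,Thailand,2021,86653
TH,Thailand,2022,103983
TH,Thailand,2023,86653
TR,Turkey,2021,46767
TR,Turkey,2022,70150
TR,Turkey,2023,46767
US,United States of America,2021,2048836
US,United States of America,2022,2211811
US,United States of America,2023,2165247
UY,Uruguay,2021,8036
UY,Uruguay,2022,8351
UY,Uruguay,2023,6933
VN,Viet Nam,2021,18629
VN,Viet Nam,2022,14903
VN,Viet Nam,2023,14903
ZA,South Africa,2021,86221
ZA,South Africa,2022,90924
ZA,South Africa,2023,84653
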