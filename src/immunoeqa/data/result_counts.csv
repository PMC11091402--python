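scheme,year,count
ALO,2011,14681
ALO,2012,66200
ALO,2013,68425
ALO,2014,69220
ALO,2015,68699
ALO,2016,74893
ALO,2017,73101
ALO,2018,130260
ALO,2019,170496
ALO,2020,187605
ALO,2021,210847
ALO,2022,329698
LOW,2011,3161
LOW,2012,3659
LOW,2013,3683
LOW,2014,3482
LOW,2015,4002
LOW,2016,3257
LOW,2017,5508
LOW,2018,6636
LOW,2019,7980
LOW,2020,6840
LOW,2021,7980
LOW,2022,6660
HI,2011,2915
HI,2012,3503
HI,2013,3403
HI,2014,3387
HI,2015,3674
HI,2016,3234
HI,2017,4869
HI,2018,6488
HI,2019,7705
HI,2020,6380
HI,2021,7364
HI,2022,6160
XM,2011,1973
XM,2012,1112
XM,2013,1078
XM,2014,1133
XM,2015,1077
XM,2016,1168
XM,2017,1838
XM,2018,3382
XM,2019,3780
XM,2020,3612
XM,2021,4368
XM,2022,2352
KIR,2011,0
KIR,2012,0
KIR,2013,0
KIR,2014,0
KIR,2015,2383
KIR,2016,0
KIR,2017,3541
KIR,2018,4016
KIR,2019,4200
KIR,2020,3538
KIR,2021,4500
KIR,2022,3833
XMFC,2011,0
XMFC,2012,831
XMFC,2013,787
XMFC,2014,684
XMFC,2015,892
XMFC,2016,582
XMFC,2017,1551
XMFC,2018,1442
XMFC,2019,1568
XMFC,2020,1230
XMFC,2021,1792
XMFC,2022,1120
CD,2011,0
CD,2012,756
CD,2013,690
CD,2014,445
CD,2015,914
CD,2016,345
CD,2017,1665
CD,2018,1408
CD,2019,1600
CD,2020,1170
CD,2021,1760
CD,2022,1095
SER,2011,1250
SER,2012,773
SER,2013,976
SER,2014,1026
SER,2015,579
SER,2016,1199
SER,2017,296
SER,2018,541
SER,2019,560
SER,2020,640
SER,2021,400
SER,2022,760
B57,2011,0
B57,2012,942
B57,2013,320
B57,2014,200
B57,2015,846
B57,2016,170
B57,2017,1050
B57,2018,797
B57,2019,1240
B57,2020,775
B57,2021,1540
B57,2022,724
B27,2011,199
B27,2012,282
B27,2013,278
B27,2014,187
B27,2015,297
B27,2016,191
B27,2017,705
B27,2018,497
B27,2019,750
B27,2020,370
B27,2021,890
B27,2022,380
HPA,2011,0
HPA,2012,0
HPA,2013,0
HPA,2014,0
HPA,2015,0
HPA,2016,0
HPA,2017,698
HPA,2018,600
HPA,2019,600
HPA,2020,400
HPA,2021,720
HPA,2022,500
CHM,2011,0
CHM,2012,0
CHM,2013,168
CHM,2014,152
CHM,2015,110
CHM,2016,190
CHM,2017,281
CHM,2018,320
CHM,2019,290
CHM,2020,260
CHM,2021,321
CHM,2022,280
AHPA,2011,0
AHPA,2012,0
AHPA,2013,0
AHPA,2014,0
AHPA,2015,0
AHPA,2016,0
AHPA,2017,0
AHPA,2018,0
AHPA,2019,166
AHPA,2020,175
AHPA,2021,139
AHPA,2022,240
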