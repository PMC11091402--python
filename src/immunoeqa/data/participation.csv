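scheme,year,labs
B27,2011,25
B27,2012,25
B27,2013,24
B27,2014,29
B27,2015,29
B27,2016,33
B27,2017,38
B27,2018,37
B27,2019,37
B27,2020,40
B27,2021,41
B27,2022,47
CD,2012,17
CD,2013,20
CD,2014,24
CD,2015,26
CD,2016,33
CD,2017,37
CD,2018,39
CD,2019,42
CD,2020,42
CD,2021,44
CD,2022,45
LOW,2011,33
LOW,2012,33
LOW,2013,34
LOW,2014,36
LOW,2015,35
LOW,2016,37
LOW,2017,38
LOW,2018,38
LOW,2019,39
LOW,2020,42
LOW,2021,43
LOW,2022,44
B57,2012,12
B57,2013,14
B57,2014,18
B57,2015,23
B57,2016,26
B57,2017,29
B57,2018,31
B57,2019,33
B57,2020,36
B57,2021,40
B57,2022,40
HI,2011,28
HI,2012,28
HI,2013,28
HI,2014,28
HI,2015,28
HI,2016,30
HI,2017,31
HI,2018,29
HI,2019,34
HI,2020,33
HI,2021,33
HI,2022,34
KIR,2016,16
KIR,2017,21
KIR,2018,22
KIR,2019,23
KIR,2020,22
KIR,2021,22
KIR,2022,25
HPA,2017,5
HPA,2018,4
HPA,2019,6
HPA,2020,6
HPA,2021,7
HPA,2022,6
XM,2011,23
XM,2012,22
XM,2013,22
XM,2014,22
XM,2015,22
XM,2016,23
XM,2017,24
XM,2018,22
XM,2019,23
XM,2020,24
XM,2021,25
XM,2022,27
XMFC,2012,7
XMFC,2013,10
XMFC,2014,8
XMFC,2015,9
XMFC,2016,10
XMFC,2017,13
XMFC,2018,14
XMFC,2019,15
XMFC,2020,16
XMFC,2021,18
XMFC,2022,17
ALO,2011,27
ALO,2012,29
ALO,2013,29
ALO,2014,30
ALO,2015,31
ALO,2016,30
ALO,2017,34
ALO,2018,33
ALO,2019,33
ALO,2020,34
ALO,2021,36
ALO,2022,41
AHPA,2019,5
AHPA,2020,6
AHPA,2021,7
AHPA,2022,7
CHM,2013,7
CHM,2014,10
CHM,2015,10
CHM,2016,12
CHM,2017,14
CHM,2018,14
CHM,2019,18
CHM,2020,15
CHM,2021,16
CHM,2022,16
SER,2011,18
SER,2012,18
SER,2013,16
SER,2014,16
SER,2015,12
SER,2016,11
SER,2017,12
SER,2018,11
SER,2019,9
SER,2020,9
SER,2021,6
SER,2022,5
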