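scheme,year,success_rate
HPA,2017,100.0
HPA,2018,100.0
HPA,2019,99.0
HPA,2020,99.5
HPA,2021,100.0
HPA,2022,100.0
KIR,2016,98.9
KIR,2017,99.4
KIR,2018,99.3
KIR,2019,99.7
KIR,2020,99.8
KIR,2021,99.7
KIR,2022,99.9
LOW,2011,99.0
LOW,2012,98.9
LOW,2013,99.0
LOW,2014,99.5
LOW,2015,99.2
LOW,2016,99.3
LOW,2017,99.2
LOW,2018,99.8
LOW,2019,99.8
LOW,2020,99.6
LOW,2021,99.8
LOW,2022,99.9
B57,2012,98.8
B57,2013,99.5
B57,2014,99.7
B57,2015,100.0
B57,2016,98.1
B57,2017,100.0
B57,2018,98.8
B57,2019,99.0
B57,2020,99.9
B57,2021,99.2
B57,2022,99.8
HI,2011,99.0
HI,2012,99.0
HI,2013,99.1
HI,2014,99.5
HI,2015,99.3
HI,2016,99.6
HI,2017,98.7
HI,2018,99.1
HI,2019,99.1
HI,2020,99.0
HI,2021,98.0
HI,2022,98.6
B27,2011,99.5
B27,2012,99.5
B27,2013,95.7
B27,2014,99.3
B27,2015,98.9
B27,2016,99.3
B27,2017,98.7
B27,2018,98.4
B27,2019,99.8
B27,2020,99.5
B27,2021,99.2
B27,2022,99.9
CD,2012,96.8
CD,2013,99.1
CD,2014,99.3
CD,2015,99.3
CD,2016,95.3
CD,2017,98.9
CD,2018,97.8
CD,2019,98.1
CD,2020,98.8
CD,2021,98.4
CD,2022,99.6
AHPA,2019,100.0
AHPA,2020,98.3
AHPA,2021,99.3
AHPA,2022,100.0
ALO,2011,97.7
ALO,2012,98.7
ALO,2013,99.1
ALO,2014,98.7
ALO,2015,98.3
ALO,2016,98.6
ALO,2017,99.8
ALO,2018,99.4
ALO,2019,99.3
ALO,2020,99.5
ALO,2021,99.3
ALO,2022,99.7
SER,2011,96.2
SER,2012,96.0
SER,2013,98.9
SER,2014,99.6
SER,2015,99.4
SER,2016,99.8
SER,2017,99.7
SER,2018,99.5
SER,2019,99.3
SER,2020,99.3
SER,2021,99.3
SER,2022,100.0
XM,2011,96.2
XM,2012,97.2
XM,2013,97.4
XM,2014,97.5
XM,2015,97.3
XM,2016,95.0
XM,2017,99.2
XM,2018,99.3
XM,2019,98.3
XM,2020,99.6
XM,2021,96.6
XM,2022,99.2
XMFC,2012,94.9
XMFC,2013,94.7
XMFC,2014,97.3
XMFC,2015,95.1
XMFC,2016,94.1
XMFC,2017,95.2
XMFC,2018,94.5
XMFC,2019,95.4
XMFC,2020,97.1
XMFC,2021,95.3
XMFC,2022,97.8
CHM,2013,88.2
CHM,2014,92.1
CHM,2015,97.0
CHM,2016,95.8
CHM,2017,96.4
CHM,2018,94.6
CHM,2019,93.8
CHM,2020,96.6
CHM,2021,95.7
CHM,2022,97.8
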