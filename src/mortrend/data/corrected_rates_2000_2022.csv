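sex,age_group,year,rate
total,10-19,2000,2.10
total,10-19,2001,2.67
total,10-19,2002,2.52
total,10-19,2003,2.47
total,10-19,2004,2.43
total,10-19,2005,2.43
total,10-19,2006,2.50
total,10-19,2007,2.43
total,10-19,2008,2.50
total,10-19,2009,2.33
total,10-19,2010,2.41
total,10-19,2011,2.46
total,10-19,2012,2.61
total,10-19,2013,2.62
total,10-19,2014,2.73
total,10-19,2015,2.85
total,10-19,2016,3.01
total,10-19,2017,3.56
total,10-19,2018,3.70
total,10-19,2019,4.39
total,10-19,2020,4.23
total,10-19,2021,4.66
total,10-19,2022,4.62
male,10-19,2000,2.68
male,10-19,2001,3.48
male,10-19,2002,3.28
male,10-19,2003,3.25
male,10-19,2004,3.17
male,10-19,2005,3.12
male,10-19,2006,3.32
male,10-19,2007,3.28
male,10-19,2008,3.25
male,10-19,2009,3.31
male,10-19,2010,3.33
male,10-19,2011,3.26
male,10-19,2012,3.58
male,10-19,2013,3.64
male,10-19,2014,3.74
male,10-19,2015,3.89
male,10-19,2016,4.17
male,10-19,2017,4.68
male,10-19,2018,4.84
male,10-19,2019,6.05
male,10-19,2020,5.68
male,10-19,2021,5.84
male,10-19,2022,5.95
female,10-19,2000,1.52
female,10-19,2001,1.86
female,10-19,2002,1.76
female,10-19,2003,1.69
female,10-19,2004,1.70
female,10-19,2005,1.74
female,10-19,2006,1.68
female,10-19,2007,1.58
female,10-19,2008,1.73
female,10-19,2009,1.34
female,10-19,2010,1.47
female,10-19,2011,1.66
female,10-19,2012,1.62
female,10-19,2013,1.57
female,10-19,2014,1.70
female,10-19,2015,1.77
female,10-19,2016,1.80
female,10-19,2017,2.41
female,10-19,2018,2.50
female,10-19,2019,2.66
female,10-19,2020,2.72
female,10-19,2021,3.42
female,10-19,2022,3.23
total,10-14,2000,0.65
total,10-14,2001,0.83
total,10-14,2002,0.76
total,10-14,2003,0.70
total,10-14,2004,0.73
total,10-14,2005,0.74
total,10-14,2006,0.82
total,10-14,2007,0.83
total,10-14,2008,0.74
total,10-14,2009,0.77
total,10-14,2010,0.72
total,10-14,2011,0.76
total,10-14,2012,0.81
total,10-14,2013,0.86
total,10-14,2014,1.00
total,10-14,2015,0.93
total,10-14,2016,1.02
total,10-14,2017,1.23
total,10-14,2018,1.23
total,10-14,2019,1.42
total,10-14,2020,1.30
total,10-14,2021,1.69
total,10-14,2022,1.57
male,10-14,2000,0.70
male,10-14,2001,0.84
male,10-14,2002,0.78
male,10-14,2003,0.78
male,10-14,2004,0.65
male,10-14,2005,0.73
male,10-14,2006,0.85
male,10-14,2007,0.95
male,10-14,2008,0.74
male,10-14,2009,0.80
male,10-14,2010,0.79
male,10-14,2011,0.88
male,10-14,2012,1.03
male,10-14,2013,0.99
male,10-14,2014,1.13
male,10-14,2015,1.05
male,10-14,2016,1.06
male,10-14,2017,1.25
male,10-14,2018,1.32
male,10-14,2019,1.33
male,10-14,2020,1.24
male,10-14,2021,1.55
male,10-14,2022,1.47
female,10-14,2000,0.61
female,10-14,2001,0.82
female,10-14,2002,0.74
female,10-14,2003,0.62
female,10-14,2004,0.80
female,10-14,2005,0.76
female,10-14,2006,0.80
female,10-14,2007,0.71
female,10-14,2008,0.74
female,10-14,2009,0.73
female,10-14,2010,0.65
female,10-14,2011,0.64
female,10-14,2012,0.58
female,10-14,2013,0.74
female,10-14,2014,0.87
female,10-14,2015,0.81
female,10-14,2016,0.97
female,10-14,2017,1.21
female,10-14,2018,1.14
female,10-14,2019,1.52
female,10-14,2020,1.37
female,10-14,2021,1.84
female,10-14,2022,1.68
total,15-19,2000,3.53
total,15-19,2001,4.47
total,15-19,2002,4.23
total,15-19,2003,4.20
total,15-19,2004,4.10
total,15-19,2005,4.10
total,15-19,2006,4.18
total,15-19,2007,4.03
total,15-19,2008,4.26
total,15-19,2009,3.90
total,15-19,2010,4.08
total,15-19,2011,4.15
total,15-19,2012,4.37
total,15-19,2013,4.30
total,15-19,2014,4.37
total,15-19,2015,4.64
total,15-19,2016,4.85
total,15-19,2017,5.73
total,15-19,2018,5.98
total,15-19,2019,7.15
total,15-19,2020,6.96
total,15-19,2021,7.43
total,15-19,2022,7.51
male,15-19,2000,4.65
male,15-19,2001,6.07
male,15-19,2002,5.72
male,15-19,2003,5.68
male,15-19,2004,5.64
male,15-19,2005,5.51
male,15-19,2006,5.80
male,15-19,2007,5.63
male,15-19,2008,5.79
male,15-19,2009,5.86
male,15-19,2010,5.89
male,15-19,2011,5.64
male,15-19,2012,6.11
male,15-19,2013,6.23
male,15-19,2014,6.25
male,15-19,2015,6.58
male,15-19,2016,7.09
male,15-19,2017,7.89
male,15-19,2018,8.13
male,15-19,2019,10.46
male,15-19,2020,9.84
male,15-19,2021,9.87
male,15-19,2022,10.20
female,15-19,2000,2.41
female,15-19,2001,2.88
female,15-19,2002,2.74
female,15-19,2003,2.73
female,15-19,2004,2.57
female,15-19,2005,2.70
female,15-19,2006,2.56
female,15-19,2007,2.43
female,15-19,2008,2.72
female,15-19,2009,1.95
female,15-19,2010,2.28
female,15-19,2011,2.66
female,15-19,2012,2.62
female,15-19,2013,2.36
female,15-19,2014,2.47
female,15-19,2015,2.67
female,15-19,2016,2.56
female,15-19,2017,3.51
female,15-19,2018,3.76
female,15-19,2019,3.72
female,15-19,2020,3.97
female,15-19,2021,4.89
female,15-19,2022,4.71
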