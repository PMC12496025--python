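country,financial_year,measure,proportion
England,2008,bundle,0.00
England,2009,bundle,0.01
England,2010,bundle,0.34
England,2011,bundle,0.52
England,2012,bundle,0.61
England,2013,bundle,0.66
England,2014,bundle,0.67
England,2008,bpt1,0.54
England,2009,bpt1,0.57
England,2010,bpt1,0.67
England,2011,bpt1,0.72
England,2012,bpt1,0.76
England,2013,bpt1,0.77
England,2014,bpt1,0.77
England,2008,bpt2,0.01
England,2009,bpt2,0.05
England,2010,bpt2,0.74
England,2011,bpt2,0.88
England,2012,bpt2,0.94
England,2013,bpt2,0.97
England,2014,bpt2,0.98
England,2008,bpt3,0.02
England,2009,bpt3,0.07
England,2010,bpt3,0.76
England,2011,bpt3,0.90
England,2012,bpt3,0.95
England,2013,bpt3,0.98
England,2014,bpt3,0.97
England,2008,bpt4,0.66
England,2009,bpt4,0.63
England,2010,bpt4,0.62
England,2011,bpt4,0.72
England,2012,bpt4,0.99
England,2013,bpt4,1.00
England,2014,bpt4,1.00
England,2008,bpt6,0.00
England,2009,bpt6,0.02
England,2010,bpt6,0.58
England,2011,bpt6,0.75
England,2012,bpt6,0.84
England,2013,bpt6,0.88
England,2014,bpt6,0.90
England,2008,bpt7,0.02
England,2009,bpt7,0.08
England,2010,bpt7,0.88
England,2011,bpt7,0.92
England,2012,bpt7,0.94
England,2013,bpt7,0.96
England,2014,bpt7,0.97
England,2008,bpt8,0.52
England,2009,bpt8,0.64
England,2010,bpt8,0.81
England,2011,bpt8,0.92
England,2012,bpt8,0.96
England,2013,bpt8,0.97
England,2014,bpt8,0.98
England,2008,bpt9,0.68
England,2009,bpt9,0.75
England,2010,bpt9,0.88
England,2011,bpt9,0.94
England,2012,bpt9,0.96
England,2013,bpt9,0.97
England,2014,bpt9,0.98
Wales,2008,bundle,0.00
Wales,2009,bundle,0.00
Wales,2010,bundle,0.06
Wales,2011,bundle,0.03
Wales,2012,bundle,0.02
Wales,2013,bundle,0.01
Wales,2014,bundle,0.01
Wales,2008,bpt1,0.56
Wales,2009,bpt1,0.60
Wales,2010,bpt1,0.59
Wales,2011,bpt1,0.62
Wales,2012,bpt1,0.65
Wales,2013,bpt1,0.65
Wales,2014,bpt1,0.64
Wales,2008,bpt2,0.00
Wales,2009,bpt2,0.03
Wales,2010,bpt2,0.17
Wales,2011,bpt2,0.15
Wales,2012,bpt2,0.19
Wales,2013,bpt2,0.15
Wales,2014,bpt2,0.22
Wales,2008,bpt3,0.02
Wales,2009,bpt3,0.11
Wales,2010,bpt3,0.58
Wales,2011,bpt3,0.75
Wales,2012,bpt3,0.77
Wales,2013,bpt3,0.74
Wales,2014,bpt3,0.63
Wales,2008,bpt4,0.71
Wales,2009,bpt4,0.72
Wales,2010,bpt4,0.54
Wales,2011,bpt4,0.49
Wales,2012,bpt4,0.70
Wales,2013,bpt4,0.94
Wales,2014,bpt4,0.92
Wales,2008,bpt6,0.01
Wales,2009,bpt6,0.03
Wales,2010,bpt6,0.28
Wales,2011,bpt6,0.29
Wales,2012,bpt6,0.27
Wales,2013,bpt6,0.32
Wales,2014,bpt6,0.41
Wales,2008,bpt7,0.03
Wales,2009,bpt7,0.20
Wales,2010,bpt7,0.76
Wales,2011,bpt7,0.88
Wales,2012,bpt7,0.87
Wales,2013,bpt7,0.84
Wales,2014,bpt7,0.89
Wales,2008,bpt8,0.55
Wales,2009,bpt8,0.43
Wales,2010,bpt8,0.57
Wales,2011,bpt8,0.69
Wales,2012,bpt8,0.71
Wales,2013,bpt8,0.68
Wales,2014,bpt8,0.68
Wales,2008,bpt9,0.90
Wales,2009,bpt9,0.80
Wales,2010,bpt9,0.90
Wales,2011,bpt9,0.90
Wales,2012,bpt9,0.84
Wales,2013,bpt9,0.84
Wales,2014,bpt9,0.84
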