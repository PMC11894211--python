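year,district,area_ha
2017-18,Thanjavur,126226
2018-19,Thanjavur,124618
2019-20,Thanjavur,141287
2020-21,Thanjavur,141077
2021-22,Thanjavur,139171
2022-23,Thanjavur,117907
2017-18,Thiruvarur,132258
2018-19,Thiruvarur,126019
2019-20,Thiruvarur,125589
2020-21,Thiruvarur,127752
2021-22,Thiruvarur,127028
2022-23,Thiruvarur,110512
2017-18,Nagapattinam,119411
2018-19,Nagapattinam,105107
2019-20,Nagapattinam,117761
2020-21,Nagapattinam,110938
2021-22,Nagapattinam,124219
2022-23,Nagapattinam,102792
2017-18,Cuddalore,99170
2018-19,Cuddalore,77312
2019-20,Cuddalore,104331
2020-21,Cuddalore,88002
2021-22,Cuddalore,101821
2022-23,Cuddalore,100348
2017-18,Tiruchirappalli,31516
2018-19,Tiruchirappalli,23545
2019-20,Tiruchirappalli,17877
2020-21,Tiruchirappalli,43944
2021-22,Tiruchirappalli,32484
2022-23,Tiruchirappalli,45027
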