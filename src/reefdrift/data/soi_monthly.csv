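year,october,november,december,january_next,event_label
2010,18.3,16.4,27.1,19.9,Very strong La Nina
2011,7.3,13.8,23.0,9.4,Moderate La Nina
2012,2.4,3.9,-6.0,-1.1,Neutral
2013,-1.9,9.2,0.6,12.2,Neutral
2014,-8.0,-10.0,-5.5,-7.8,El Nino alert
2015,-20.2,-5.3,-9.1,-19.7,Strong El Nino
2016,-4.3,-0.7,2.6,1.3,Neutral-La Nina
2017,9.1,11.8,-1.4,8.9,Neutral-La Nina
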