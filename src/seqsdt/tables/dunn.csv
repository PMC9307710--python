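category,tp1,tp2,tp3,tp4,tp5,tp6,ta
yes@1,701,119,104,122,90,106,185
yes@2,8,626,68,75,68,62,94
yes@3,7,10,631,72,47,91,99
yes@4,11,10,12,532,63,63,86
yes@5,17,12,6,6,485,53,87
yes@6,15,12,11,9,10,421,79
reject,224,185,175,154,148,143,790
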