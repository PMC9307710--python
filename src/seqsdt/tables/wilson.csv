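category,tp1,tp2,tp3,tp4,tp5,tp6,ta
yes@1,579,137,127,123,132,125,766
yes@2,2,450,98,82,91,93,539
yes@3,9,7,391,108,109,89,554
yes@4,14,15,9,331,67,62,488
yes@5,21,7,5,2,229,53,305
yes@6,9,6,9,8,5,214,232
reject,75,74,52,45,63,65,1267
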