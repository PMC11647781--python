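strength
1.014
1.081
1.082
1.185
1.223
1.248
1.267
1.271
1.272
1.275
1.276
1.278
1.286
1.288
1.292
1.304
1.306
1.355
1.361
1.364
1.379
1.409
1.426
1.459
1.460
1.476
1.481
1.484
1.501
1.506
1.524
1.526
1.535
1.541
1.568
1.579
1.581
1.591
1.593
1.602
1.666
1.670
1.684
1.691
1.704
1.731
1.735
1.747
1.748
1.757
1.800
1.806
1.867
1.876
1.878
1.910
1.916
1.972
2.012
2.456
2.592
3.197
4.121
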