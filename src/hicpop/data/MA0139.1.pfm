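>MA0139.1 CTCF
A [    87    167    281     56      8    744     40    107    851      5    333     54     12     56    104    372     82    117    402 ]
C [   291    145     49    800    903     13    528    433     11      0      3     12      0      8    733     13    482    322    181 ]
G [    76    414    449     21      0     65    334     48     32    903    566    504    890    775      5    507    307     73    266 ]
T [   459    187    134     36      2     91     11    324     18      3      9    341      8     71     67     17     37    396     59 ]
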