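{
 "model": "JTT",
 "source": "Jones, Taylor & Thornton (1992) empirical amino-acid exchangeabilities, as distributed in phangorn 2.12.1",
 "alphabet": "ARNDCQEGHILKMFPSTWYV",
 "lower_triangle_colmajor": [
  58.0,
  54.0,
  81.0,
  56.0,
  57.0,
  105.0,
  179.0,
  27.0,
  36.0,
  30.0,
  35.0,
  54.0,
  15.0,
  194.0,
  378.0,
  475.0,
  9.0,
  11.0,
  298.0,
  45.0,
  16.0,
  113.0,
  310.0,
  29.0,
  137.0,
  328.0,
  22.0,
  38.0,
  646.0,
  44.0,
  5.0,
  74.0,
  101.0,
  64.0,
  126.0,
  20.0,
  17.0,
  528.0,
  34.0,
  86.0,
  58.0,
  81.0,
  391.0,
  47.0,
  12.0,
  263.0,
  30.0,
  10.0,
  15.0,
  503.0,
  232.0,
  8.0,
  70.0,
  16.0,
  10.0,
  49.0,
  767.0,
  130.0,
  112.0,
  11.0,
  7.0,
  26.0,
  15.0,
  4.0,
  15.0,
  59.0,
  38.0,
  4.0,
  46.0,
  31.0,
  9.0,
  5.0,
  59.0,
  69.0,
  17.0,
  23.0,
  7.0,
  31.0,
  78.0,
  14.0,
  223.0,
  42.0,
  115.0,
  209.0,
  62.0,
  323.0,
  26.0,
  597.0,
  9.0,
  72.0,
  292.0,
  43.0,
  4.0,
  164.0,
  53.0,
  51.0,
  18.0,
  24.0,
  20.0,
  119.0,
  26.0,
  12.0,
  9.0,
  181.0,
  18.0,
  5.0,
  18.0,
  30.0,
  32.0,
  10.0,
  7.0,
  45.0,
  23.0,
  6.0,
  6.0,
  27.0,
  14.0,
  5.0,
  24.0,
  201.0,
  33.0,
  55.0,
  8.0,
  47.0,
  16.0,
  56.0,
  45.0,
  33.0,
  40.0,
  115.0,
  73.0,
  46.0,
  8.0,
  573.0,
  11.0,
  229.0,
  21.0,
  479.0,
  89.0,
  10.0,
  40.0,
  245.0,
  9.0,
  32.0,
  961.0,
  14.0,
  388.0,
  248.0,
  102.0,
  59.0,
  25.0,
  52.0,
  24.0,
  180.0,
  65.0,
  4.0,
  21.0,
  47.0,
  103.0,
  10.0,
  8.0,
  14.0,
  43.0,
  16.0,
  29.0,
  226.0,
  24.0,
  18.0,
  323.0,
  17.0,
  92.0,
  12.0,
  53.0,
  536.0,
  62.0,
  285.0,
  118.0,
  6.0,
  10.0,
  23.0,
  477.0,
  35.0,
  63.0,
  38.0,
  12.0,
  21.0,
  112.0,
  71.0,
  25.0,
  16.0
 ],
 "frequencies": [
  0.07674792325207676,
  0.051690948309051694,
  0.04264495735504265,
  0.05154394845605155,
  0.019802980197019805,
  0.04075195924804075,
  0.06182993817006184,
  0.07315192684807316,
  0.022943977056022944,
  0.05376094623905377,
  0.0919039080960919,
  0.05867594132405868,
  0.02382597617402383,
  0.040125959874040135,
  0.05090094909905091,
  0.06876493123506877,
  0.05856494143505857,
  0.014260985739014262,
  0.0321019678980321,
  0.066004933995066
 ]
}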