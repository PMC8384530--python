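{
  "description": "Independent scalar-loop reference runs on the 10-D sphere, bounds +/-100, population 25, 500 iterations, seeds 0-19. 'threshold' = 1000 x the reference median; a correctly working optimizer lands within three decades of the reference on this log-scale quantity, while a broken one stalls around 1e+1 or worse.",
  "settings": {
    "objective": "sphere",
    "d": 10,
    "bounds": [
      -100,
      100
    ],
    "n": 25,
    "max_iter": 500,
    "seeds": [
      0,
      1,
      2,
      3,
      4,
      5,
      6,
      7,
      8,
      9,
      10,
      11,
      12,
      13,
      14,
      15,
      16,
      17,
      18,
      19
    ]
  },
  "per_seed_final_cost": [
    5.212620266647404e-09,
    1.19669730396444e-09,
    2.0201351766871733e-10,
    1.0284992632196077e-09,
    9.956511776885714e-09,
    2.9311003077332284e-09,
    5.785814403087163e-10,
    5.742633724842526e-09,
    1.7461639668676965e-10,
    7.406029508968841e-11,
    3.79398236303896e-11,
    5.574239051491261e-09,
    6.900049616282808e-11,
    9.71902020522511e-10,
    4.644580908887071e-09,
    6.450402526911616e-08,
    3.848504239215828e-10,
    7.726393051443805e-10,
    1.6428648566300704e-10,
    3.9869400398226984e-09
  ],
  "median_final_cost": 1.0002006418710593e-09,
  "threshold": 1.0002006418710593e-06
}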