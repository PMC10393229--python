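{
 "d0": 2.697145240950368,
 "s0_sq": 0.6463096438202046,
 "coef": [
  -0.5215319476503192,
  -0.7055105014049818,
  0.2152417403014195,
  -0.04201022083128018,
  -0.1882125107285778,
  -0.850100142253813,
  -0.1343585631408097,
  1.359233014265582,
  0.09496679799006527,
  -0.2658291891216167,
  0.424592943022335,
  0.3988334615721589,
  0.2450632106710177,
  0.1315849695086519,
  -1.14209423553263,
  -0.4024696392961668,
  -0.1142614621205483,
  0.4760818116669667,
  0.4174391189018751,
  -0.06598823151128878,
  -1.169533984801359,
  2.141590440830765,
  -0.3897716314136027,
  -0.5982029119975963,
  0.6119838941658009,
  2.132451720286799,
  0.1270637163270726,
  0.218017888045752,
  -0.4755049665415484,
  -0.7415137213416736,
  0.2678176641736716,
  -0.7451688155914026,
  -0.3707834230780747,
  -0.09159905944869262,
  -0.3208971743059165,
  0.3962564868310006,
  -0.2954567173994131,
  0.3928626265515878,
  0.1807670165862223,
  -0.4343791738185985,
  -0.4077601345885031,
  0.7159695926533062,
  -1.063696342577813,
  0.2491191520562588,
  -0.7647317926245825,
  0.2826355710451188,
  -0.5597570600790935,
  -0.1858296348759538,
  1.021880110534222,
  -0.7879629641944131
 ],
 "t": [
  -2.243875587726377,
  -0.6724058244847112,
  0.3247229079034893,
  -0.1013354194979002,
  -0.7388726503209029,
  -1.144419619469498,
  -0.2776970469829068,
  2.208744886449054,
  0.2305492603262584,
  -1.019600095165085,
  0.4937945038850157,
  0.894338660878002,
  1.456787025155366,
  0.6926131445605656,
  -3.483192272026439,
  -1.918665605521631,
  -0.4333684712942618,
  1.31928220802972,
  0.4544549838715995,
  -0.1068206248774997,
  -2.71807789718672,
  2.08463664649778,
  -0.605355347367538,
  -2.744189558947622,
  2.202318390606594,
  2.80424012212741,
  0.2863460626750836,
  0.3397185135924831,
  -1.284559336190726,
  -2.436049575791472,
  0.6441192303369053,
  -1.062607712331681,
  -1.81212573156859,
  -0.2036557788011396,
  -0.5375895167190242,
  1.618356019303556,
  -0.5273778360868671,
  1.274671693480221,
  1.155094729696966,
  -1.546069686518587,
  -1.274298707173528,
  1.824252842858241,
  -3.296694497972966,
  0.5116104712570967,
  -2.117238073338475,
  0.7929602411084802,
  -1.22408970343492,
  -0.3032789614764391,
  2.747840340955435,
  -3.461997026540165
 ],
 "p": [
  0.0344592676422204,
  0.5078293306024441,
  0.7482400541929533,
  0.9201367513382578,
  0.4672402426053897,
  0.2638779450989137,
  0.7836533018330764,
  0.03711733727498145,
  0.8196437532333143,
  0.3182153407049081,
  0.6259972041111639,
  0.3801346844530183,
  0.1582991050823259,
  0.4952844178002053,
  0.001946202829655993,
  0.06715084340179261,
  0.6686664729509313,
  0.1996808794917243,
  0.6536369175458137,
  0.9158304824525705,
  0.01207638634244546,
  0.04805661413764019,
  0.5506969679329236,
  0.0113739097174519,
  0.03762321972482605,
  0.009902018333418887,
  0.7771015813043527,
  0.7370611313792268,
  0.2113622476207797,
  0.02275065729211313,
  0.5256841654830833,
  0.2986693523317687,
  0.08265847469101859,
  0.8403612660677929,
  0.5958734062972644,
  0.1188204633748681,
  0.6028343572805692,
  0.214783072214722,
  0.259566626914579,
  0.1353393297042692,
  0.2149129408158039,
  0.0807496345967727,
  0.003070994659059096,
  0.613658296080644,
  0.04493331189724205,
  0.4356687824423208,
  0.2329496334252981,
  0.7643238875553842,
  0.01127882293076223,
  0.002050320868398613
 ],
 "s2_post": [
  0.3180215427419816,
  6.480914387180646,
  2.5865411226818,
  1.011764978067358,
  0.3819882873270115,
  3.248342702575728,
  1.378099043558926,
  2.229404984168474,
  0.9988686356545345,
  0.4001638485265643,
  4.352565272019782,
  1.170769549810608,
  0.1665928513217,
  0.2124825953134539,
  0.6329089477759059,
  0.2590358782967645,
  0.4092391584417918,
  0.7666197817756277,
  4.967030214799961,
  2.246544384452835,
  1.089918808832523,
  6.213042951543646,
  2.440573775486863,
  0.2797441950059638,
  0.4545817828187701,
  3.404240780278866,
  1.159185467341644,
  2.424588712377461,
  0.8066665115387929,
  0.5454543276736991,
  1.01774307977772,
  2.895047337105115,
  0.2464655463411053,
  1.190915110558419,
  2.09759894671714,
  0.3529367543015711,
  1.847720349198589,
  0.5592126684542715,
  0.1441768155461662,
  0.464699400792834,
  0.6027806405449856,
  0.9067996538220092,
  0.6128725613208447,
  1.395814280860923,
  0.7680175673763829,
  0.7478991953680644,
  1.231019473270917,
  2.21023082471429,
  0.8141588633617948,
  0.304965339086393
 ]
}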