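accession	erucic_pct	category
Cardamine hirsuta	0	L
Cardamine parviflora	0	L
Nasturtium officinale	0	L
Lobularia maritima var. benthamii	0.24	L
Orychophragmus violaceus	0.37	L
Aethionema grandiflorum	0.48	L
Capsella bursa-pastoris	0.61	L
Coronopus didymus	1.30	L
Arabidopsis thaliana	1.88	L
Lepidium apetalum	2.41	L
Camelina microcarpa	2.53	L
Camelina sativa	3.03	L
Goldbachia laevigata	8.27	L
Arabidopsis lyrata subsp. kamchatica	9.21	L
Neslia paniculata	10.50	M1
Erysimum siliculosa	11.01	M1
Cardaria draba	11.04	M1
Cardaria draba subsp. chalepensis	12.12	M1
Cochlearia officinalis	13.77	M1
Sisymbrium loeselii	16.89	M1
Sisymbrium officinale	17.00	M1
Descurainia sophia	18.16	M1
Erysimum cheiranthoides	20.50	M2
Erysimum sisymbrioides	20.87	M2
Isatis tinctoria	21.02	M2
Diplotaxis tenuisiliqua	21.33	M2
Erucastrum gallicum	21.91	M2
Rorippa indica	22.32	M2
Lepidium campestre	22.65	M2
Diplotaxis murali	23.73	M2
Rorippa dubia	26.16	M2
Myagrum perfoliatum	28.32	M2
Sinapis alba	31.11	M3
Erucastrum canariense	31.53	M3
Cheiranthus cheiri	31.62	M3
Sinapis arvensis	34.51	M3
Brassica nigra	34.88	M3
Raphanus sativus	35.51	M3
Thlaspi perfoliatum	36.19	M3
Brassica juncea	36.96	M3
Thlaspi arvense	37.79	M3
Raphanus raphanistrum	39.79	M3
Brassica napus	39.8	M3
Brassica oleracea	41.10	H
Brassica carinata	42.53	H
Eruca vesicaria subsp. sativa	43.50	H
Brassica oleracea var. gemmifera	44.00	H
Lunaria annua	44.96	H
Crambe kralikii	45.50	H
Brassica oleracea var. albiflora	45.81	H
Brassica napus var. napobrassica	46.41	H
Brassica elongata	47.14	H
Brassica oleracea var. gongylodes	47.94	H
Brassica oleracea var. botrytis	48.03	H
Brassica tournefortii	48.08	H
Brassica rapa	48.32	H
Brassica oleracea var. italica	49.77	H
Crambe filiformis	51.88	H
Crambe hispanica subsp abyssinica	53.12	H
Crambe hispanica	55.82	H
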