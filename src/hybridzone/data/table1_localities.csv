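code,locality,latitude,longitude,species,n_kasp,hybrid_index,n_mtdna,mtdna_freq
1,Turkiye: Hurriyet,40.276,28.650,nesterovi,12,0.00,3,0
2,Turkiye: Avdancik,40.291,29.160,nesterovi,12,0.00,3,0
3,Turkiye: Mustafali,40.361,29.572,nesterovi,12,0.00,3,0
4,Turkiye: Levent,40.965,30.433,nesterovi,12,0.00,3,0
5,Turkiye: Abant Golu,40.612,31.288,nesterovi,3,0.00,3,0
6,Turkiye: Hacilar,41.497,32.102,nesterovi,12,0.00,3,0
7,Turkiye: Cal,41.367,32.944,nesterovi,12,0.00,3,0
8,Turkiye: Basboyunduruk,41.014,32.861,nesterovi,12,0.00,3,0
9,Turkiye: Cibankoy,41.201,34.037,nesterovi,12,0.00,3,0
10,Turkiye: Cebeli,41.121,35.330,nesterovi,12,0.00,3,0
11,Turkiye: Cakiralan,41.182,35.774,nesterovi,12,0.00,3,0
12,Turkiye: Kethuda,41.116,36.017,nesterovi,14,0.00,3,0
13,Turkiye: Cumhuriyet,41.213,36.678,nesterovi,13,0.00,6,0
14,Turkiye: Carsamba,41.186,36.749,nesterovi,14,0.00,4,0
15,Turkiye: Agcaguney,41.126,36.604,nesterovi,14,0.00,11,0
16,Turkiye: Tepealti,41.116,36.792,nesterovi,9,0.01,9,0
17,Turkiye: Sogutlu,41.219,36.863,nesterovi,14,0.00,7,0
18,Turkiye: Kocaman,41.141,36.974,nesterovi,14,0.01,9,0
19,Turkiye: Sakarli,41.155,37.069,nesterovi,6,0.02,6,0
20,Turkiye: Akcay,41.144,37.146,nesterovi,15,0.06,9,0
21,Turkiye: Unye,41.142,37.196,ophryticus,15,0.98,9,1
22,Turkiye: Guzeyali,41.105,37.380,ophryticus,16,0.95,9,1
23,Turkiye: Dizdar,40.969,37.148,ophryticus,11,1.00,9,1
24,Turkiye: Kizilelma,40.860,37.055,ophryticus,12,1.00,5,1
25,Turkiye: Bali,40.829,37.235,ophryticus,14,0.99,5,1
26,Turkiye: Karahamza,40.887,37.423,ophryticus,13,1.00,5,1
27,Turkiye: Catalan,40.828,36.602,ophryticus,14,1.00,3,1
28,Turkiye: Kadincik,40.888,37.700,ophryticus,16,1.00,5,1
29,Turkiye: Cihadiye,40.684,37.567,ophryticus,16,1.00,3,1
30,Turkiye: Cakirli,40.446,37.483,ophryticus,14,1.00,3,1
31,Turkiye: Maden,40.949,38.157,ophryticus,11,0.99,3,1
32,Turkiye: Kockayasi,40.565,38.470,ophryticus,13,0.99,3,1
33,Turkiye: Espiye,40.955,38.726,ophryticus,12,0.99,3,1
34,Turkiye: Gokcekent,40.287,38.132,ophryticus,9,1.00,3,1
35,Turkiye: Yesiltepe Koyu,40.953,39.630,ophryticus,14,0.99,3,1
36,Turkiye: Yomra,40.983,39.827,ophryticus,12,0.99,3,1
37,Turkiye: Yesilyali,40.959,39.998,ophryticus,12,0.99,3,1
38,Turkiye: Denizgoren,40.968,40.380,ophryticus,4,1.00,3,1
39,Turkiye: Karagol,41.223,41.610,ophryticus,12,1.00,3,1
40,Turkiye: Ortakoy,41.284,41.913,ophryticus,12,1.00,3,1
41,Turkiye: Kopruyaka,41.260,42.312,ophryticus,12,1.00,3,1
42,Georgia: Mtskheta,41.809,44.498,ophryticus,12,1.00,3,1
I,Spain: Sierra de Busa,42.098,1.647,admixed,11,0.69,11,1
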