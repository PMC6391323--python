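metabolite_id	name	biofluid
10382	16:0 lysophosphatidic acid	Serum
10384	18:0 lysophosphatidic acid	Serum
00201	Acetyl carnitine	Serum/Urine
00562	Carnitine	Serum/Urine
00062	Creatinine	Urine
00637	Glycochenodeoxycholic acid	Serum
00138	Glycocholic acid	Serum
00631	Glycodeoxycholic acid	Serum
02117	Oleamide	Serum
00159	Phenylalanine	Serum
29006	Phenylalanyl-tryptophan	Serum
00951	Taurochenodeoxycholic acid	Serum
00036	Taurocholic acid	Serum
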