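family	reference_gene	BraLF	BraMF1	BraMF2	BolLF	BolMF1	BolMF2
UGT71	AT1G07240.1	Bra015567	NA	NA	Bol041114	NA	NA
UGT71	AT1G07260.1	Bra015568	NA	NA	Bol041115	NA	NA
UGT71	AT3G21750.1	Bra031306	NA	NA	Bol038332	NA	NA
UGT71	AT3G21760.1	Bra031307	NA	NA	Bol038331	NA	NA
UGT73	AT2G36750.1	Bra005246	NA	NA	NA	NA	NA
UGT73	AT2G36770.1	Bra005245	NA	Bra023080	NA	NA	Bol039728
UGT73	AT2G36780.1	Bra005243	NA	NA	Bol001666	NA	Bol039729
UGT73	AT2G36800.1	Bra005241	NA	Bra023079	Bol001668	NA	NA
UGT73	AT3G53150.1	Bra006971	NA	NA	NA	NA	NA
UGT73	AT3G53160.1	Bra006973	NA	NA	NA	NA	NA
UGT73	AT4G34131.1	Bra011495	NA	Bra034608	Bol013630	NA	Bol014271
UGT73	AT4G34138.1	Bra011496	NA	Bra034610	Bol013632	NA	Bol014269
UGT74	AT2G43820.1	Bra004787	NA	NA	Bol030029	NA	NA
UGT74	AT2G43840.2	Bra004788	NA	NA	Bol030030	NA	NA
UGT76	AT3G46670.1	NA	Bra033808	NA	NA	Bol018766	NA
UGT76	AT3G46680.1	NA	NA	NA	NA	Bol018765	NA
UGT76	AT3G46690.1	NA	Bra033807	NA	NA	NA	NA
UGT76	AT5G05860.1	Bra009142	NA	NA	Bol044004	NA	NA
UGT76	AT5G05870.1	Bra009143	NA	NA	Bol044003	NA	NA
UGT76	AT5G05880.1	Bra009144	NA	NA	Bol043998	NA	NA
UGT76	AT5G05890.1	NA	NA	NA	Bol044000	NA	NA
UGT76	AT5G05900.1	Bra009145	NA	NA	NA	NA	NA
UGT84	AT2G23250.1	NA	Bra039191	NA	NA	NA	NA
UGT84	AT2G23260.1	NA	Bra039192	NA	NA	NA	NA
UGT84	AT4G15490.1	NA	NA	NA	Bol000782	NA	NA
UGT84	AT4G15500.1	NA	NA	NA	Bol000784	NA	NA
UGT85	AT1G22340.1	Bra031386	NA	NA	NA	NA	NA
UGT85	AT1G22360.1	Bra031387	NA	NA	NA	NA	NA
UGT85	AT1G22370.2	Bra031388	NA	NA	NA	NA	NA
UGT85	AT1G22380.1	NA	Bra012322	NA	NA	Bol041988	NA
UGT85	AT1G22400.1	NA	Bra012323	NA	NA	Bol041987	NA
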