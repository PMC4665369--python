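category	rrna_label	mt_label	human_partner	bacterial_equivalent	bacterial_partner	tunnel	placeable	het_data	direct	indirect	mito_biochem	note
NEE	122G > A	m.1792G > A	115C	G468	C461	Y	Y	Y	none	none	N
NEE	161G > A	m.1831G > A	169C	C535	G558		Y	Y	none	none	N
NEE	216G > A	m.1886G > A		U606			Y	Y	none	none	N
NEE	222A > G	m.1892A > G					Y	Y	none	none	N
NEE	235C > A	m.C1905C > A		C673		Y	Y	Y	none	none	N	mt label as printed
NEE	243G > A	m.1913G > A	336C	G681	C796	Y	Y	Y	none	none	N
NEE	270A > G	m.1940A > G	264U	C730	G702		Y	Y	none	none	N
NEE	282U > C	m.T1952T > C	295A	G742	C755		Y	Y	none	none	N	mt label as printed
NEE	297U > C	m.1967T > C	280U	U757	U740		Y	Y	none	none	N
NEE	320G > A	m.1990G > A		G780		Y	Y	Y	none	none	N
NEE	334G > A	m.2004G > A	245C	794	683	Y	Y	Y	none	none	N	bacterial cells printed without base letters
NEE	337U > C	m.2007T > C	242A	C797	G680	Y	Y	Y	none	none	N
NEE	345G > A	m.2015G > A		G805		Y	Y	Y	none	none	N
NEE	404delA	m.2074delA					Y	Y	none	none	N
NEE	409C > U	m.2079C > T					Y	Y	none	none	N
NEE	413U > G	m.2083T > G					Y	Y	none	none	N
NEE	449 3T > 4T	m.2119 3T > 4T	432A	U967	G950		Y	Y	none	none	N
NEE	451G > A	m.2121G > A	430C	G969	C948		Y	Y	none	none	N
NEE	478-479 dupAG	m.2148-2149 dupAG	582C & 583U	G997 & C998	G1157 & C1158		Y	Y	none	none	N
NEE	480 delU	m.2150 delT	?	U999	A1155		Y	Y	none	none	N	human partner printed as '?'
NEE	481 delA	m.2151 delA		A1000			Y	Y	none	none	N
NEE	605U > C	m.2275T > C	620A	U1199	A1246		Y	Y	none	none	N
NEE	880A > U	m.2550A > T		G1839			Y	Y	none	none	N	partner-like entry in bacterial-equivalent column as printed
NEE	948U > C	m.2618T > C		U1955			Y	Y	none	none	N
NEE	973G > C	m.2643G > C		A1980	C1771		Y	Y	none	none	N
NEE	974A > G	m.2644A > G		A1981			Y	Y	none	none	N
NEE	994U > C	m.2664T > C	793A	C2001	G1659		Y	Y	none	none	N
NEE	1028G > A	m.2698G > A		G2035		Y	Y	Y	none	none	N
NEE	1135A > U	m.2805A > T	1072U	A2241	U2079		Y	Y	none	none	N
NEE	1283U > C	m.2953T > C	1301A	C2466	G2484		Y	Y	none	none	N
NEE	1328 InsU	m.2998 InsT		U2511			Y	Y	none	none	N
NEE	1344G > A	m.3014G > A	1353C	C2527	G2536		Y	Y	none	none	N
NEE	1362G > A	m.3032G > A	1337C	G2545	C2520		Y	Y	none	none	N
NEE	1384G > A	m.3054G > A	1334C	G2567	C2517		Y	Y	none	none	N
NEE	1490A > U	m.3160A > T					Y	Y	none	none	N
NEE	1535C > U	m.3205C > T					Y	Y	none	none	N
U	34U > C	m.1704T > C					Y	Y	none	tolerance	N
U	253C > U	m.1923C > T	311G	C691	G771		Y	Y	none	tolerance	N
U	568A > G	m.2238A > G					Y	Y	none	tolerance	N
U	677C > U	m.2347C > T	696G				Y	Y	none	tolerance	N
U	1011G > A	m.2681G > A	157C	G2018	C531		Y	Y	none	tolerance	N
U	1433C > U	m.3103C > U	1046G	C2616	G2053		Y	Y	none	tolerance	N
und	399U > G	m.2069T > G					N	N	none	none	N
und	551C > U	m.2221C > T					N	N	none	none	N
und	1114A > C	m.2784A > C					N	N	none	none	N
und	1120 InsT	m.2790 InsT					N	N	none	none	N
und	1214C > U	m.2884C > T					N	N	none	none	N
L	629U > A	m.2299T > A		U1255			Y	Y	none	disruption	N
L	875U > C	m.2545T > C		U1834			Y	Y	none	disruption	N
L	889U > G	m.2559T > G					Y	Y	none	disruption	N
L	923G > A	m.2593G > A		G1930			Y	Y	none	disruption	N
L	1169C > A	m.2839C > A	1149G	C2275	G2255		Y	Y	none	disruption	N
L	1253G > A	m.2923G > A	1066C	G2436	C2073		Y	Y	none	disruption	N
L	1328U > C	m.2998T > C		U2511			Y	Y	none	disruption	N
L	1409G > A	m.3079G > A	1418C	G2592	C2601		Y	Y	none	disruption	N
L	1412G > C	m.3082G > C		G2595			Y	Y	none	disruption	N
L	1420G > A	m.3090G > A	1408C	G2603	C2591		Y	Y	none	disruption	N
L	1423C > G	m.3093C > G	1405G	C2606	G2588		Y	Y	none	disruption	N
L	1424G > A	m.3094G > A		G2607			Y	Y	none	disruption	N
E	1010U > C	m.2680T > C	636A	U2017	A1262	Y	Y	Y	disruption	none	N
E	1145G > A	m.2815G > A		G2251			Y	Y	disruption	none	N
E	1146G > A	m.2816G > A		G2252			Y	Y	disruption	none	N
E	1398G > A	m.3068G > A		G2581			Y	Y	disruption	none	N
P	173U > C	m.1843T > C	1026A	U562	A2033		Y	Y	none	disruption	Y
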