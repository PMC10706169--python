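# synthetic BRCA1/BRCA2-like toy panel (0-based half-open; name = GENE|EXON|POOL[|TAG])
chr17	43041500	43041650	BRCA1|ex1|p1|a1
chr17	43041660	43041810	BRCA1|ex1|p2|a2
chr17	43043000	43043150	BRCA1|ex2|p1
chr17	43044500	43044650	BRCA1|ex3|p2
chr17	43046000	43046150	BRCA1|ex4|p1|a1
chr17	43046160	43046310	BRCA1|ex4|p2|a2
chr17	43046320	43046470	BRCA1|ex4|p1|a3
chr17	43047500	43047650	BRCA1|ex5|p2|a1
chr17	43047660	43047810	BRCA1|ex5|p1|a2
chr17	43049000	43049150	BRCA1|ex6|p2
chr17	43050500	43050650	BRCA1|ex7|p1
chr17	43052000	43052150	BRCA1|ex8|p2|a1
chr17	43052160	43052310	BRCA1|ex8|p1|a2
chr17	43052320	43052470	BRCA1|ex8|p2|a3
chr17	43053500	43053650	BRCA1|ex9|p1|a1
chr17	43053660	43053810	BRCA1|ex9|p2|a2
chr17	43055000	43055150	BRCA1|ex10|p1
chr17	43056500	43056650	BRCA1|ex11|p2
chr17	43058000	43058150	BRCA1|ex12|p1|a1
chr17	43058160	43058310	BRCA1|ex12|p2|a2
chr17	43058320	43058470	BRCA1|ex12|p1|a3
chr17	43059500	43059650	BRCA1|ex13|p2|a1
chr17	43059660	43059810	BRCA1|ex13|p1|a2
chr17	43061000	43061150	BRCA1|ex14|p2
chr17	43062500	43062650	BRCA1|ex15|p1
chr17	43064000	43064150	BRCA1|ex16|p2|a1
chr17	43064160	43064310	BRCA1|ex16|p1|a2
chr17	43064320	43064470	BRCA1|ex16|p2|a3
chr17	43065500	43065650	BRCA1|ex17|p1|a1
chr17	43065660	43065810	BRCA1|ex17|p2|a2
chr17	43067000	43067150	BRCA1|ex18|p1
chr17	43068500	43068650	BRCA1|ex19|p2
chr17	43070000	43070150	BRCA1|ex20|p1|a1
chr17	43070160	43070310	BRCA1|ex20|p2|a2
chr17	43070320	43070470	BRCA1|ex20|p1|a3
chr17	43071500	43071650	BRCA1|ex21|p2|a1
chr17	43071660	43071810	BRCA1|ex21|p1|a2
chr17	43073000	43073150	BRCA1|ex22|p2
chr17	43074500	43074650	BRCA1|ex23|p1
chr17	43076000	43076150	BRCA1|ex24|p2|a1
chr17	43076160	43076310	BRCA1|ex24|p1|a2
chr17	43076320	43076470	BRCA1|ex24|p2|a3
chr17	43077500	43077650	BRCA1|ex25|p1|a1
chr17	43077660	43077810	BRCA1|ex25|p2|a2
chr13	32311500	32311650	BRCA2|ex1|p1|a1
chr13	32311660	32311810	BRCA2|ex1|p2|a2
chr13	32313000	32313150	BRCA2|ex2|p1
chr13	32314500	32314650	BRCA2|ex3|p2
chr13	32316000	32316150	BRCA2|ex4|p1|a1
chr13	32316160	32316310	BRCA2|ex4|p2|a2
chr13	32316320	32316470	BRCA2|ex4|p1|a3
chr13	32317500	32317650	BRCA2|ex5|p2|a1
chr13	32317660	32317810	BRCA2|ex5|p1|a2
chr13	32319000	32319150	BRCA2|ex6|p2
chr13	32320500	32320650	BRCA2|ex7|p1
chr13	32322000	32322150	BRCA2|ex8|p2|a1
chr13	32322160	32322310	BRCA2|ex8|p1|a2
chr13	32322320	32322470	BRCA2|ex8|p2|a3
chr13	32323500	32323650	BRCA2|ex9|p1|a1
chr13	32323660	32323810	BRCA2|ex9|p2|a2
chr13	32325000	32325150	BRCA2|ex10|p1
chr13	32326500	32326650	BRCA2|ex11|p2
chr13	32328000	32328150	BRCA2|ex12|p1|a1
chr13	32328160	32328310	BRCA2|ex12|p2|a2
chr13	32328320	32328470	BRCA2|ex12|p1|a3
chr13	32329500	32329650	BRCA2|ex13|p2|a1
chr13	32329660	32329810	BRCA2|ex13|p1|a2
chr13	32331000	32331150	BRCA2|ex14|p2
chr13	32332500	32332650	BRCA2|ex15|p1
chr13	32334000	32334150	BRCA2|ex16|p2|a1
chr13	32334160	32334310	BRCA2|ex16|p1|a2
chr13	32334320	32334470	BRCA2|ex16|p2|a3
chr13	32335500	32335650	BRCA2|ex17|p1|a1
chr13	32335660	32335810	BRCA2|ex17|p2|a2
chr13	32337000	32337150	BRCA2|ex18|p1
chr13	32338500	32338650	BRCA2|ex19|p2
chr13	32340000	32340150	BRCA2|ex20|p1|a1
chr13	32340160	32340310	BRCA2|ex20|p2|a2
chr13	32340320	32340470	BRCA2|ex20|p1|a3
chr13	32341500	32341650	BRCA2|ex21|p2|a1
chr13	32341660	32341810	BRCA2|ex21|p1|a2
chr13	32343000	32343150	BRCA2|ex22|p2
chr13	32344500	32344650	BRCA2|ex23|p1
chr13	32346000	32346150	BRCA2|ex24|p2|a1
chr13	32346160	32346310	BRCA2|ex24|p1|a2
chr13	32346320	32346470	BRCA2|ex24|p2|a3
chr13	32347500	32347650	BRCA2|ex25|p1|a1
chr13	32347660	32347810	BRCA2|ex25|p2|a2
chr13	32349000	32349150	BRCA2|ex26|p1
chr13	32350500	32350650	BRCA2|ex27|p2
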