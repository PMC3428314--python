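"""Bundled reference tables.

``TABLE1`` holds the published class/superfamily exaptation tabulation for
the human genome: counts of exapted CNEEs and bases alongside genomic
mobile-element fragments and bases, for each repeat class and superfamily
plus the grand total.  Only the four count columns are stored together with
the two ratio columns as printed; the package recomputes the ratios from
the counts (see :func:`exaptscan.intervals.summary_from_counts`), so the
printed ratio columns serve purely as a cross-check of the one-decimal
truncation arithmetic.
"""

from __future__ import annotations

import io

import pandas as pd

_TABLE1_TSV = """\
class	superfamily	exapted_elements	exapted_bases	genomic_elements	genomic_bases	printed_elements_per_exaptation	printed_bases_per_exapted_base
LINE	L1	67103	1963366	937370	511375943	13.9	260.4
LINE	L2	46532	946311	462005	103894644	9.9	109.7
LINE	CR1	19644	586282	60731	10855797	3	18.5
LINE	RTE	6218	156338	17696	3652083	2.8	23.3
LINE	Dong-R4	797	25967	550	120346	0.6	4.6
LINE	RTE-BovB	398	12401	659	74688	1.6	6
LINE	L1-like	44	1715	83	6788	1.8	3.9
LINE		140760	3695873	1479094	629957456	10.5	170.4
SINE	MIR	61335	1122485	590380	84230914	9.6	75
SINE	Deu	1815	70613	1266	178943	0.6	2.5
SINE	Alu	1624	107958	1174518	306522171	723.2	2839.2
SINE	SINE	1602	66502	964	161994	0.6	2.4
SINE	tRNA	1026	27838	1652	229877	1.6	8.2
SINE		67418	1397359	1768780	391323899	26.2	280
DNA	hAT-Charlie	23994	515751	251682	44862356	10.4	86.9
DNA	TcMar-Tigger	9024	264739	102787	33907139	11.3	128
DNA	hAT-Tip100	2663	64363	30206	6602950	11.3	102.5
DNA	TcMar-like	2380	127346	3426	624957	1.4	4.9
DNA	DNA	1894	88980	2750	339865	1.4	3.8
DNA	TcMar-Mariner	1496	39382	16229	2815735	10.8	71.4
DNA	TcMar-Tc2	1463	34606	8083	1664901	5.5	48.1
DNA	hAT-Blackjack	1360	31624	19571	3415244	14.3	107.9
DNA	hAT	767	12459	12421	1673724	16.1	134.3
DNA	TcMar	674	17320	1940	319735	2.8	18.4
DNA	PiggyBac-like	458	18964	239	44436	0.5	2.3
DNA	hAT-like	323	6851	3027	503467	9.3	73.4
DNA	PiggyBac	80	3041	2115	497959	26.4	163.7
DNA	MuDR	14	1302	1972	686896	140.8	527.5
DNA	Merlin	1	56	55	17595	55	314.1
DNA		46561	1226696	456503	97959784	9.8	79.8
LTR	ERVL-MaLR	14468	289612	343284	110688741	23.7	382.1
LTR	ERVL	8441	185880	157889	56087725	18.7	301.7
LTR	ERV1	2855	81186	172636	83248758	60.4	1025.4
LTR	Gypsy	1815	38904	10760	2295297	5.9	58.9
LTR	Gypsy-like	1323	26101	7808	1454545	5.9	55.7
LTR	LTR	837	22332	2196	472591	2.6	21.1
LTR	ERVL-like	320	6700	1782	413433	5.5	61.7
LTR	ERV	35	579	580	191020	16.5	329.9
LTR	ERVK	7	271	10455	8790037	1493.5	32435.5
LTR		30083	651379	707390	263530842	23.5	404.5
Total		284857	6988191	4411767	1382528004	15.4	197.8
"""


def load_table1() -> pd.DataFrame:
    """The published exaptation tabulation (counts + printed ratios)."""
    df = pd.read_csv(io.StringIO(_TABLE1_TSV), sep="\t", keep_default_na=False)
    df["superfamily"] = df["superfamily"].astype(str)
    return df


TABLE1 = load_table1()
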